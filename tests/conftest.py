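import pytest
from hypothesis import HealthCheck, settings

from phenochunk.chunkers import FeatureResources
from phenochunk.synthetic import generate_preset

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def resources() -> FeatureResources:
    return FeatureResources.bundled()


@pytest.fixture(scope="session")
def small_separable():
    """60 captions of the separable preset plus 20 held-out ones."""
    train, _ = generate_preset("separable", 60, 11)
    held, _ = generate_preset("separable", 20, 12)
    return train, held


@pytest.fixture(scope="session")
def paperlike_200():
    corpus, ledger = generate_preset("paperlike", 200, 5)
    return corpus, ledger
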