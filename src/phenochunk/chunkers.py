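"""Four divergent BIO sequence-labeling backends behind one contract.

Two linear-chain CRF variants (``crf_a``, ``crf_b``) differ in feature
preset and regularization strength; two SVM chunkers (``svm_ovo``,
``svm_ova``) are greedy left-to-right windowed token classifiers with a
degree-2 polynomial kernel, differing only in the multiclass decomposition
(one-vs-one vs one-vs-rest).  The SVM chunkers emulate forward parsing by
feeding the previously predicted label back in as a feature; a
linear-kernel fallback keeps them tractable on large corpora.

Per-backend best feature presets:

* ``crf_a`` — all simple + morphological features, generic gazetteers,
  token bigrams with window 3;
* ``crf_b`` — the same plus token unigrams with window 5, regularization
  constant 3.5;
* ``svm_ovo`` / ``svm_ova`` — all simple + morphological features, generic
  gazetteers, token unigrams with window 5.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import joblib
import numpy as np
import scipy.sparse as sp
from sklearn.feature_extraction import DictVectorizer
from sklearn.multiclass import OneVsOneClassifier, OneVsRestClassifier
from sklearn.svm import SVC, LinearSVC

from .corpus import Caption, Corpus, Span, bio_to_spans, spans_to_bio
from .crf import LinearChainCRF
from .features import (
    DOMAIN_DICTIONARIES,
    GENERIC_DICTIONARIES,
    KNOWN_FEATURES,
    Dictionary,
    FeatureConfig,
    featurize_sequence,
    load_bundled_dictionaries,
)
from .lexicon import LexiconProvider, default_providers

BACKENDS = ("crf_a", "crf_b", "svm_ovo", "svm_ova")

_START = "<s>"


def _csr32(X: sp.csr_matrix) -> sp.csr_matrix:
    # liblinear rejects 64-bit sparse indices
    X = X.tocsr()
    X.indices = X.indices.astype(np.int32, copy=False)
    X.indptr = X.indptr.astype(np.int32, copy=False)
    return X


@dataclass
class FeatureResources:
    """Lemma/POS providers and loaded gazetteers shared by featurization."""

    providers: tuple[LexiconProvider, LexiconProvider]
    dictionaries: dict[str, Dictionary]

    @classmethod
    def bundled(cls) -> "FeatureResources":
        return cls(
            providers=default_providers(),
            dictionaries=load_bundled_dictionaries(),
        )


@dataclass
class ChunkerSpec:
    """Declarative description of one backend + feature configuration."""

    backend: str
    feature_config: FeatureConfig
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backend not in BACKENDS:
            raise ValueError(f"unknown backend {self.backend!r}")

    def to_dict(self) -> dict:
        return {
            "backend": self.backend,
            "feature_config": self.feature_config.to_dict(),
            "hyperparams": dict(self.hyperparams),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChunkerSpec":
        return cls(
            backend=d["backend"],
            feature_config=FeatureConfig.from_dict(d["feature_config"]),
            hyperparams=dict(d.get("hyperparams", {})),
            seed=int(d.get("seed", 0)),
        )


def preset_spec(
    name: str, with_domain_dicts: bool = False, seed: int = 0
) -> ChunkerSpec:
    """Best-known per-backend feature configuration.

    All presets enable every simple and morphological feature plus the four
    generic gazetteers; ``with_domain_dicts`` adds the anatomy and quality
    gazetteers.  The backends differ in their token-context features and
    hyperparameters (see module docstring).
    """
    if name not in BACKENDS:
        raise ValueError(f"unknown preset {name!r}")
    dictionaries = GENERIC_DICTIONARIES + (
        DOMAIN_DICTIONARIES if with_domain_dicts else ()
    )
    context = {
        "crf_a": [("bi", 3)],
        "crf_b": [("bi", 3), ("uni", 5)],
        "svm_ovo": [("uni", 5)],
        "svm_ova": [("uni", 5)],
    }[name]
    hyper: dict = {
        "crf_a": {"c": 1.0},
        "crf_b": {"c": 3.5},
        "svm_ovo": {"kernel": "poly", "degree": 2, "scheme": "ovo"},
        "svm_ova": {"kernel": "poly", "degree": 2, "scheme": "ova"},
    }[name]
    config = FeatureConfig.make(
        enabled=KNOWN_FEATURES,
        affix_n=5,
        context_specs=context,
        dictionaries=dictionaries,
    )
    return ChunkerSpec(
        backend=name, feature_config=config, hyperparams=hyper, seed=seed
    )


def featurize_caption(
    caption: Caption, config: FeatureConfig, resources: FeatureResources
) -> list[dict[str, str]]:
    """Per-token feature dicts for one caption."""
    return [
        fv.features
        for fv in featurize_sequence(
            caption, config, resources.providers, resources.dictionaries
        )
    ]


def _to_item_strings(feat_dicts: list[dict[str, str]]) -> list[list[str]]:
    return [[f"{k}={v}" for k, v in d.items()] for d in feat_dicts]


class _ConstantTagger:
    """Degenerate fallback when training data contains a single label."""

    def __init__(self, label: str):
        self.label = label

    def predict_sequence(self, feat_dicts):
        return [self.label] * len(feat_dicts)


class SvmTagger:
    """Greedy left-to-right SVM token classifier with a previous-label feature.

    Training uses gold previous labels (teacher forcing); prediction feeds
    back the model's own previous decision, which emulates a forward
    parsing chunker.
    """

    def __init__(
        self,
        scheme: str = "ovo",
        kernel: str = "poly",
        degree: int = 2,
        C: float = 1.0,
        seed: int = 0,
        linear_fallback: bool = False,
    ):
        if scheme not in ("ovo", "ova"):
            raise ValueError(f"unknown multiclass scheme {scheme!r}")
        self.scheme = scheme
        self.kernel = kernel
        self.degree = degree
        self.C = C
        self.seed = seed
        self.linear_fallback = linear_fallback
        self._vec: DictVectorizer | None = None
        self._est = None

    def _base_estimator(self):
        if self.linear_fallback or self.kernel == "linear":
            return LinearSVC(
                C=self.C, random_state=self.seed, max_iter=5000, dual="auto"
            )
        return SVC(
            kernel=self.kernel,
            degree=self.degree,
            coef0=1.0,
            C=self.C,
            random_state=self.seed,
        )

    def fit(
        self,
        seq_feat_dicts: list[list[dict[str, str]]],
        seq_labels: list[list[str]],
    ) -> "SvmTagger":
        rows: list[dict[str, str]] = []
        ys: list[str] = []
        for fs, ls in zip(seq_feat_dicts, seq_labels):
            prev = _START
            for d, lab in zip(fs, ls):
                rows.append({**d, "prev": prev})
                ys.append(lab)
                prev = lab
        if not rows:
            raise ValueError("no training tokens")
        classes = sorted(set(ys))
        if len(classes) == 1:
            self._est = _ConstantTagger(classes[0])
            return self
        self._vec = DictVectorizer()
        X = _csr32(self._vec.fit_transform(rows))
        base = self._base_estimator()
        est = (
            OneVsOneClassifier(base)
            if self.scheme == "ovo"
            else OneVsRestClassifier(base)
        )
        est.fit(X, np.asarray(ys))
        self._est = est
        return self

    def predict_sequence(self, feat_dicts: list[dict[str, str]]) -> list[str]:
        if self._est is None:
            raise RuntimeError("SvmTagger is not fitted")
        if isinstance(self._est, _ConstantTagger):
            return self._est.predict_sequence(feat_dicts)
        if not feat_dicts:
            return []
        X_base = _csr32(self._vec.transform(feat_dicts))  # prev columns all zero
        n_feats = X_base.shape[1]
        vocab = self._vec.vocabulary_
        unit_cache: dict[str, sp.csr_matrix] = {}

        def prev_unit(prev: str) -> sp.csr_matrix | None:
            if prev not in unit_cache:
                j = vocab.get(f"prev={prev}")
                unit_cache[prev] = (
                    None
                    if j is None
                    else sp.csr_matrix(
                        ([1.0], ([0], [j])), shape=(1, n_feats)
                    )
                )
            return unit_cache[prev]

        labels: list[str] = []
        prev = _START
        for t in range(X_base.shape[0]):
            x = X_base[t]
            u = prev_unit(prev)
            if u is not None:
                x = _csr32(x + u)
            prev = str(self._est.predict(x)[0])
            labels.append(prev)
        return labels


@dataclass
class TrainedChunker:
    """A fitted sequence labeler: token sequences → BIO label sequences."""

    spec: ChunkerSpec
    model: object  # LinearChainCRF | SvmTagger | _ConstantTagger
    resources: FeatureResources

    def predict_labels(self, caption: Caption) -> list[str]:
        feat_dicts = featurize_caption(
            caption, self.spec.feature_config, self.resources
        )
        if isinstance(self.model, LinearChainCRF):
            return self.model.predict(_to_item_strings(feat_dicts))
        return self.model.predict_sequence(feat_dicts)

    def predict_spans(self, caption: Caption) -> list[Span]:
        return bio_to_spans(self.predict_labels(caption))

    def save(self, path) -> None:
        """Serialized model plus a JSON sidecar recording the spec."""
        joblib.dump(self, path)
        with open(f"{path}.spec.json", "w", encoding="utf-8") as fh:
            json.dump(self.spec.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "TrainedChunker":
        obj = joblib.load(path)
        if not isinstance(obj, cls):
            raise TypeError(f"{path} does not contain a TrainedChunker")
        return obj


def train(
    spec: ChunkerSpec,
    corpus: Corpus,
    resources: FeatureResources | None = None,
    *,
    linear_fallback: bool = False,
    max_iter: int | None = None,
    precomputed: dict[str, list[dict[str, str]]] | None = None,
) -> TrainedChunker:
    """Train one backend on a corpus.

    ``precomputed`` optionally maps caption id → per-token feature dicts
    (already extracted under ``spec.feature_config``); cross-validation uses
    it to featurize each corpus once rather than once per fold.
    """
    if resources is None:
        resources = FeatureResources.bundled()
    captions = [c for c in corpus if len(c.tokens) > 0]
    if not captions:
        raise ValueError("cannot train on an empty corpus")

    seq_feats = [
        precomputed[c.id]
        if precomputed is not None
        else featurize_caption(c, spec.feature_config, resources)
        for c in captions
    ]
    seq_labels = [spans_to_bio(c) for c in captions]

    if spec.backend.startswith("crf"):
        c = float(spec.hyperparams.get("c", 1.0))
        crf = LinearChainCRF(
            l2=1.0 / c,
            max_iter=max_iter or int(spec.hyperparams.get("max_iter", 80)),
        )
        crf.fit(_to_item_strings_nested(seq_feats), seq_labels)
        model: object = crf
    else:
        tagger = SvmTagger(
            scheme=spec.hyperparams.get("scheme", "ovo"),
            kernel=spec.hyperparams.get("kernel", "poly"),
            degree=int(spec.hyperparams.get("degree", 2)),
            C=float(spec.hyperparams.get("C", 1.0)),
            seed=spec.seed,
            linear_fallback=linear_fallback
            or bool(spec.hyperparams.get("linear_fallback", False)),
        )
        tagger.fit(seq_feats, seq_labels)
        model = tagger
    return TrainedChunker(spec=spec, model=model, resources=resources)


def _to_item_strings_nested(
    seq_feats: list[list[dict[str, str]]],
) -> list[list[list[str]]]:
    return [_to_item_strings(fs) for fs in seq_feats]


def predict_labels(model: TrainedChunker, caption: Caption) -> list[str]:
    return model.predict_labels(caption)


def predict_spans(model: TrainedChunker, caption: Caption) -> list[Span]:
    return model.predict_spans(caption)
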