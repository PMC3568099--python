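"""Entity-level scoring, stratified folds, cross-validation, ablation."""

import random

import pytest

from phenochunk.aggregation import VoteConfig
from phenochunk.chunkers import ChunkerSpec, preset_spec
from phenochunk.corpus import Caption, Corpus, Span
from phenochunk.evaluation import (
    System,
    ablate_leave_one_out,
    ablate_single,
    cross_validate,
    cross_validate_suite,
    match_spans,
    prf,
    stratified_folds,
)
from phenochunk.features import FeatureConfig
from phenochunk.synthetic import generate_preset


class TestMatching:
    def test_exact_match_counts(self):
        gold = [Span(0, 2), Span(5, 6)]
        pred = [Span(0, 2), Span(8, 9)]
        assert match_spans(gold, pred) == (1, 1, 1)

    def test_perfect_prediction(self):
        gold = [Span(0, 2), Span(5, 6)]
        assert match_spans(gold, list(gold)) == (2, 0, 0)

    def test_boundary_error_scores_zero_under_exact_match(self):
        assert match_spans([Span(0, 3)], [Span(0, 2)]) == (0, 1, 1)
        # diagnostic overlap mode credits the partial match
        assert match_spans([Span(0, 3)], [Span(0, 2)], mode="overlap") == (1, 0, 0)

    def test_agreement_with_pairwise_bruteforce(self):
        rng = random.Random(3)
        for _ in range(300):
            gold = [Span(i, i + rng.randint(1, 2)) for i in
                    sorted(rng.sample(range(0, 20, 3), rng.randint(0, 5)))]
            pred = [Span(i, i + rng.randint(1, 2)) for i in
                    sorted(rng.sample(range(0, 20, 3), rng.randint(0, 5)))]
            tp = sum(
                1 for g in gold
                if any(p.tok_start == g.tok_start and p.tok_end == g.tok_end
                       for p in pred)
            )
            assert match_spans(gold, pred) == (tp, len(pred) - tp, len(gold) - tp)


class TestPRF:
    @pytest.mark.parametrize(
        "counts,p,r,f1",
        [((1, 1, 1), 0.5, 0.5, 0.5), ((2, 0, 0), 1, 1, 1), ((0, 3, 2), 0, 0, 0)],
    )
    def test_values(self, counts, p, r, f1):
        m = prf(*counts)
        assert (m.precision, m.recall, m.f1) == (p, r, f1)

    def test_degenerate_flagged(self):
        assert prf(0, 0, 0).degenerate

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            prf(-1, 0, 0)

    def test_f1_between_min_and_max_of_p_and_r(self):
        rng = random.Random(4)
        for _ in range(200):
            m = prf(rng.randint(0, 9), rng.randint(0, 9), rng.randint(0, 9))
            if m.precision + m.recall > 0:
                eps = 1e-12
                assert min(m.precision, m.recall) - eps <= m.f1
                assert m.f1 <= max(m.precision, m.recall) + eps


class TestStratifiedFolds:
    def _corpus(self, span_counts):
        caps = []
        for i, n in enumerate(span_counts):
            tokens = " ".join(f"t{j}" for j in range(max(2 * n, 2)))
            spans = [Span(2 * j, 2 * j + 1) for j in range(n)]
            caps.append(Caption.from_text(f"c{i}", tokens, spans))
        return Corpus(captions=caps)

    def test_equal_fold_sizes(self):
        corpus = self._corpus([0, 1, 2, 3, 4, 5, 0, 1, 2, 3] * 2)
        folds = stratified_folds(corpus, 10, seed=0)
        sizes = [len(folds.fold_ids(f)) for f in range(10)]
        assert sizes == [2] * 10

    def test_partition_covers_corpus_disjointly(self, paperlike_200):
        corpus, _ = paperlike_200
        folds = stratified_folds(corpus, 10, seed=1)
        all_ids = [cid for f in range(10) for cid in folds.fold_ids(f)]
        assert sorted(all_ids) == sorted(c.id for c in corpus)

    def test_strata_balanced_within_one(self, paperlike_200):
        corpus, _ = paperlike_200
        folds = stratified_folds(corpus, 10, seed=1)
        from phenochunk.evaluation import _stratum
        strata = {c.id: _stratum(len(c.gold_spans)) for c in corpus}
        for b in range(4):
            per_fold = [
                sum(1 for cid in folds.fold_ids(f) if strata[cid] == b)
                for f in range(10)
            ]
            assert max(per_fold) - min(per_fold) <= 1

    def test_deterministic_per_seed_and_sensitive_to_seed(self, paperlike_200):
        corpus, _ = paperlike_200
        a = stratified_folds(corpus, 10, seed=5)
        b = stratified_folds(corpus, 10, seed=5)
        c = stratified_folds(corpus, 10, seed=6)
        assert a.assignment == b.assignment
        assert a.assignment != c.assignment

    def test_k_larger_than_corpus_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            stratified_folds(self._corpus([1, 2]), 5, seed=0)


class TestCrossValidation:
    @staticmethod
    def _pattern_corpus(n=40):
        # every fold sees the full (tiny) vocabulary: the "quality word
        # before thorax" rule is learnable from any k-1 folds
        caps = []
        for i in range(n):
            q = ["short", "broad", "narrow", "small"][i % 4]
            if i % 2 == 0:
                caps.append(Caption.from_text(
                    f"c{i}", f"the {q} thorax is seen", [Span(1, 3)]))
            else:
                caps.append(Caption.from_text(
                    f"c{i}", "the thorax appears normal today", []))
        return Corpus(captions=caps)

    def test_perfect_system_scores_one_and_is_reproducible(self, resources):
        corpus = self._pattern_corpus()
        spec = preset_spec("crf_a")
        r1 = cross_validate(corpus, spec, k=5, seed=2, resources=resources)
        assert len(r1.per_fold) == 5
        assert r1.mean.f1 == pytest.approx(1.0)
        r2 = cross_validate(corpus, spec, k=5, seed=2, resources=resources)
        assert [m.f1 for m in r1.per_fold] == [m.f1 for m in r2.per_fold]

    def test_suite_shares_folds_and_union_dominates_recall(self, resources,
                                                           small_separable):
        corpus, _ = small_separable
        specs = {
            "crf_a": preset_spec("crf_a"),
            "svm_ova": preset_spec("svm_ova"),
        }
        systems = [
            System(name="crf_a", kind="chunker", chunker="crf_a"),
            System(name="svm_ova", kind="chunker", chunker="svm_ova"),
            System(name="union", kind="expr",
                   expr=["union", "crf_a", "svm_ova"]),
            System(name="vote", kind="vote",
                   vote=VoteConfig(
                       voters=("crf_a", "crf_a2", "svm_ova", "svm_ova2"),
                       veto_owner="crf_a")),
        ]
        specs["crf_a2"] = preset_spec("crf_a", seed=1)
        specs["svm_ova2"] = preset_spec("svm_ova", seed=1)
        results = cross_validate_suite(
            corpus, specs, systems, k=5, seed=3,
            resources=resources, linear_fallback=True,
        )
        for fold in range(5):
            assert results["union"].per_fold[fold].recall >= max(
                results["crf_a"].per_fold[fold].recall,
                results["svm_ova"].per_fold[fold].recall,
            )
        assert 0.0 <= results["vote"].mean.f1 <= 1.0

    def test_mean_is_arithmetic_mean_of_folds(self, resources, small_separable):
        corpus, _ = small_separable
        r = cross_validate(corpus, preset_spec("svm_ovo"), k=5, seed=2,
                           resources=resources, linear_fallback=True)
        assert r.mean.f1 == pytest.approx(
            sum(m.f1 for m in r.per_fold) / len(r.per_fold)
        )

    def test_unknown_system_spec_rejected(self, small_separable, resources):
        corpus, _ = small_separable
        with pytest.raises(KeyError, match="ghost"):
            cross_validate_suite(
                corpus, {}, [System(name="x", kind="chunker", chunker="ghost")],
                k=2, seed=0, resources=resources,
            )


@pytest.fixture(scope="module")
def planted():
    from phenochunk.features import Dictionary, load_bundled_dictionaries
    from phenochunk.lexicon import default_providers
    from phenochunk.chunkers import FeatureResources
    from phenochunk.synthetic import planted_signal_corpus

    corpus, markers = planted_signal_corpus(120, 7)
    res = FeatureResources(
        providers=default_providers(),
        dictionaries={
            **load_bundled_dictionaries(),
            "marker": Dictionary("marker", frozenset(markers)),
        },
    )
    base = ChunkerSpec(
        backend="crf_a",
        feature_config=FeatureConfig.make(
            enabled=("prefix", "suffix", "digits"),
            dictionaries=("marker",),
        ),
        hyperparams={"c": 1.0},
    )
    return corpus, res, base


class TestAblation:
    def test_single_feature_rows_and_planted_signal(self, planted):
        corpus, res, base = planted
        report = ablate_single(base, corpus, k=4, seed=1, resources=res)
        assert set(report.rows) == {"prefix", "suffix", "digits", "dict_marker"}
        f1 = {n: r.mean.f1 for n, r in report.rows.items()}
        assert max(f1, key=f1.get) == "dict_marker"
        # reproducible per seed
        again = ablate_single(base, corpus, k=4, seed=1, resources=res)
        assert {n: r.mean.f1 for n, r in again.rows.items()} == f1

    def test_leave_one_out_degrades_most_without_signal_feature(self, planted):
        corpus, res, base = planted
        report = ablate_leave_one_out(base, corpus, k=4, seed=1, resources=res)
        assert set(report.rows) == {"prefix", "suffix", "digits", "dict_marker"}
        f1 = {n: r.mean.f1 for n, r in report.rows.items()}
        assert min(f1, key=f1.get) == "dict_marker"
        # 'digits' is constant ("no*") on this corpus: removing it is neutral
        full = cross_validate(corpus, base, k=4, seed=1, resources=res)
        assert abs(f1["digits"] - full.mean.f1) < 0.02
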