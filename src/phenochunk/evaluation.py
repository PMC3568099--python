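"""Entity-level scoring, stratified cross-validation and feature ablation.

Scoring is exact-match at the entity level: a predicted span counts as a
true positive only when its token boundaries equal a gold span's.  Fold
metrics pool counts over the captions of the fold; the cross-validation
summary is the arithmetic mean of the per-fold precision/recall/F1 (macro
over folds).  A partial-overlap matching mode exists for diagnostics only.

Fold assignment is stratified on the caption's gold span count (bins 0,
1–2, 3–5, 6+): captions in each bin are shuffled with the seeded RNG and
dealt round-robin, so fold sizes differ by at most one and each bin's
distribution across folds is balanced.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Sequence

from .aggregation import SpanSet, VoteConfig, evaluate_expr, majority_vote_veto
from .chunkers import (
    ChunkerSpec,
    FeatureResources,
    TrainedChunker,
    featurize_caption,
    train,
)
from .corpus import Caption, Corpus, Span, bio_to_spans, spans_to_bio
from .features import (
    DOMAIN_DICTIONARIES,
    GENERIC_DICTIONARIES,
    FeatureConfig,
)

STRATA_BINS = ((0, 0), (1, 2), (3, 5), (6, None))


@dataclass
class EvalMetrics:
    """Precision/recall/F1 with the counts they derive from."""

    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    degenerate: bool = False


def prf(tp: int, fp: int, fn: int) -> EvalMetrics:
    """Standard precision/recall/F1; zero denominators yield 0, flagged."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    degenerate = False
    if tp + fp == 0:
        p, degenerate = 0.0, True
    else:
        p = tp / (tp + fp)
    if tp + fn == 0:
        r, degenerate = 0.0, True
    else:
        r = tp / (tp + fn)
    f1 = 0.0 if p + r == 0 else 2 * p * r / (p + r)
    return EvalMetrics(tp=tp, fp=fp, fn=fn, precision=p, recall=r, f1=f1,
                       degenerate=degenerate)


def match_spans(
    gold: Sequence[Span], pred: Sequence[Span], mode: str = "exact"
) -> tuple[int, int, int]:
    """(tp, fp, fn) for one caption.

    ``exact`` (the scoring criterion) counts identical (start, end)
    intervals; ``overlap`` (diagnostic) greedily matches each predicted span
    to an unused overlapping gold span.
    """
    if mode == "exact":
        tp = len({(s.tok_start, s.tok_end) for s in gold}
                 & {(s.tok_start, s.tok_end) for s in pred})
    elif mode == "overlap":
        used: set[int] = set()
        tp = 0
        for p in pred:
            for gi, g in enumerate(gold):
                if gi in used:
                    continue
                if p.tok_start < g.tok_end and g.tok_start < p.tok_end:
                    used.add(gi)
                    tp += 1
                    break
    else:
        raise ValueError(f"unknown matching mode {mode!r}")
    return tp, len(pred) - tp, len(gold) - tp


def score_spansets(gold: SpanSet, pred: SpanSet) -> EvalMetrics:
    """Exact-match metrics between corpus-level span sets."""
    tp = len(gold.elements & pred.elements)
    return prf(tp, len(pred) - tp, len(gold) - tp)


@dataclass
class FoldAssignment:
    """Caption id → fold index partition for k-fold cross-validation."""

    k: int
    assignment: dict[str, int]
    seed: int

    def fold_ids(self, fold: int) -> list[str]:
        return [cid for cid, f in self.assignment.items() if f == fold]


def _stratum(n_spans: int) -> int:
    for i, (lo, hi) in enumerate(STRATA_BINS):
        if n_spans >= lo and (hi is None or n_spans <= hi):
            return i
    raise AssertionError("unreachable")


def stratified_folds(corpus: Corpus, k: int, seed: int) -> FoldAssignment:
    """Partition captions into k folds, stratified on gold span count."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(corpus):
        raise ValueError(f"k={k} exceeds corpus size {len(corpus)}")
    rng = random.Random(seed)
    bins: dict[int, list[str]] = {i: [] for i in range(len(STRATA_BINS))}
    for cap in corpus:
        bins[_stratum(len(cap.gold_spans))].append(cap.id)
    assignment: dict[str, int] = {}
    counter = 0  # continues across bins so overall fold sizes differ by <= 1
    for b in sorted(bins):
        ids = bins[b]
        rng.shuffle(ids)
        for cid in ids:
            assignment[cid] = counter % k
            counter += 1
    return FoldAssignment(k=k, assignment=assignment, seed=seed)


@dataclass
class CVResult:
    """Per-fold and fold-averaged entity-level metrics."""

    per_fold: list[EvalMetrics]
    mean: EvalMetrics

    def as_dict(self) -> dict:
        def row(m: EvalMetrics) -> dict:
            return {
                "precision": m.precision, "recall": m.recall, "f1": m.f1,
                "tp": m.tp, "fp": m.fp, "fn": m.fn,
            }
        return {"per_fold": [row(m) for m in self.per_fold],
                "mean": row(self.mean)}


def _mean_metrics(per_fold: list[EvalMetrics]) -> EvalMetrics:
    n = len(per_fold)
    return EvalMetrics(
        tp=sum(m.tp for m in per_fold),
        fp=sum(m.fp for m in per_fold),
        fn=sum(m.fn for m in per_fold),
        precision=sum(m.precision for m in per_fold) / n,
        recall=sum(m.recall for m in per_fold) / n,
        f1=sum(m.f1 for m in per_fold) / n,
        degenerate=any(m.degenerate for m in per_fold),
    )


# ---------------------------------------------------------------------------
# systems: a single chunker, a set expression, or a voting ensemble


@dataclass
class System:
    """A named evaluation target over a shared pool of chunker specs.

    ``kind`` is "chunker" (evaluate one spec's predictions), "expr"
    (a union/intersection tree over spec ids), or "vote"
    (token-level majority voting with veto over four spec ids).
    """

    name: str
    kind: str
    chunker: str | None = None
    expr: list | None = None
    vote: VoteConfig | None = None

    def required_specs(self) -> set[str]:
        if self.kind == "chunker":
            return {self.chunker}
        if self.kind == "expr":
            return _expr_leaves(self.expr)
        if self.kind == "vote":
            return set(self.vote.voters)
        raise ValueError(f"unknown system kind {self.kind!r}")


def _expr_leaves(expr) -> set[str]:
    if isinstance(expr, str):
        return {expr}
    return set().union(*(_expr_leaves(c) for c in expr[1:]))


def cross_validate_suite(
    corpus: Corpus,
    specs: dict[str, ChunkerSpec],
    systems: Sequence[System],
    k: int = 10,
    seed: int = 0,
    resources: FeatureResources | None = None,
    linear_fallback: bool = False,
    max_iter: int | None = None,
) -> dict[str, CVResult]:
    """k-fold CV for several systems sharing per-fold trained chunkers.

    All chunkers named by any system are trained once per fold on the k−1
    training folds; every system is then scored on the held-out fold from
    those shared predictions.  Featurization is cached per distinct feature
    configuration across folds (extraction is per-token and fold-independent;
    model-side feature indexing still sees only training data).
    """
    if resources is None:
        resources = FeatureResources.bundled()
    needed = set().union(*(s.required_specs() for s in systems))
    missing = needed - set(specs)
    if missing:
        raise KeyError(f"systems reference unknown specs: {sorted(missing)}")

    # featurize once per distinct feature config
    feat_cache: dict[FeatureConfig, dict[str, list[dict[str, str]]]] = {}
    for sid in needed:
        cfg = specs[sid].feature_config
        if cfg not in feat_cache:
            feat_cache[cfg] = {
                c.id: featurize_caption(c, cfg, resources) for c in corpus
            }

    folds = stratified_folds(corpus, k, seed)
    by_id = {c.id: c for c in corpus}
    per_system: dict[str, list[EvalMetrics]] = {s.name: [] for s in systems}

    for fold in range(k):
        test_ids = set(folds.fold_ids(fold))
        train_caps = [c for c in corpus if c.id not in test_ids]
        test_caps = [by_id[cid] for cid in sorted(test_ids)]
        train_corpus = Corpus(captions=train_caps, provenance=corpus.provenance)

        # audit: never train on held-out captions
        assert not ({c.id for c in train_caps} & test_ids)

        fold_labels: dict[str, dict[str, list[str]]] = {}
        for sid in sorted(needed):
            spec = specs[sid]
            model = train(
                spec,
                train_corpus,
                resources,
                linear_fallback=linear_fallback,
                max_iter=max_iter,
                precomputed=feat_cache[spec.feature_config],
            )
            fold_labels[sid] = {
                c.id: _predict_cached(
                    model, c, feat_cache[spec.feature_config][c.id]
                )
                for c in test_caps
            }

        gold_set = SpanSet.from_predictions(
            {c.id: c.gold_spans for c in test_caps}
        )
        span_sets = {
            sid: SpanSet.from_predictions(
                {cid: bio_to_spans(labs) for cid, labs in preds.items()}
            )
            for sid, preds in fold_labels.items()
        }

        for system in systems:
            if system.kind == "chunker":
                pred = span_sets[system.chunker]
            elif system.kind == "expr":
                pred = evaluate_expr(system.expr, span_sets)
            else:
                voted = {
                    c.id: bio_to_spans(
                        majority_vote_veto(
                            {v: fold_labels[v][c.id] for v in system.vote.voters},
                            system.vote,
                        )
                    )
                    for c in test_caps
                }
                pred = SpanSet.from_predictions(voted)
            per_system[system.name].append(score_spansets(gold_set, pred))

    return {
        name: CVResult(per_fold=ms, mean=_mean_metrics(ms))
        for name, ms in per_system.items()
    }


def _predict_cached(
    model: TrainedChunker, caption: Caption, feat_dicts: list[dict[str, str]]
) -> list[str]:
    from .chunkers import LinearChainCRF, _to_item_strings

    if isinstance(model.model, LinearChainCRF):
        return model.model.predict(_to_item_strings(feat_dicts))
    return model.model.predict_sequence(feat_dicts)


def cross_validate(
    corpus: Corpus,
    system: ChunkerSpec | tuple[dict[str, ChunkerSpec], list | VoteConfig],
    k: int = 10,
    seed: int = 0,
    **kwargs,
) -> CVResult:
    """k-fold stratified CV for one system (chunker or ensemble)."""
    if isinstance(system, ChunkerSpec):
        specs = {"model": system}
        sys_obj = System(name="model", kind="chunker", chunker="model")
    else:
        specs, combiner = system
        if isinstance(combiner, VoteConfig):
            sys_obj = System(name="ensemble", kind="vote", vote=combiner)
        else:
            sys_obj = System(name="ensemble", kind="expr", expr=combiner)
    return cross_validate_suite(
        corpus, specs, [sys_obj], k=k, seed=seed, **kwargs
    )[sys_obj.name]


# ---------------------------------------------------------------------------
# ablation protocols


@dataclass
class AblationReport:
    """Per-feature CV results for single-feature or leave-one-out runs."""

    mode: str  # "single_feature" | "leave_one_out"
    rows: dict[str, CVResult] = field(default_factory=dict)


def _ablation_units(config: FeatureConfig) -> list[tuple[str, dict]]:
    """The separately ablatable pieces of a feature configuration.

    Simple/morphological features ablate individually; context specs
    ablate per (gram, window); gazetteers ablate as the generic and domain
    groups.
    """
    units: list[tuple[str, dict]] = []
    for name in sorted(config.enabled):
        units.append((name, {"enabled": {name}}))
    for spec in config.context_specs:
        units.append((f"context_{spec[0]}{spec[1]}", {"context_specs": [spec]}))
    generic = tuple(d for d in config.dictionaries if d in GENERIC_DICTIONARIES)
    domain = tuple(d for d in config.dictionaries if d in DOMAIN_DICTIONARIES)
    other = tuple(
        d for d in config.dictionaries if d not in generic + domain
    )
    if generic:
        units.append(("dict_generic", {"dictionaries": generic}))
    if domain:
        units.append(("dict_domain", {"dictionaries": domain}))
    for d in other:
        units.append((f"dict_{d}", {"dictionaries": (d,)}))
    return units


def _only_config(config: FeatureConfig, part: dict) -> FeatureConfig:
    return FeatureConfig.make(
        enabled=part.get("enabled", ()),
        affix_n=config.affix_n,
        context_specs=part.get("context_specs", ()),
        dictionaries=part.get("dictionaries", ()),
    )


def _without_config(config: FeatureConfig, part: dict) -> FeatureConfig:
    drop_ctx = set(map(tuple, part.get("context_specs", ())))
    drop_dicts = set(part.get("dictionaries", ()))
    return FeatureConfig.make(
        enabled=config.enabled - set(part.get("enabled", ())),
        affix_n=config.affix_n,
        context_specs=[c for c in config.context_specs if c not in drop_ctx],
        dictionaries=[d for d in config.dictionaries if d not in drop_dicts],
    )


def _ablation_cv(
    base: ChunkerSpec, config: FeatureConfig, corpus, k, seed, **kwargs
) -> CVResult:
    spec = ChunkerSpec(
        backend=base.backend,
        feature_config=config,
        hyperparams=dict(base.hyperparams),
        seed=base.seed,
    )
    return cross_validate(corpus, spec, k=k, seed=seed, **kwargs)


def ablate_single(
    base: ChunkerSpec, corpus: Corpus, k: int = 10, seed: int = 0, **kwargs
) -> AblationReport:
    """One CV run per feature unit, enabling only that unit."""
    units = _ablation_units(base.feature_config)
    if len(units) < 2:
        raise ValueError("ablation needs at least two feature units")
    report = AblationReport(mode="single_feature")
    for name, part in units:
        cfg = _only_config(base.feature_config, part)
        report.rows[name] = _ablation_cv(base, cfg, corpus, k, seed, **kwargs)
    return report


def ablate_leave_one_out(
    base: ChunkerSpec, corpus: Corpus, k: int = 10, seed: int = 0, **kwargs
) -> AblationReport:
    """One CV run per feature unit, removing that unit from the base."""
    units = _ablation_units(base.feature_config)
    if len(units) < 2:
        raise ValueError("ablation needs at least two feature units")
    report = AblationReport(mode="leave_one_out")
    for name, part in units:
        cfg = _without_config(base.feature_config, part)
        report.rows[name] = _ablation_cv(base, cfg, corpus, k, seed, **kwargs)
    return report
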