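"""Ensemble aggregation: span-set algebra and majority voting with veto.

Two aggregation families combine the four chunkers' outputs:

* set operations — predicted spans across the corpus are treated as sets of
  exact ``(caption_id, tok_start, tok_end)`` triples; union keeps every
  outcome (recall-oriented), intersection keeps only outcomes present in
  both results (precision-oriented).  Expressions nest, e.g.
  ``["intersect", ["union", "crf_a", "svm_ova"], ["union", "crf_b", "svm_ovo"]]``.
* majority voting with veto — per token, the BIO label receiving at least
  50% of the votes and a unique maximum wins; on a tie at the threshold
  (or no label reaching it) the designated veto owner's label wins.
  The voted sequence is repaired before span decoding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .corpus import BIO_LABELS, repair_bio

SpanTriple = tuple[str, int, int]


@dataclass(frozen=True)
class SpanSet:
    """Predicted spans over a corpus, as exact (caption, start, end) triples.

    Overlapping-but-unequal spans are distinct members; no merging policy is
    applied.
    """

    elements: frozenset[SpanTriple]

    @classmethod
    def from_predictions(cls, spans_by_caption: dict[str, Sequence]) -> "SpanSet":
        """Build from a map caption id → span list (token-interval spans)."""
        triples = {
            (cid, s.tok_start, s.tok_end)
            for cid, spans in spans_by_caption.items()
            for s in spans
        }
        return cls(frozenset(triples))

    def __len__(self) -> int:
        return len(self.elements)

    def __contains__(self, triple: SpanTriple) -> bool:
        return triple in self.elements


def span_union(a: SpanSet, b: SpanSet) -> SpanSet:
    """Keep every outcome from either result."""
    return SpanSet(a.elements | b.elements)


def span_intersection(a: SpanSet, b: SpanSet) -> SpanSet:
    """Keep only outcomes present in both results."""
    return SpanSet(a.elements & b.elements)


# Expression trees are nested lists: a leaf is a classifier id (str); an
# internal node is ["union"|"intersect", child, child, ...].
_OPS = {"union": span_union, "intersect": span_intersection}


def evaluate_expr(expr, predictions: dict[str, SpanSet]) -> SpanSet:
    """Recursively evaluate a union/intersection expression tree."""
    if isinstance(expr, str):
        try:
            return predictions[expr]
        except KeyError:
            raise KeyError(f"no predictions for classifier {expr!r}") from None
    if not isinstance(expr, (list, tuple)) or len(expr) < 3:
        raise ValueError(
            f"malformed expression {expr!r}: expected [op, child, child, ...]"
        )
    op, *children = expr
    if op not in _OPS:
        raise ValueError(f"unknown operator {op!r}")
    result = evaluate_expr(children[0], predictions)
    for child in children[1:]:
        result = _OPS[op](result, evaluate_expr(child, predictions))
    return result


@dataclass(frozen=True)
class VoteConfig:
    """Voting setup: ordered voter ids, the veto owner, and the threshold.

    ``threshold`` is the minimum vote fraction a label needs (default 0.5,
    i.e. "50% or more"); the veto owner resolves ties at the threshold.
    """

    voters: tuple[str, str, str, str]
    veto_owner: str
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if len(self.voters) != 4 or len(set(self.voters)) != 4:
            raise ValueError("exactly four distinct voters are required")
        if self.veto_owner not in self.voters:
            raise ValueError(f"veto owner {self.veto_owner!r} is not a voter")
        if not 0.0 < self.threshold <= 1.0:
            raise ValueError("threshold must be in (0, 1]")


def majority_vote_veto(
    label_seqs: dict[str, Sequence[str]], config: VoteConfig
) -> list[str]:
    """Token-wise majority vote over four aligned BIO sequences.

    Per token: the label with the strictly highest count, provided that
    count reaches ``ceil(threshold * 4)`` votes, wins.  If two labels tie at
    or above the threshold — or no label reaches it — the veto owner's own
    label wins (even when the veto owner voted a third label).  The result
    is repaired to a decodable BIO sequence.
    """
    seqs = []
    for v in config.voters:
        if v not in label_seqs:
            raise KeyError(f"missing label sequence for voter {v!r}")
        seqs.append(list(label_seqs[v]))
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"label sequences differ in length: {sorted(lengths)}")

    need = math.ceil(config.threshold * len(config.voters))
    veto_idx = config.voters.index(config.veto_owner)
    out: list[str] = []
    for votes in zip(*seqs):
        for lab in votes:
            if lab not in BIO_LABELS:
                raise ValueError(f"unknown BIO label {lab!r}")
        counts = {lab: votes.count(lab) for lab in set(votes)}
        top = max(counts.values())
        winners = [lab for lab, c in counts.items() if c == top]
        if top >= need and len(winners) == 1:
            out.append(winners[0])
        else:
            out.append(votes[veto_idx])
    return repair_bio(out)
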