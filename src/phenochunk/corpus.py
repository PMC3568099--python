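"""Annotated caption corpora: tokenization, BIO coding, readers/writers, statistics.

A corpus is an ordered collection of figure captions.  Each caption carries
its raw text, a tokenization with character offsets, and gold phenotype
spans expressed as half-open token intervals.  Phenotype mentions are a
single entity class, so label sequences use the plain ``B``/``I``/``O``
alphabet without a type suffix.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

BIO_LABELS = ("B", "I", "O")

#: words (with internal hyphens/apostrophes kept), otherwise one char per token
_TOKEN_RE = re.compile(r"[A-Za-z0-9]+(?:[-'][A-Za-z0-9]+)*|\S")


class CorpusFormatError(ValueError):
    """Raised for malformed corpus files or invalid annotations."""


@dataclass(frozen=True)
class Token:
    """A token with half-open character offsets into its caption text."""

    text: str
    char_start: int
    char_end: int

    def __post_init__(self) -> None:
        if not (0 <= self.char_start < self.char_end):
            raise ValueError(
                f"invalid token offsets [{self.char_start}, {self.char_end})"
            )


@dataclass(frozen=True, order=True)
class Span:
    """A phenotype-description mention as a half-open token interval."""

    tok_start: int
    tok_end: int
    label: str = "PHENO"

    def __post_init__(self) -> None:
        if not (0 <= self.tok_start < self.tok_end):
            raise ValueError(
                f"invalid span interval [{self.tok_start}, {self.tok_end})"
            )

    def __len__(self) -> int:
        return self.tok_end - self.tok_start


@dataclass
class Caption:
    """One figure caption: text, tokens and gold phenotype spans."""

    id: str
    text: str
    tokens: list[Token]
    gold_spans: list[Span] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.gold_spans = sorted(self.gold_spans)
        _check_spans(self.gold_spans, len(self.tokens))

    @classmethod
    def from_text(
        cls, id: str, text: str, gold_spans: Iterable[Span] = ()
    ) -> "Caption":
        return cls(id=id, text=text, tokens=tokenize(text), gold_spans=list(gold_spans))

    @property
    def token_texts(self) -> list[str]:
        return [t.text for t in self.tokens]


@dataclass
class Corpus:
    """An ordered caption collection with free-text provenance metadata."""

    captions: list[Caption]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [c.id for c in self.captions]
        if len(ids) != len(set(ids)):
            raise ValueError("caption ids are not unique")

    def __len__(self) -> int:
        return len(self.captions)

    def __iter__(self):
        return iter(self.captions)

    def __getitem__(self, i: int) -> Caption:
        return self.captions[i]


@dataclass
class CorpusStats:
    """Summary statistics over captions, tokens and gold spans.

    Means are exact :class:`~fractions.Fraction` values; span means are
    ``None`` for a corpus without spans.
    """

    n_captions: int
    n_tokens: int
    n_spans: int
    mean_tokens_per_caption: Fraction | None
    mean_spans_per_caption: Fraction | None
    mean_tokens_per_span: Fraction | None
    min_span_len: int | None
    max_span_len: int | None

    def as_dict(self, precision: int = 3) -> dict:
        def fmt(x):
            return None if x is None else round(float(x), precision)

        return {
            "n_captions": self.n_captions,
            "n_tokens": self.n_tokens,
            "n_spans": self.n_spans,
            "mean_tokens_per_caption": fmt(self.mean_tokens_per_caption),
            "mean_spans_per_caption": fmt(self.mean_spans_per_caption),
            "mean_tokens_per_span": fmt(self.mean_tokens_per_span),
            "min_span_len": self.min_span_len,
            "max_span_len": self.max_span_len,
        }


def _check_spans(spans: Sequence[Span], n_tokens: int) -> None:
    prev_end = 0
    for s in spans:
        if s.tok_end > n_tokens:
            raise ValueError(f"span {s} exceeds token count {n_tokens}")
        if s.tok_start < prev_end:
            raise ValueError(f"overlapping gold spans at {s}")
        prev_end = s.tok_end


def tokenize(text: str) -> list[Token]:
    """Split text into tokens over non-whitespace runs.

    Punctuation becomes separate one-character tokens, except hyphens and
    apostrophes internal to a word, which stay attached ("bell-shaped" is a
    single token).  Offsets are half-open into ``text``; re-slicing the text
    by them reproduces the token strings exactly.
    """
    return [
        Token(m.group(), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)
    ]


def spans_to_bio(caption: Caption) -> list[str]:
    """Encode gold spans as one B/I/O label per token."""
    _check_spans(caption.gold_spans, len(caption.tokens))
    labels = ["O"] * len(caption.tokens)
    for s in caption.gold_spans:
        labels[s.tok_start] = "B"
        for i in range(s.tok_start + 1, s.tok_end):
            labels[i] = "I"
    return labels


def repair_bio(labels: Sequence[str]) -> list[str]:
    """Turn any I that does not continue a span into a B.

    Classifier (and voting) output can be structurally invalid; repair makes
    every sequence decodable.  Idempotent.
    """
    out = []
    prev = "O"
    for lab in labels:
        if lab not in BIO_LABELS:
            raise ValueError(f"unknown BIO label {lab!r}")
        if lab == "I" and prev == "O":
            lab = "B"
        out.append(lab)
        prev = lab
    return out


def bio_to_spans(labels: Sequence[str]) -> list[Span]:
    """Decode a label sequence into spans (maximal ``B I*`` runs).

    A leading or post-O ``I`` is repaired to ``B`` first, so any sequence
    over the BIO alphabet decodes.  Inverse of :func:`spans_to_bio` on valid
    sequences.
    """
    labels = repair_bio(labels)
    spans: list[Span] = []
    start = None
    for i, lab in enumerate(labels):
        if lab == "B":
            if start is not None:
                spans.append(Span(start, i))
            start = i
        elif lab == "O":
            if start is not None:
                spans.append(Span(start, i))
                start = None
    if start is not None:
        spans.append(Span(start, len(labels)))
    return spans


# ---------------------------------------------------------------------------
# CoNLL-style two-column format


def write_conll(corpus: Corpus, path) -> None:
    """Write ``token<TAB>label`` lines, captions separated by a blank line."""
    with open(path, "w", encoding="utf-8") as fh:
        for caption in corpus:
            for tok, lab in zip(caption.tokens, spans_to_bio(caption)):
                fh.write(f"{tok.text}\t{lab}\n")
            fh.write("\n")


def read_conll(path, provenance: str = "") -> Corpus:
    """Read a two-column CoNLL-style file back into a :class:`Corpus`.

    Caption text is reconstructed by joining tokens with single spaces, so
    ``read(write(c))`` preserves token texts, labels and caption boundaries
    (original whitespace is not kept).
    """
    captions: list[Caption] = []
    toks: list[str] = []
    labs: list[str] = []

    def flush() -> None:
        if not toks:
            return
        text = " ".join(toks)
        cap = Caption.from_text(f"c{len(captions) + 1:04d}", text)
        if [t.text for t in cap.tokens] != toks:
            # tokens containing whitespace can't occur; re-tokenization of a
            # space-joined token list must be the identity
            cap = Caption(
                id=f"c{len(captions) + 1:04d}",
                text=text,
                tokens=_retokenize_exact(text, toks),
            )
        cap.gold_spans = bio_to_spans(labs)
        _check_spans(cap.gold_spans, len(cap.tokens))
        captions.append(cap)
        toks.clear()
        labs.clear()

    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                flush()
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise CorpusFormatError(
                    f"{path}:{lineno}: expected 'token<TAB>label', got {line!r}"
                )
            tok, lab = parts
            if lab not in BIO_LABELS:
                raise CorpusFormatError(
                    f"{path}:{lineno}: unknown label {lab!r} (expected B/I/O)"
                )
            toks.append(tok)
            labs.append(lab)
    flush()
    return Corpus(captions=captions, provenance=provenance or str(path))


def _retokenize_exact(text: str, toks: list[str]) -> list[Token]:
    """Token objects for a space-joined token list, preserving token texts."""
    out = []
    pos = 0
    for t in toks:
        start = text.index(t, pos)
        out.append(Token(t, start, start + len(t)))
        pos = start + len(t)
    return out


# ---------------------------------------------------------------------------
# Stand-off JSON format (character-offset spans over raw caption text)


def write_standoff(corpus: Corpus, path) -> None:
    payload = {"captions": []}
    for cap in corpus:
        payload["captions"].append(
            {
                "id": cap.id,
                "text": cap.text,
                "spans": [
                    {
                        "start": cap.tokens[s.tok_start].char_start,
                        "end": cap.tokens[s.tok_end - 1].char_end,
                    }
                    for s in cap.gold_spans
                ],
            }
        )
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, ensure_ascii=False, indent=1)
        fh.write("\n")


def char_span_to_token_span(caption: Caption, start: int, end: int) -> Span:
    """Map a half-open character span to the smallest covering token span.

    A character span not aligned with token boundaries is snapped outward
    (with a logged warning) rather than rejected.
    """
    if not (0 <= start < end <= len(caption.text)):
        raise CorpusFormatError(
            f"caption {caption.id}: char span ({start}, {end}) outside text"
        )
    tok_start = tok_end = None
    for i, tok in enumerate(caption.tokens):
        if tok.char_end > start and tok_start is None:
            tok_start = i
        if tok.char_start < end:
            tok_end = i + 1
    if tok_start is None or tok_end is None or tok_start >= tok_end:
        raise CorpusFormatError(
            f"caption {caption.id}: char span ({start}, {end}) covers no token"
        )
    snapped_start = caption.tokens[tok_start].char_start
    snapped_end = caption.tokens[tok_end - 1].char_end
    if (snapped_start, snapped_end) != (start, end):
        logger.warning(
            "caption %s: char span (%d, %d) snapped outward to (%d, %d)",
            caption.id, start, end, snapped_start, snapped_end,
        )
    return Span(tok_start, tok_end)


def read_standoff(path, provenance: str = "") -> Corpus:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    captions = []
    for entry in payload["captions"]:
        cap = Caption.from_text(entry["id"], entry["text"])
        spans = [
            char_span_to_token_span(cap, s["start"], s["end"])
            for s in entry["spans"]
        ]
        cap.gold_spans = sorted(spans)
        _check_spans(cap.gold_spans, len(cap.tokens))
        captions.append(cap)
    return Corpus(captions=captions, provenance=provenance or str(path))


# ---------------------------------------------------------------------------


def corpus_stats(corpus: Corpus) -> CorpusStats:
    """Exact corpus statistics (counts as ints, means as Fractions)."""
    n_captions = len(corpus)
    n_tokens = sum(len(c.tokens) for c in corpus)
    span_lens = [len(s) for c in corpus for s in c.gold_spans]
    n_spans = len(span_lens)
    return CorpusStats(
        n_captions=n_captions,
        n_tokens=n_tokens,
        n_spans=n_spans,
        mean_tokens_per_caption=(
            Fraction(n_tokens, n_captions) if n_captions else None
        ),
        mean_spans_per_caption=(
            Fraction(n_spans, n_captions) if n_captions else None
        ),
        mean_tokens_per_span=(
            Fraction(sum(span_lens), n_spans) if n_spans else None
        ),
        min_span_len=min(span_lens) if span_lens else None,
        max_span_len=max(span_lens) if span_lens else None,
    )
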