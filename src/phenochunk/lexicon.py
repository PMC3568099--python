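"""Pluggable lemma / part-of-speech providers.

Two providers back the lemma and POS features: a rule-based shallow-NLP
style provider with a fine-grained Penn-like tagset (always returns a
value), and a lexicon-lookup provider over a bundled word list with a
concise tagset (noun/adj/verb/...), which reports absence explicitly for
out-of-list tokens.  The lookup provider's partial coverage is intentional:
downstream features encode absent lookups with a shared sentinel, which
flattens the feature's discriminative power for uncovered vocabulary.
"""

from __future__ import annotations

from importlib import resources
from typing import Protocol, runtime_checkable


@runtime_checkable
class LexiconProvider(Protocol):
    """Deterministic lemma/POS lookup; ``None`` signals an absent entry."""

    def lemma(self, text: str) -> str | None: ...

    def pos(self, text: str) -> str | None: ...


_DETERMINERS = {"the", "a", "an", "this", "that", "these", "those"}
_CONJUNCTIONS = {"and", "or", "nor", "but", "either", "neither"}
_PREPOSITIONS = {
    "of", "in", "at", "on", "to", "with", "within", "without", "from", "by",
    "for", "into", "between", "under", "over", "near", "along", "across",
    "through", "during", "as", "than",
}
_BE_FORMS = {"is": "be", "are": "be", "was": "be", "were": "be", "be": "be"}

_ADJ_SUFFIXES = ("ous", "ive", "ic", "al", "ar", "ile", "oid", "like", "shaped")
_ADV_SUFFIX = "ly"


class RuleLexiconProvider:
    """Shallow rule-based lemmatizer and tagger.

    Total (never absent) and deterministic.  The tagset is Penn-style
    (NN, NNS, JJ, VBG, VBN, RB, IN, CC, DT, CD, PUNCT) — deliberately more
    varied than the lookup provider's concise tags.
    """

    def lemma(self, text: str) -> str:
        w = text.lower()
        if w in _BE_FORMS:
            return _BE_FORMS[w]
        if len(w) > 4 and w.endswith("ies"):
            return w[:-3] + "y"
        if len(w) > 3 and w.endswith("es") and w[-3] in "sxzh":
            return w[:-2]
        if len(w) > 3 and w.endswith("s") and not w.endswith("ss"):
            return w[:-1]
        if len(w) > 5 and w.endswith("ing"):
            stem = w[:-3]
            return stem + "e" if stem[-1] not in "aeiou" and stem[-2:-1] in "aeiou" else stem
        if len(w) > 4 and w.endswith("ed"):
            return w[:-2]
        return w

    def pos(self, text: str) -> str:
        w = text.lower()
        if not any(ch.isalnum() for ch in text):
            return "PUNCT"
        if any(ch.isdigit() for ch in text):
            return "CD"
        if w in _DETERMINERS:
            return "DT"
        if w in _CONJUNCTIONS:
            return "CC"
        if w in _PREPOSITIONS:
            return "IN"
        if w in _BE_FORMS or w.endswith(("ise", "ize", "ate")):
            return "VB"
        if w.endswith("ing"):
            return "VBG"
        if w.endswith("ed"):
            return "VBN"
        if w.endswith(_ADV_SUFFIX) and len(w) > 3:
            return "RB"
        if w.endswith(_ADJ_SUFFIXES):
            return "JJ"
        if w.endswith("s") and not w.endswith("ss") and len(w) > 3:
            return "NNS"
        if text[:1].isupper() and w[1:].islower():
            return "NNP"
        return "NN"


class WordlistLexiconProvider:
    """Lookup provider over a tab-separated ``word lemma pos`` word list.

    Lookups are case-folded; words outside the list are absent (``None``).
    """

    def __init__(self, entries: dict[str, tuple[str, str]]):
        self._entries = entries

    @classmethod
    def from_file(cls, path) -> "WordlistLexiconProvider":
        entries: dict[str, tuple[str, str]] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                word, lemma, pos = line.split("\t")
                entries[word.lower()] = (lemma, pos)
        return cls(entries)

    @classmethod
    def bundled(cls) -> "WordlistLexiconProvider":
        ref = resources.files("phenochunk.data") / "lexicon_wordlist.txt"
        with resources.as_file(ref) as path:
            return cls.from_file(path)

    def lemma(self, text: str) -> str | None:
        entry = self._entries.get(text.lower())
        return entry[0] if entry else None

    def pos(self, text: str) -> str | None:
        entry = self._entries.get(text.lower())
        return entry[1] if entry else None


def default_providers() -> tuple[LexiconProvider, LexiconProvider]:
    """(primary rule-based, secondary bundled-wordlist) provider pair."""
    return RuleLexiconProvider(), WordlistLexiconProvider.bundled()
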