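"""Per-token feature extraction: simple, morphological, dictionary and
context feature families, assembled under a declarative configuration.

Feature values are categorical strings; a model backend turns each
``(name, value)`` pair into one indicator dimension.  Four families are
available:

* simple — character affixes up to length ``affix_n`` plus lemma and POS
  from two independent providers (a rule-based tagger and a lexicon lookup
  whose misses are encoded by the shared sentinel ``"@"``);
* morphological — punctuation flag, vowel pattern, digit pattern, word
  shape and compressed ("brief") shape;
* dictionary — case-folded unigram membership in named gazetteers;
* context — unigram/bigram/trigram windows of neighbouring tokens.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

from .corpus import Caption, Token
from .lexicon import LexiconProvider

ABSENT_SENTINEL = "@"
PAD = "<PAD>"

SIMPLE_FEATURES = ("prefix", "suffix", "lemma_nlp", "lemma_lex", "pos_nlp", "pos_lex")
MORPH_FEATURES = ("punct", "vowels", "digits", "shape", "brief_shape")
KNOWN_FEATURES = SIMPLE_FEATURES + MORPH_FEATURES

GENERIC_DICTIONARIES = ("ordinals", "conjunctions", "connectives", "coordinates")
DOMAIN_DICTIONARIES = ("anatomy", "quality")

_GRAMS = ("uni", "bi", "tri")
_VOWELS = frozenset("aeiouAEIOU")


@dataclass(frozen=True)
class Dictionary:
    """A named unigram gazetteer (lowercase single-token terms)."""

    name: str
    terms: frozenset[str]

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError(f"dictionary {self.name!r} is empty")
        bad = [t for t in self.terms if t != t.lower() or any(c.isspace() for c in t)]
        if bad:
            raise ValueError(f"dictionary {self.name!r}: non-unigram or non-lowercase terms {bad[:3]}")

    def __contains__(self, token_text: str) -> bool:
        return token_text.lower() in self.terms

    @classmethod
    def from_file(cls, name: str, path) -> "Dictionary":
        terms = set()
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if line:
                    terms.add(line.lower())
        return cls(name, frozenset(terms))


def load_bundled_dictionaries() -> dict[str, Dictionary]:
    """The six bundled gazetteers, keyed by name."""
    out = {}
    for name in GENERIC_DICTIONARIES + DOMAIN_DICTIONARIES:
        ref = resources.files("phenochunk.data") / f"dict_{name}.txt"
        with resources.as_file(ref) as path:
            out[name] = Dictionary.from_file(name, path)
    return out


@dataclass(frozen=True)
class FeatureConfig:
    """Declarative description of the feature battery for one model.

    ``enabled`` selects simple/morphological feature names;
    ``context_specs`` lists ``(gram, window)`` pairs with gram in
    {uni, bi, tri} and window (tokens on each side) in 1..5;
    ``dictionaries`` names the gazetteers to apply.
    """

    enabled: frozenset[str] = frozenset()
    affix_n: int = 5
    context_specs: tuple[tuple[str, int], ...] = ()
    dictionaries: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        unknown = set(self.enabled) - set(KNOWN_FEATURES)
        if unknown:
            raise ValueError(f"unknown feature names: {sorted(unknown)}")
        if self.affix_n < 1:
            raise ValueError("affix_n must be >= 1")
        for gram, w in self.context_specs:
            if gram not in _GRAMS:
                raise ValueError(f"unknown context gram {gram!r}")
            if not 1 <= w <= 5:
                raise ValueError(f"context window {w} outside 1..5")
        if len(set(self.dictionaries)) != len(self.dictionaries):
            raise ValueError("duplicate dictionary names")

    @classmethod
    def make(
        cls,
        enabled: Sequence[str] = (),
        affix_n: int = 5,
        context_specs: Sequence[tuple[str, int]] = (),
        dictionaries: Sequence[str] = (),
    ) -> "FeatureConfig":
        return cls(
            enabled=frozenset(enabled),
            affix_n=affix_n,
            context_specs=tuple((g, int(w)) for g, w in context_specs),
            dictionaries=tuple(dictionaries),
        )

    def to_dict(self) -> dict:
        return {
            "enabled": sorted(self.enabled),
            "affix_n": self.affix_n,
            "context_specs": [list(cs) for cs in self.context_specs],
            "dictionaries": list(self.dictionaries),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureConfig":
        return cls.make(
            enabled=d.get("enabled", ()),
            affix_n=d.get("affix_n", 5),
            context_specs=[tuple(cs) for cs in d.get("context_specs", ())],
            dictionaries=d.get("dictionaries", ()),
        )


@dataclass
class FeatureVector:
    """Named feature→value map for one token."""

    token_index: int
    features: dict[str, str] = field(default_factory=dict)

    def items(self):
        return self.features.items()


# ---------------------------------------------------------------------------
# feature families


def extract_simple(
    token: Token,
    primary: LexiconProvider,
    secondary: LexiconProvider,
    n: int = 5,
) -> dict[str, str]:
    """Affixes up to length n, plus lemma/POS from both providers.

    Affixes are truncated at the token length ("flattening" at n=5 yields
    prefixes f, fl, fla, flat, flatt and suffixes g, ng, ing, ning, ening).
    An absent lookup is encoded by the sentinel ``"@"``, so all uncovered
    tokens share one value.
    """
    if n < 1:
        raise ValueError("affix length must be >= 1")
    text = token.text
    out: dict[str, str] = {}
    for i in range(1, min(n, len(text)) + 1):
        out[f"p{i}"] = text[:i]
        out[f"s{i}"] = text[-i:]
    out["lemma_nlp"] = primary.lemma(text) or ABSENT_SENTINEL
    out["pos_nlp"] = primary.pos(text) or ABSENT_SENTINEL
    out["lemma_lex"] = secondary.lemma(text) or ABSENT_SENTINEL
    out["pos_lex"] = secondary.pos(text) or ABSENT_SENTINEL
    return out


def vowel_pattern(text: str) -> str:
    """Consonants replaced by '-', vowels kept ("flattening" → "--a--e-i--")."""
    return "".join("-" if c.isalpha() and c not in _VOWELS else c for c in text)


def digit_pattern(text: str) -> str:
    """Digits replaced by '*'; tokens without digits map to the shared "no*"."""
    if not any(c.isdigit() for c in text):
        return "no*"
    return "".join("*" if c.isdigit() else c for c in text)


def word_shape(text: str) -> str:
    """Uppercase → 'A', lowercase → 'a', digit → '0', other characters kept."""
    out = []
    for c in text:
        if c.isupper():
            out.append("A")
        elif c.islower():
            out.append("a")
        elif c.isdigit():
            out.append("0")
        else:
            out.append(c)
    return "".join(out)


def brief_shape(text: str) -> str:
    """Word shape with runs of equal adjacent characters compressed ("Aa")."""
    shape = word_shape(text)
    out = []
    for c in shape:
        if not out or out[-1] != c:
            out.append(c)
    return "".join(out)


def extract_morph(token: Token) -> dict[str, str]:
    text = token.text
    return {
        "punct": "true" if any(not c.isalnum() for c in text) else "false",
        "vowels": vowel_pattern(text),
        "digits": digit_pattern(text),
        "shape": word_shape(text),
        "brief_shape": brief_shape(text),
    }


def extract_dict(token: Token, dictionaries: Sequence[Dictionary]) -> dict[str, str]:
    """One boolean membership feature per gazetteer (case-folded)."""
    return {
        f"dict_{d.name}": "true" if token.text in d else "false"
        for d in dictionaries
    }


def extract_context(
    sequence: Sequence[Token], i: int, spec: tuple[str, int]
) -> dict[str, str]:
    """n-gram context features from the symmetric window around token i.

    uni emits each window position (2w+1 features, offset 0 included);
    bi each adjacent pair with both offsets inside the window (2w);
    tri each adjacent triple (2w−1).  Positions outside the sequence take
    the boundary sentinel.
    """
    gram, w = spec
    if not 0 <= i < len(sequence):
        raise IndexError(f"token index {i} out of range")
    if gram not in _GRAMS:
        raise ValueError(f"unknown context gram {gram!r}")

    def at(o: int) -> str:
        j = i + o
        return sequence[j].text if 0 <= j < len(sequence) else PAD

    out: dict[str, str] = {}
    if gram == "uni":
        for o in range(-w, w + 1):
            out[f"u{w}[{o:+d}]"] = at(o)
    elif gram == "bi":
        for o in range(-w, w):
            out[f"b{w}[{o:+d}]"] = f"{at(o)}|{at(o + 1)}"
    else:
        for o in range(-w, w - 1):
            out[f"t{w}[{o:+d}]"] = f"{at(o)}|{at(o + 1)}|{at(o + 2)}"
    return out


def featurize_sequence(
    caption: Caption,
    config: FeatureConfig,
    providers: tuple[LexiconProvider, LexiconProvider],
    dictionaries: dict[str, Dictionary],
) -> list[FeatureVector]:
    """One FeatureVector per token, exactly the union of enabled families."""
    primary, secondary = providers
    active_dicts = []
    for name in config.dictionaries:
        if name not in dictionaries:
            raise ValueError(f"dictionary {name!r} not loaded")
        active_dicts.append(dictionaries[name])

    want_simple = [f for f in SIMPLE_FEATURES if f in config.enabled]
    want_morph = [f for f in MORPH_FEATURES if f in config.enabled]

    vectors = []
    for i, token in enumerate(caption.tokens):
        feats: dict[str, str] = {}
        if want_simple:
            simple = extract_simple(token, primary, secondary, config.affix_n)
            for name in want_simple:
                if name == "prefix":
                    feats.update(
                        {k: v for k, v in simple.items()
                         if k[0] == "p" and k[1:].isdigit()}
                    )
                elif name == "suffix":
                    feats.update(
                        {k: v for k, v in simple.items()
                         if k[0] == "s" and k[1:].isdigit()}
                    )
                else:
                    feats[name] = simple[name]
        if want_morph:
            morph = extract_morph(token)
            for name in want_morph:
                feats[name] = morph[name]
        if active_dicts:
            feats.update(extract_dict(token, active_dicts))
        for spec in config.context_specs:
            feats.update(extract_context(caption.tokens, i, spec))
        vectors.append(FeatureVector(token_index=i, features=feats))
    return vectors
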