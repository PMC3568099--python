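"""Synthetic figure-caption corpus generator.

Generates annotated caption corpora with the structure of real
skeletal-radiology figure captions: multi-sentence captions averaging a few
phenotype-description spans each, span lengths from one token up to a hard
cap of 31 averaging about five, a mix of canonical ("bell-shaped thorax"),
verb-linked ("ribs appear short", with the linking verb inside the span),
conjunction-chained ("short and wide ribs with metaphyseal cupping") and
nested ("flattening, underdevelopment and squaring of the heads of the
metacarpals") forms, abbreviations (L4-S1), hedges/qualifiers, and
non-phenotype distractor sentences.  Leading articles stay outside spans.

Everything is template-driven and seeded: the same configuration and seed
reproduce a byte-identical corpus, and the generator returns a ledger of
its own bookkeeping (true span counts and form types per caption) for
downstream assertions.

Three presets:

* ``separable`` — spans are exactly the gazetteer pattern
  "quality term followed by anatomy term" and the distractor vocabulary is
  disjoint from the quality list, so the labeling is fully determined by
  visible evidence; a sanity upper bound for any competent chunker.
* ``hard`` — the full form mix plus two planted difficulties: tokens such
  as "radial" and "long" are used both inside and outside phenotype roles,
  and a fraction of well-formed phenotype phrases is left unannotated,
  emulating the expert-judgment cases no surface feature can resolve.
* ``paperlike`` — caption sizes and span statistics emulating a real
  annotated corpus (≈50 tokens/caption, ≈4 spans/caption, span mean ≈5).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .corpus import Caption, Corpus, Span, tokenize

MAX_SPAN_LEN = 31

FORMS = ("canonical", "verb_linked", "conjunction", "nested")


@dataclass(frozen=True)
class GenConfig:
    """Generation parameters; defaults mirror the target corpus statistics."""

    n_captions: int = 100
    mean_spans_per_caption: float = 4.0
    span_length_target: float = 5.0
    form_mix: tuple[float, float, float, float] = (0.40, 0.25, 0.20, 0.15)
    distractor_rate: float = 0.35
    abbreviation_rate: float = 0.08
    hedge_rate: float = 0.15
    ambiguity_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_captions < 1:
            raise ValueError("n_captions must be >= 1")
        if abs(sum(self.form_mix) - 1.0) > 1e-9:
            raise ValueError("form_mix must sum to 1")
        for name in ("distractor_rate", "abbreviation_rate", "hedge_rate",
                     "ambiguity_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 1.0 <= self.span_length_target <= MAX_SPAN_LEN:
            raise ValueError("span_length_target outside [1, 31]")


@dataclass(frozen=True)
class Lexicons:
    """Word lists the templates draw from.

    Anatomy and quality lists must be disjoint; seed vocabulary follows the
    domain's stock examples (thorax, ribs, metacarpals, bell-shaped,
    hitchhiker, flattening, L4, ...).
    """

    anatomy: tuple[str, ...]
    quality: tuple[str, ...]
    metaphor: tuple[str, ...]
    hedges: tuple[str, ...]
    verbs: tuple[str, ...]
    gerunds: tuple[str, ...]
    coordinates: tuple[str, ...]
    abbreviations: tuple[str, ...]
    distractor_nouns: tuple[str, ...]
    standalone: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name in ("anatomy", "quality", "metaphor", "hedges", "verbs",
                     "gerunds"):
            if not getattr(self, name):
                raise ValueError(f"lexicon {name!r} is empty")
        overlap = set(self.anatomy) & set(self.quality)
        if overlap:
            raise ValueError(f"anatomy/quality lists overlap: {sorted(overlap)}")


DEFAULT_LEXICONS = Lexicons(
    anatomy=(
        "thorax", "ribs", "clavicles", "metacarpals", "metatarsals", "femur",
        "tibia", "fibula", "humerus", "radius", "ulna", "vertebrae", "pelvis",
        "skull", "thumb", "fingers", "spine", "phalanges", "metaphyses",
        "epiphyses", "hands", "feet", "knees", "hips", "sternum", "scapula",
        "acetabulum", "mandible", "patella", "sacrum",
    ),
    quality=(
        "short", "wide", "broad", "flattened", "irregular", "hypoplastic",
        "bowed", "narrow", "small", "squared", "thickened", "sclerotic",
        "cupped", "fragmented", "elongated", "widened", "dysplastic",
        "osteopenic", "gracile", "stippled", "beaked", "deformed",
    ),
    metaphor=(
        "bell-shaped", "cone-shaped", "wedge-shaped", "hitchhiker",
        "bone-in-bone", "trident", "spade-like",
    ),
    hedges=("subtle", "mild", "apparent", "possible", "slight", "probable"),
    verbs=("are", "appear", "remain", "look", "seem"),
    gerunds=(
        "flattening", "squaring", "cupping", "bowing", "thickening",
        "narrowing", "widening", "underdevelopment", "shortening",
        "fragmentation", "sclerosis", "irregularity",
    ),
    coordinates=("proximal", "distal", "bilateral", "left", "right",
                 "cervical", "thoracic", "lumbar"),
    abbreviations=("L1", "L4", "L5", "S1", "T12", "C2", "L4-S1", "T10-L2"),
    distractor_nouns=(
        "radiograph", "film", "view", "appearance", "examination", "patient",
        "image", "study", "scan",
    ),
    standalone=(
        "platyspondyly", "brachydactyly", "arachnodactyly", "clinodactyly",
        "scoliosis", "kyphosis", "polydactyly",
    ),
)

# deliberately confusable vocabulary for the hard preset: "radial" names a
# coordinate and an anatomical entity; "long" is both a quality and part of
# the entity name "long bones"
_AMBIGUOUS_QUALITIES = ("long", "radial")
_AMBIGUOUS_ANATOMY = ("bones",)


def preset(name: str) -> tuple[GenConfig, Lexicons]:
    """(GenConfig, Lexicons) for the named study preset."""
    if name == "paperlike":
        return GenConfig(), DEFAULT_LEXICONS
    if name == "separable":
        cfg = GenConfig(
            mean_spans_per_caption=2.0,
            span_length_target=2.0,
            form_mix=(1.0, 0.0, 0.0, 0.0),
            distractor_rate=0.35,
            abbreviation_rate=0.0,
            hedge_rate=0.0,
            ambiguity_rate=0.0,
        )
        return cfg, DEFAULT_LEXICONS
    if name == "hard":
        cfg = GenConfig(
            mean_spans_per_caption=3.0,
            form_mix=(0.35, 0.25, 0.20, 0.20),
            distractor_rate=0.35,
            abbreviation_rate=0.10,
            hedge_rate=0.20,
            ambiguity_rate=0.25,
        )
        lex = Lexicons(
            anatomy=DEFAULT_LEXICONS.anatomy + _AMBIGUOUS_ANATOMY,
            quality=DEFAULT_LEXICONS.quality + _AMBIGUOUS_QUALITIES,
            metaphor=DEFAULT_LEXICONS.metaphor,
            hedges=DEFAULT_LEXICONS.hedges,
            verbs=DEFAULT_LEXICONS.verbs,
            gerunds=DEFAULT_LEXICONS.gerunds,
            coordinates=DEFAULT_LEXICONS.coordinates,
            abbreviations=DEFAULT_LEXICONS.abbreviations,
            distractor_nouns=DEFAULT_LEXICONS.distractor_nouns,
        )
        return cfg, lex
    raise ValueError(f"unknown preset {name!r} (separable|hard|paperlike)")


# ---------------------------------------------------------------------------
# caption assembly


class _CaptionBuilder:
    """Accumulates tokens and span intervals, then renders text + Caption."""

    def __init__(self) -> None:
        self.tokens: list[str] = []
        self.spans: list[tuple[int, int]] = []

    def add(self, words) -> None:
        self.tokens.extend(words)

    def add_span(self, words) -> None:
        start = len(self.tokens)
        self.tokens.extend(words)
        self.spans.append((start, len(self.tokens)))

    def render(self, caption_id: str) -> Caption:
        parts: list[str] = []
        for tok in self.tokens:
            if tok in {".", ",", ";", ":"} and parts:
                parts[-1] += tok
            else:
                parts.append(tok)
        text = " ".join(parts)
        cap = Caption(
            id=caption_id,
            text=text,
            tokens=tokenize(text),
            gold_spans=[Span(a, b) for a, b in self.spans],
        )
        if cap.token_texts != self.tokens:  # template/tokenizer misalignment
            raise AssertionError(
                f"builder tokens diverge from tokenizer for {text!r}"
            )
        return cap


def _phenotype_phrase(
    form: str, config: GenConfig, lex: Lexicons, rng: np.random.Generator
) -> list[str]:
    """Token list for one phenotype description of the given form."""
    choice = lambda xs: xs[int(rng.integers(len(xs)))]

    def quality_word() -> str:
        if rng.random() < 0.25:
            return choice(lex.metaphor)
        return choice(lex.quality)

    def anatomy_phrase() -> list[str]:
        words = [choice(lex.anatomy)]
        if rng.random() < 0.25:
            words.insert(0, choice(lex.coordinates))
        return words

    if form == "canonical":
        if lex.standalone and rng.random() < 0.08:
            # single-token phenotype noun ("platyspondyly")
            words = [choice(lex.standalone)]
        else:
            words = [quality_word()] + anatomy_phrase()
            if rng.random() < config.hedge_rate:
                words.insert(0, choice(lex.hedges))
    elif form == "verb_linked":
        words = anatomy_phrase() + [choice(lex.verbs)]
        if rng.random() < config.hedge_rate:
            words.append(choice(lex.hedges))
        words.append(quality_word())
        if rng.random() < 0.3:
            words += ["and", quality_word()]
    elif form == "conjunction":
        words = [quality_word(), "and", quality_word()] + anatomy_phrase()
        if rng.random() < 0.5:
            words += ["with", choice(lex.gerunds), "of", "the"] + anatomy_phrase()
    elif form == "nested":
        n_heads = 2 + int(rng.integers(3))  # 2..4 coordinated gerunds
        heads = [choice(lex.gerunds) for _ in range(n_heads)]
        words = [heads[0]]
        for h in heads[1:-1]:
            words += [",", h]
        words += ["and", heads[-1], "of", "the"] + anatomy_phrase()
        if rng.random() < 0.4:
            words += ["particularly", "at", "the"] + anatomy_phrase()
    else:
        raise ValueError(f"unknown form {form!r}")

    if config.abbreviation_rate and rng.random() < config.abbreviation_rate:
        words += ["in", choice(lex.abbreviations)]
    return words[:MAX_SPAN_LEN]


def _distractor_sentence(lex: Lexicons, rng: np.random.Generator) -> list[str]:
    choice = lambda xs: xs[int(rng.integers(len(xs)))]
    noun = choice(lex.distractor_nouns)
    anat = choice(lex.anatomy)
    age = str(int(rng.integers(1, 16)))
    fig = str(int(rng.integers(1, 6)))
    templates = [
        [noun.capitalize(), "of", "the", anat, "at", "age", age, "years", "."],
        ["Figure", fig, "shows", "the", anat, "of", "the", "patient",
         "at", "age", age, "years", "."],
        ["Note", "the", "normal", "appearance", "of", "the", anat, "."],
        ["Anteroposterior", noun, "of", "the", anat, "obtained", "at",
         "age", age, "years", "."],
        ["The", "patient", "was", "examined", "at", "age", age, "years", "."],
        ["Lateral", noun, "of", "the", "same", "patient", "obtained",
         "at", "age", age, "."],
    ]
    return templates[int(rng.integers(len(templates)))]


def generate_caption(
    config: GenConfig,
    lexicons: Lexicons,
    rng: np.random.Generator,
    caption_id: str = "c0001",
) -> tuple[Caption, dict]:
    """One caption plus its bookkeeping record (span count, forms)."""
    builder = _CaptionBuilder()
    record: dict = {"id": caption_id, "forms": [], "n_unannotated": 0}

    if config.distractor_rate >= 1.0:
        n_spans = 0
    else:
        n_spans = min(int(rng.poisson(config.mean_spans_per_caption)), 10)

    # pack spans into sentences of one or two phenotype descriptions
    pheno_sentences: list[list[tuple[str, bool]]] = []
    remaining = n_spans
    while remaining > 0:
        take = 2 if remaining >= 2 and rng.random() < 0.4 else 1
        sentence = []
        for _ in range(take):
            form = FORMS[int(rng.choice(len(FORMS), p=config.form_mix))]
            annotate = rng.random() >= config.ambiguity_rate
            sentence.append((form, annotate))
        pheno_sentences.append(sentence)
        remaining -= take

    n_pheno = len(pheno_sentences)
    r = config.distractor_rate
    if r >= 1.0:
        n_distract = 1 + int(rng.integers(3))
    elif n_pheno == 0:
        n_distract = 1 + int(rng.integers(2))
    else:
        n_distract = int(round(r / (1.0 - r) * n_pheno))

    slots = ["p"] * n_pheno + ["d"] * n_distract
    rng.shuffle(slots)

    pheno_iter = iter(pheno_sentences)
    intros = ([], ["There", "is"], ["Note", "the"], ["The"])
    for slot in slots:
        if slot == "d":
            builder.add(_distractor_sentence(lexicons, rng))
            continue
        sentence = next(pheno_iter)
        builder.add(list(intros[int(rng.integers(len(intros)))]))
        for j, (form, annotate) in enumerate(sentence):
            if j > 0:
                builder.add([",", "and"])
            words = _phenotype_phrase(form, config, lexicons, rng)
            if annotate:
                builder.add_span(words)
                record["forms"].append(form)
            else:
                builder.add(words)
                record["n_unannotated"] += 1
        builder.add(["."])

    caption = builder.render(caption_id)
    record["n_spans"] = len(caption.gold_spans)
    record["n_tokens"] = len(caption.tokens)
    return caption, record


def generate_corpus(
    config: GenConfig, lexicons: Lexicons = DEFAULT_LEXICONS
) -> tuple[Corpus, dict]:
    """A seeded corpus plus the generation ledger.

    The ledger records the configuration and, per caption, the realized
    span count and span forms — the generator's own bookkeeping, usable as
    an exact oracle for corpus statistics.
    """
    rng = np.random.default_rng(config.seed)
    captions = []
    records = []
    for i in range(config.n_captions):
        cap, rec = generate_caption(config, lexicons, rng, f"c{i + 1:05d}")
        captions.append(cap)
        records.append(rec)
    corpus = Corpus(
        captions=captions,
        provenance=f"synthetic corpus (seed={config.seed})",
    )
    ledger = {
        "config": asdict(config),
        "captions": records,
        "totals": {
            "n_captions": len(captions),
            "n_tokens": sum(r["n_tokens"] for r in records),
            "n_spans": sum(r["n_spans"] for r in records),
            "n_unannotated": sum(r["n_unannotated"] for r in records),
        },
    }
    return corpus, ledger


def planted_signal_corpus(
    n_captions: int,
    seed: int,
    n_marker_terms: int = 2000,
    tokens_per_caption: int = 12,
):
    """A corpus whose spans are determined solely by gazetteer membership.

    Marker and filler tokens are drawn from the same random consonant–vowel
    word distribution, and the marker vocabulary is far larger than the
    corpus, so held-out captions mostly contain marker terms never seen in
    training: surface features (affixes, shapes, token identity) cannot
    generalize, while the returned gazetteer identifies every span exactly.
    Each marker occurrence is a single-token gold span.

    Returns ``(corpus, marker_dictionary)`` with the dictionary given as a
    plain set of lowercase terms.
    """
    rng = np.random.default_rng(seed)
    syllables = [c + v for c in "btkmnrsl" for v in "aeiou"]

    def word() -> str:
        n = 2 + int(rng.integers(2))
        return "".join(syllables[int(rng.integers(len(syllables)))]
                       for _ in range(n))

    markers = set()
    while len(markers) < n_marker_terms:
        markers.add(word())
    marker_list = sorted(markers)

    captions = []
    for i in range(n_captions):
        builder = _CaptionBuilder()
        for _ in range(tokens_per_caption):
            if rng.random() < 0.25:
                builder.add_span(
                    [marker_list[int(rng.integers(len(marker_list)))]]
                )
            else:
                w = word()
                while w in markers:
                    w = word()
                builder.add([w])
        builder.add(["."])
        captions.append(builder.render(f"c{i + 1:05d}"))
    corpus = Corpus(captions=captions,
                    provenance=f"planted-signal corpus (seed={seed})")
    return corpus, markers


def generate_preset(
    name: str, n_captions: int, seed: int
) -> tuple[Corpus, dict]:
    """Generate a corpus from a named preset at the given size and seed."""
    cfg, lex = preset(name)
    cfg = GenConfig(**{**asdict(cfg), "n_captions": n_captions, "seed": seed})
    return generate_corpus(cfg, lex)
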