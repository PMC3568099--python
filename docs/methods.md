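# Methods

## Problem and scope

`phenochunk` recognizes *phenotype descriptions* — free-text statements of a
qualitative aspect or abnormality of an anatomical entity, such as
"bell-shaped thorax" or "flattening and squaring of the metacarpal heads" —
in figure-caption-like biomedical text. Recognition is cast as BIO sequence
labeling over tokens (B = first token of a description, I = inside,
O = outside), with a single entity class, so a tagger's output decodes into
token-interval spans. The package covers the full experimental loop:
corpus I/O, feature extraction, four divergent chunker backends, ensemble
aggregation, entity-level evaluation under stratified cross-validation, and
a seeded synthetic corpus generator that stands in for manually annotated
data.

## Tokenization and BIO coding

Tokens are maximal alphanumeric runs with internal hyphens and apostrophes
kept ("bell-shaped" is one token, matching how metaphorical quality terms
behave as single lexical units); every other non-whitespace character is a
one-character token. Character offsets are 0-based half-open, as are token
intervals, so all interval arithmetic is uniform.

Classifier output can be structurally invalid BIO (an `I` with no preceding
`B`/`I`). Decoding therefore first applies a repair rule — such an `I`
becomes `B` — rather than rejecting the sequence. Repair is idempotent and
the encode/decode pair is the identity on valid sequences; both properties
are tested exhaustively on all label sequences up to length 8.

Gold annotation conventions baked into the generator: leading articles stay
outside spans (they carry no phenotype semantics), while the verb that links
an anatomical entity to a quality ("ribs **appear** short") is inside the
span, keeping non-canonical descriptions complete.

## Features

Four families, assembled per token under a declarative `FeatureConfig`:

* **Simple** — character prefixes and suffixes of length 1..`affix_n`
  (default 5, matching the worked examples: "flattening" yields prefixes
  `f fl fla flat flatt` and suffixes `g ng ing ning ening`), plus lemma and
  POS from two providers. The primary provider is a rule-based shallow
  tagger with a fine-grained Penn-style tagset; the secondary is a lookup
  over a bundled word list (a synthetic excerpt standing in for a licensed
  clinical lexicon) with a concise tagset. Absent lookups are encoded by
  the shared sentinel `@`, which deliberately reproduces the coverage-gap
  effect: a feature that maps most tokens to one value has little
  discriminative power.
* **Morphological** — punctuation flag; vowel pattern (consonants → `-`, so
  "flattening" → `--a--e-i--`); digit pattern (digits → `*`, digit-free
  tokens share the standard value `no*`); word shape (uppercase → `A`,
  lowercase → `a`, digit → `0`: "Flattening" → `Aaaaaaaaaa`); brief shape
  (run-length-compressed shape: `Aa`).
* **Dictionary** — case-folded exact unigram membership, one boolean per
  gazetteer. Bundled: four generic lists (ordinals, conjunctions,
  connectives, coordinates) and two domain excerpts (anatomy ~140 terms,
  quality ~110 terms); user-supplied full term dumps load through the same
  one-term-per-line format.
* **Token contexts** — symmetric windows of w tokens on each side
  (w ∈ 1..5). Unigram contexts emit each window position (2w+1 features),
  bigram contexts each adjacent pair fully inside the window (2w), trigram
  contexts each adjacent triple (2w−1); positions beyond the sequence emit
  `<PAD>`. The symmetric-window reading and adjacent-tuple n-grams are
  design choices: they follow standard chunking practice and keep feature
  growth linear in w.

## Chunker backends

All four backends implement one contract (token sequence → BIO labels) and
are deliberately divergent rather than tool-faithful: the goal is an
ensemble of different inductive biases, not score parity with any
particular legacy implementation.

* `crf_a`, `crf_b` — a linear-chain CRF written in this package (numpy +
  scipy): indicator features per (feature-string, label), shared transition
  and initial-state weights, L2-penalized maximum likelihood, batched
  log-space forward–backward, L-BFGS optimization, Viterbi decoding. No
  feature induction; all observed indicators get dense weights. The two
  variants differ in feature preset (`crf_a`: token bigrams with window 3;
  `crf_b`: additionally token unigrams with window 5) and regularization:
  `crf_b` uses a regularization constant of 3.5, mapped to an inverse L2
  penalty (penalty = 1/3.5); the mapping between different CRF tools'
  hyperparameter scales is inexact by nature, and 1.0 is kept for `crf_a`.
* `svm_ovo`, `svm_ova` — greedy left-to-right token classification with a
  degree-2 polynomial kernel SVM, one-vs-one vs one-vs-rest multiclass
  decomposition (scikit-learn). Context windows already live in the
  feature vector; forward parsing is emulated by feeding the previous
  (gold at training time, predicted at inference time) label back as a
  feature. A linear-kernel fallback (`LinearSVC` under the same
  decompositions) exists for corpora where the kernel SVM is impractical;
  the polynomial kernel remains the default.

Determinism: CRF training is deterministic (deterministic optimizer, fixed
feature ordering); SVM backends fix `random_state` from the spec seed.
Models serialize with joblib plus a JSON sidecar recording backend, feature
configuration and seed.

The CRF's L-BFGS iteration cap defaults to 80; on the synthetic presets the
held-out F1 plateaus well before that (by ~40–60 iterations), so
cross-validation at scale runs with a cap of 60.

## Aggregation

Predicted spans across a corpus form sets of exact
`(caption_id, tok_start, tok_end)` triples. Union keeps every outcome from
either classifier (recall can only rise); intersection keeps outcomes
present in both (precision-oriented). Overlapping-but-unequal spans are
distinct set members — "treating results as sets" implies exact identity,
and no merging policy is imposed. Expressions nest arbitrarily
(`(A ∪ B) ∩ (C ∪ D)`).

Majority voting operates token-wise on the four aligned BIO sequences: a
label wins if it has the unique maximum count and at least 50% of the
votes; a tie at the threshold (with four voters, exactly the 2–2 case) goes
to the designated veto owner — read literally, so the veto owner prevails
even when it voted a third label. With four voters and three labels some
label always reaches two votes, so "complete disagreement" cannot occur
token-wise; whether the original ensembles voted on tokens or whole spans
is not recoverable, and token-level voting is this package's documented
choice (the voters are chunkers emitting aligned label sequences). Voted
sequences pass through BIO repair before decoding. The default veto owner
is `crf_a`, the strongest individual backend.

## Evaluation

Scoring is entity-level exact match: a predicted span counts only if its
token boundaries equal a gold span's. Exact match is chosen over partial
credit because boundary completeness is precisely what makes this entity
type hard; a partial-overlap mode exists for diagnostics only. Fold metrics
pool counts over the fold's captions; the cross-validation summary is the
arithmetic mean of per-fold precision/recall/F1 (macro over folds, matching
"average across the folds"; micro-pooling is the obvious alternative and
the counts needed for it are retained in the results).

Folds are stratified on the caption's gold span count (bins 0, 1–2, 3–5,
6+) — the only caption-level structure available: within each bin captions
are shuffled with the seeded RNG and dealt round-robin with a counter that
continues across bins, so fold sizes differ by at most one and each bin is
balanced within one caption across folds. Cross-validation trains every
needed backend once per fold and scores all requested systems (individual
chunkers, set expressions, voting ensembles) from those shared predictions;
a caption-id audit asserts the held-out fold never leaks into training.

Two ablation protocols over a base configuration: *single-feature* (one CV
run per feature unit, enabling only it) and *leave-one-out* (one run per
unit, removing it). Units are the individual simple/morphological features,
each context spec, and the generic/domain gazetteer groups.

## Synthetic corpora

The generator is template-based by design — deterministic, inspectable,
seedable — rather than a language model; each linguistic phenomenon it
emulates is one explicit mechanism. A caption is a shuffled mix of
phenotype-bearing sentences (one or two spans each, with optional
intro/article prefixes kept outside the span) and distractor sentences
(imaging/administrative text). Span templates cover canonical
quality–anatomy pairs (with metaphorical qualities like "bell-shaped"),
verb-linked forms with the verb inside the span, conjunction chains,
nested coordinated gerund forms, single-token phenotype nouns
("platyspondyly"), optional hedges inside the span and abbreviation tails
("in L4-S1"). Span length is capped at 31 tokens.

Default (`paperlike`) parameters target the study corpus profile: ~4 spans
per caption (Poisson), span length averaging ~5 tokens (realized by the
template mix), captions of ~45–50 tokens, 35% distractor sentences, 15%
hedge rate, 8% abbreviation rate. At 1,000 captions the realized means land
within a few percent of these targets and the generation ledger records the
exact per-caption truth.

Two diagnostic presets bracket difficulty:

* `separable` — canonical-only spans drawn from the gazetteer pattern
  "quality term before anatomy term", distractor vocabulary disjoint from
  the quality list, no hedges or ambiguity: the labeling is fully
  determined by visible evidence and any competent backend should approach
  F1 = 1 (the acceptance check uses ≥ 0.95). Captions are deliberately
  short (~20 tokens, 2 spans) — the preset probes separability, not scale.
* `hard` — the full form mix plus two planted difficulties taken from the
  domain's own confusables: tokens like "radial" and "long" occur both in
  phenotype and non-phenotype roles, and 25% of well-formed phenotype
  phrases are left unannotated, emulating the semantic-judgment cases
  ("11 pairs of ribs") that no surface feature resolves. The second
  mechanism makes part of the error irreducible, so F1 on `hard` is
  strictly below `separable` for every backend.

A separate `planted_signal_corpus` builds captions where spans are exactly
the occurrences of terms from a 2,000-word random gazetteer, with filler
drawn from the same consonant–vowel word distribution. Because the marker
vocabulary is much larger than any training split, surface features cannot
generalize to held-out markers while the dictionary feature identifies
them exactly — the controlled setting in which the ablation protocols must
rank the dictionary feature first (single-feature) and last (leave-one-out).

What passing on synthetic data does **not** show: template corpora have a
closed vocabulary, no misspellings, no real syntactic variety, and
distractors far more regular than journal prose. Results on them bound the
machinery's correctness (feature computation, training, aggregation,
scoring), not expected performance on real clinical text, where reported
F1 for this task sits near 70%.

## Problem sizes and numerical choices

* Acceptance-scale cross-validation: 1,000 captions, 10 folds, all four
  backends, linear-kernel fallback for the SVMs, CRF iteration cap 60.
  The acceptance script uses 500 captions and 5 folds per preset — the
  same protocol at the package's chosen reporting size.
* Zero-denominator metrics (no predictions, or no gold spans) report 0 and
  set a `degenerate` flag rather than raising.
* Corpus statistics use exact rational arithmetic (`fractions.Fraction`),
  rounded only at reporting time.
* Stand-off character spans not aligned to token boundaries snap outward to
  the smallest covering token interval, with a logged warning.
* Degenerate single-label training data: the CRF trains normally; the SVM
  taggers fall back to a constant predictor (the kernel machines require
  two classes).

## Known limitations

* The rule-based lemmatizer/tagger is intentionally shallow; its tags are
  features, not linguistic ground truth.
* The SVM chunkers' greedy decoding has no lookahead; a beam or
  Viterbi-over-scores variant could recover some boundary errors.
* Span-level (rather than token-level) voting is unimplemented; the
  package's voting semantics are token-wise by documented choice.
* The anatomy/quality gazetteers are small excerpts; full FMA/PATO dumps
  must be supplied by the user through the dictionary loader.
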