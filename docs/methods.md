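# Methods

## The action model

A synthesis procedure is represented as a *linear* sequence of typed
actions. The vocabulary is a closed set of 28 types: 24 laboratory
operations (`Add`, `CollectLayer`, `Concentrate`, `Degas`, `DrySolid`,
`DrySolution`, `Extract`, `Filter`, `MakeSolution`, `Microwave`,
`Partition`, `PH`, `PhaseSeparation`, `Purify`, `Quench`, `Recrystallize`,
`Reflux`, `SetTemperature`, `Sonicate`, `Stir`, `Triturate`, `Wait`,
`Wash`, `Yield`) and four flags for text that yields no operations
(`FollowOtherProcedure`, `InvalidAction`, `OtherLanguage`, `NoAction`).

Each type admits a fixed property set, frozen in
`synthactions.actions.ALLOWED_PROPERTIES` (schema version 1.0). The table
was reconstructed from the surface forms of published example sequences
and is deliberately conservative; a parse failure against real procedures
should be read as a candidate schema extension, not silently coerced.
Choices worth noting:

- `MakeSolution` requires ≥ 2 materials (a solution is a mixture); a
  one-material "solution" degrades to `Add`.
- Material-taking work-up actions (`Wash`, `Quench`, `DrySolution`,
  `Extract`, `Triturate`, `Recrystallize`, `PH`) admit 0 or 1 material:
  prose frequently omits the reagent ("washed and dried"), and a bare
  action is more faithful than an invented material.
- Repetitions ("washed twice") are a property (`Condition.repetitions`),
  keeping the sequence linear.
- `SLN` is a reserved compound name denoting the product of the most
  recent `MakeSolution`; sequence validation checks the ordering.
- Glassware and apparatus are ignored by design; branched (non-linear)
  workflows are out of scope and surface as `InvalidAction`.

## The action-string representation

`serialize`/`parse` implement a bijective textual form: one line,
clauses joined by `"; "`, each clause an action name followed by a
keyword grammar (`with`/`and`, `over`, `from`, `keep`, `at`, `under`,
`for`, `to pH`, `x N`, `dropwise`). Conventions fixed for bijectivity:

- Canonical output capitalizes type names as in the type definitions;
  parsing is case-insensitive (`ADD` ≡ `Add`). A trailing period is
  accepted on input and never emitted.
- Compound names may contain spaces and parentheses. A parenthesized
  group is a quantity group iff *every* comma-separated part matches a
  number-plus-unit pattern, which keeps `(2,4-dichlorophenyl)` inside
  names.
- Parsing arbitrary text never raises through `try_parse`; failures are
  data (clause index + offending token), which is exactly what the
  validity metric counts.

The bijection is quantified by a property test: 10,000 seeded random
sequences drawn from the allowed-property table round-trip exactly.

## The rule-based extractor

The extractor is deterministic and pattern-based throughout — no trained
tagger — so extraction is reproducible and auditable. Per sentence:

1. **Classification.** Analytical text (NMR/MS/HPLC keywords with no
   operation verb) → `NoAction`; non-English text (no English function
   words or lexicon verbs, or a high non-ASCII ratio; thresholds fixed in
   code) → `OtherLanguage`; cross references ("as described in …") →
   `FollowOtherProcedure`.
2. **Clause analysis.** Operation verbs are located via a lexicon of
   ~50 lemmas with generated inflections, each mapping to a default type
   plus ordered context rules — e.g. *heat*: reflux marker → `Reflux`,
   microwave marker → `Microwave`, duration → `Stir`, otherwise
   `SetTemperature`; *remove*: filtration context → `Filter`, otherwise
   `Concentrate`; *dry*: desiccant over-phrase or solution/layer subject →
   `DrySolution`, otherwise `DrySolid`. The lexicon is user-extensible
   from JSON (`Lexicon.from_json`). Arguments are read from the phrase
   structure around the verb (`with`/`over`/`from`/`between`/`in`
   objects; conditions by the entity patterns of `textproc`).
3. **Implicit actions.** Solution-phrase subjects ("To a suspension of A
   and B in C was added …", "X in Y was heated …") emit `MakeSolution` +
   `Add SLN` first; bare organic/aqueous-layer subjects prepend
   `CollectLayer`; "the X solution was separated" emits `PhaseSeparation`
   + `CollectLayer organic` when X is a known organic solvent.
4. **Post-processing.** A `Filter` with no kept phase followed — possibly
   across sentences — by `Concentrate`/`DrySolution`/`Purify` keeps the
   filtrate. Both addition orders ("To X is added Y" / "Y is added to X")
   produce the same sequence; sentence-initial capitalization is folded
   (orthography, not chemistry).

The extractor is total: every input yields a sequence that validates and
whose serialization re-parses, so the validity of rule-based output is
100% by construction. Unsupported verbs or constructs yield
`InvalidAction` — intentionally, since those samples are later filtered
from pretraining data.

## Corpus construction

Two rule-based sources are combined conservatively: the sentence-level
extractor provides the sequence; a legacy-format adapter (one property
schema for all action types, heat-like records expanded into
`Add` + `Stir`/`SetTemperature`) contributes only its `Yield` actions,
deduplicated by serialized equality. Pretraining filters drop pairs
containing `InvalidAction`, drop `NoAction` pairs whose sentence exceeds
30 characters without an analysis keyword (keyword list frozen in
`extractor.ANALYSIS_KEYWORDS`), then deduplicate sentences after
whitespace normalization (sentence-level, matching the stated rule).
Splits are seed-reproducible and sentence-level: duplicate sentences never
straddle splits.

## Augmentation

Each tagged entity (compound, quantity, duration, temperature) is
independently substituted with probability *p* (default 0.5) by a draw
from its class pool; the identical replacement is applied to the sentence
and the action string, so alignment is preserved by construction. Two
conventions: tags sharing the same surface string share one decision
(otherwise the two sides could not stay aligned), and a substitution must
change the string — the draw excludes the current surface — so the
empirical substitution rate is an unbiased estimate of *p* (verified at
*p* = 0.5 over 10,000 draws within 3 binomial standard errors).
Substitution is not chemistry-aware by design.

## Metrics

- *Validity*: fraction of predictions `try_parse` accepts, computed on raw
  strings before any normalization.
- *Levenshtein similarity*: `1 − d(a,b)/max(|a|,|b|)`, character-level
  (edit distance via edlib; an independent DP oracle backs the tests);
  both strings empty → 1.
- *Threshold accuracies*: fractions of sentences with similarity ≥ 1.0,
  ≥ 0.9, ≥ 0.75; the first is exact sequence accuracy.
- *Adapted BLEU* (artifact convention): corpus BLEU with uniform weights
  and corpus-level brevity penalty, with the n-gram order capped per pair
  at `min(4, |pred|, |ref|)` words so that predictions shorter than four
  words are not automatically zeroed; it reduces to standard BLEU when
  all pairs have ≥ 4 words. Word-level tokenization by whitespace.
- *Confusion ledger*: per sentence, predicted and reference actions are
  aligned by a minimal edit script over action types (ties broken
  preferring matches, then substitutions, then deletions, leftmost-first —
  a fixed convention, since no canonical alignment exists). Matches count
  as type matches, and as full matches when the serialized clauses are
  equal; insertions/deletions count as only-in-prediction /
  only-in-ground-truth; substitutions populate the off-diagonal matrix.
  Conservation holds: reference actions = type matches + substitutions +
  only-in-ground-truth.

## Synthetic fixtures

The generator draws sentences from ~30 templates covering every
laboratory action type, with default frequencies shaped like patent
corpora (addition, stirring and concentration most common;
recrystallization, microwaving and sonication rare). The ground truth is
constructed jointly with the sentence, so it is exact by construction, and
the templates are deliberately inside the extractor's lexicon: the
closed-loop recovery test (≥ 99% exact match on noise-free sentences)
measures extractor correctness, not robustness. A separate `noise` mode
adds out-of-lexicon verbs (ground truth `InvalidAction`) and typos to
exercise the failure paths and to provide imperfect pretraining labels.

What the fixtures do **not** emulate: real chemical nomenclature (names
are syntactic stand-ins), OCR noise, cross-sentence coreference, the long
tail of phrasings in real patents, and non-linear procedures. Passing the
fixture-based tests therefore demonstrates the machinery is correct on
its defined grammar — not that the extractor covers patent text at the
published coverage.

## The translation protocol and its engine

Procedures are translated sentence-by-sentence (cross-sentence facts are
restored by the post-processing step above). The protocol is: build a
shared source/target subword vocabulary from the training set; pretrain on
rule-generated pairs; continue training on annotated pairs with
checkpoints every `checkpoint_every` steps; select the checkpoint with the
highest validation exact-match accuracy (ties → latest step); optionally
ensemble several refined models by averaging per-step token
log-probabilities; decode with beam search returning the n best
candidates with scores. Invalid decodes are mapped to `InvalidAction` by
the pipeline wrapper (`predict_actions`).

The engine behind the train/translate/save/load interface is swappable.
The built-in engine is an autoregressive log-linear model: entity
delexicalization replaces compounds, quantities, durations, temperatures
and yield percentages by indexed placeholder tokens shared by source and
target (the copy mechanism), a BPE vocabulary (character fallback,
placeholders atomic, lossless round-trip on training text) tokenizes both
sides, and a multinomial logistic regression over hashed features of the
target prefix (up to trigrams), position, source unigrams/bigrams and
prefix×source conjunctions predicts the next token. Training is plain SGD
on the categorical cross-entropy with an inverse-square-root learning-rate
decay; 2^14 hashed feature dimensions. `ModelConfig` also records the
reference transformer hyperparameters (4 layers, hidden and embedding
size 256, 8 attention heads, shared vocabulary of 16,000, label smoothing
0, gradient accumulation 4, 500,000 pretraining steps, checkpoints every
1,000) as a preset for a neural engine plugged behind the same interface;
the built-in engine ignores the architecture fields.

Desk-scale defaults (`ModelConfig.desk_scale()`): vocabulary ≤ 300,
2,000 training steps, batch 64, checkpoints every 500 steps — minutes of
CPU time. Problem sizes used by the test suite: the grammar-recovery
experiment trains on 2,000 fixture pairs and evaluates exact sequence
match on 200 held-out pairs (pilot runs reach ~98%; the test requires
≥ 95%); the refinement-ordering experiment pretrains on ~900 pairs
labelled by the rule extractor on noisy sentences and refines on 400
exact pairs, requiring the refined model to be at least as accurate as its
pretrained ancestor on annotated-style data. These experiments show the
protocol works end-to-end and that the fixture grammar is learnable; they
make no claim about accuracy on real patent text.

## Numerical and procedural conventions

- All randomness flows through explicit integer seeds (`random.Random`,
  derived seeds kept below 2^31); corpora, pools, splits, augmentations
  and trained models are bit-reproducible for a given seed.
- BPE merges break count ties lexicographically; beam search breaks score
  ties by token sequence; dataset splitting assigns whole sentence groups
  with largest-remainder rounding of the requested fractions.
- Degenerate inputs: empty procedure → empty sequence; empty prediction
  list → validity 1.0 (vacuous); empty similarity list or empty BLEU
  corpus → error (undefined); `threshold_accuracies` on an empty list →
  error.
- Character offsets are 0-based half-open on the NFKC-normalized,
  whitespace-collapsed sentence; unicode temperature variants (∘, ℃,
  U+2212 minus) are folded before tagging.

## Known limitations

- The allowed-property table and the verb lexicon are reconstructions;
  both are versioned and extensible, and real-procedure coverage will
  require extending them.
- The extractor's grammar analysis is pattern-based; garden-path
  sentences, deeply nested clauses and "until"-style state-dependent
  conditions are not supported (`InvalidAction`).
- The built-in translation engine has no attention over source order
  beyond bigram features; it is adequate for the fixture grammar and for
  exercising the protocol, not a substitute for a full neural model at
  patent scale.
- Duplicate entity surfaces in one sentence share a placeholder/decision,
  which slightly under-counts independent substitution opportunities and
  can confuse decoding when one compound appears in several actions.
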