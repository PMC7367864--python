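# synthactions

Convert free-text experimental procedures for organic synthesis into
structured, machine-readable **action sequences**.

Experimental procedures in patents and papers are written in prose:

> *"23 g of aluminum chloride in 30 mL of dichloroethane was heated to
> 50 °C."*

A bench chemist — or a synthesis robot — needs the same information as an
ordered list of typed operations:

```
MakeSolution with aluminum chloride (23 g) and dichloroethane (30 mL);
Add SLN; SetTemperature 50 °C
```

`synthactions` provides the pieces of that conversion pipeline:

- **Action model** — a closed set of 28 action types (`Add`, `Stir`,
  `Filter`, `MakeSolution`, …, plus four non-laboratory flags such as
  `NoAction` and `InvalidAction`), each with a fixed table of allowed
  properties (materials, temperature, duration, atmosphere, pH, kept
  phase), and validation that reports violations as data.
- **Action strings** — a bijective single-line textual representation
  (`serialize` / `parse` are mutual inverses on the canonical form); this
  is the target language of the translation model, and "validity" of a
  prediction means it parses back into actions.
- **Rule-based extractor** — a deterministic verb-lexicon NLP model that
  maps sentences to action sequences, with context disambiguation ("heat"
  with a duration is `Stir`, without one `SetTemperature`; "remove" with a
  solvent is `Concentrate`) and implicit-action insertion (solution-phrase
  subjects become `MakeSolution` + `Add SLN`; "the organic layer was
  dried…" prepends `CollectLayer organic`).
- **Corpus tools** — an adapter for legacy one-schema action records,
  conservative combination of the two rule-based sources (only `Yield`
  actions are merged in), pretraining filters (drop `InvalidAction` pairs
  and long non-analytical `NoAction` pairs, deduplicate sentences),
  reproducible sentence-level splits, and hard-sentence selection for
  annotation.
- **Augmentation** — entity substitution (compounds, quantities,
  durations, temperatures) at probability *p* per entity, applied
  identically to the sentence and its action string.
- **Metrics** — validity, adapted BLEU (n-gram order capped per pair so
  short predictions are not penalized), character-level Levenshtein
  similarity `1 − d/max(|a|,|b|)`, threshold accuracies (fractions of
  sentences with similarity ≥ 100%/90%/75%), a per-action-type confusion
  ledger, and corpus distribution summaries.
- **Seq2seq protocol** — sentence-wise translation with a shared subword
  (BPE) vocabulary, pretraining on rule-generated pairs, refinement on
  annotated pairs with periodic checkpoints, selection of the
  highest-validation-accuracy checkpoint, beam-search n-best decoding and
  model ensembling, exercised at desk scale on synthetic fixtures.
- **Fixtures** — a seeded grammar that generates patent-style sentences
  *jointly* with their exact ground-truth actions, so correctness can be
  quantified without any proprietary data.

## Worked example

```bash
synthactions demo
```

extracts the bundled worked-example procedure (a reductive amination with
full work-up) and prints:

```
Extracted 16 actions:
   1 MakeSolution with methyl 3-7-amino-2-[(2,4-dichlorophenyl)(hydroxy)methyl]-1H-benzimidazol-1-ylpropanoate (6.00 g, 14.7 mmol) and acetic acid (7.4 mL) and methanol (147 mL)
   2 Add SLN
   3 Add acetaldehyde (4.95 mL, 88.2 mmol) at 0 °C
   4 Wait 30 min
   5 Add sodium acetoxyborohydride (18.7 g, 88.2 mmol)
   ...
  16 Yield title compound (6.30 g, 13.6 mmol, 92%)

Levenshtein similarity vs reference: 100.0%
Exact match with the reference action sequence.
```

The 16 actions are the full machine-readable recipe: make the starting
solution, add reagents with their quantities and temperatures, the two
waiting periods, the quench/concentrate/wash/dry/filter work-up chain
(note the inferred `Filter keep filtrate`), purification and the final
yield. The similarity line is the regression-tracked agreement between the
rule-based extraction and the reference sequence.

From Python:

```python
from synthactions import extract_sentence, serialize

seq = extract_sentence("The organic layer was dried over sodium sulfate.")
print(serialize(seq))   # CollectLayer organic; DrySolution over sodium sulfate
```

A desk-scale end-to-end run (generate fixtures → rule-extract → evaluate):

```bash
synthactions run-pipeline --workdir run/ --seed 7 --n 500
```

writes `report.json` with the metric suite and a `manifest.json` of
content hashes for reproducibility. Training the small translation model:

```bash
synthactions generate-fixtures --n 2000 --seed 7 --out train.tsv
synthactions train --mode pretrain --corpus train.tsv --model-out model.joblib
synthactions translate --model model.joblib --in sentences.txt --out pred.txt --beam 5
```

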