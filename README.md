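# melafish

Scoring and validation pipeline for the four-probe FISH assay used to
classify challenging melanocytic lesions (nevus vs dysplastic nevus vs
melanoma).

Histopathology alone misclassifies a meaningful fraction of melanocytic
lesions. The assay counts fluorescent in situ hybridisation signals for
RREB1 (6p25), CCND1 (11q13), MYB (6q23) and the chromosome-6 centromere
reference (CEP6/D6Z1) in individual nuclei, and calls a specimen positive
when any of four abnormal-nucleus fractions strictly exceeds its cutoff:

```
positive  ⇔  f(RREB1 > 2) > c₁  ∨  f(CCND1 > 2) > c₂
           ∨  f(RREB1 > CEP6) > c₃  ∨  f(MYB < CEP6) > c₄
```

with derived cutoffs (c₁…c₄) = (16%, 19%, 53%, 42%) — preset `table3` —
and the earlier published manual-scoring cutoffs (29%, 38%, 55%, 42%)
available as preset `gerami2009`. The package implements, with tests:

* per-nucleus enumeration rules (QC exclusion, most-abnormal-area
  selection, 3 areas × 10 nuclei, exclusion of specimens with < 20
  evaluable nuclei) and the OR positivity rule on exact rational fractions;
* ROC-based, specificity-first cutoff derivation (per-criterion threshold
  sweep under a specificity floor);
* cohort validation statistics: per-subtype/group positivity with Wilson
  intervals, sensitivity, specificity, atypical positivity rate;
* a seeded synthetic-cohort generator (clonal genotype mixtures, sectioning
  dropout/split noise, area-structured sampling) standing in for slide
  data, since no per-nucleus data are published.

This is a research/teaching reimplementation working from enumerated signal
counts; it ingests no images and is not a clinical device.

## Worked example

```python
import melafish as m

# simulate a 500-case cohort with the default composition
specimens = m.simulate_cohort(m.table1_composition(), seed=1)
calls = m.score_cohort(specimens, m.CUTOFF_PRESETS["table3"], seed=2)
summary = m.summarize_cohort(m.cohort_metadata(specimens), calls)
print(m.sensitivity(summary), m.specificity(summary))
```

prints

```
82.6 98.1
```

i.e. for this seed the pipeline calls 82.6% of the 167 simulated melanomas
positive (the validation study reports 83.8%) and 98.1% of the 157 benign
nevi negative. The same run from the shell, writing all artifacts
(nuclei/calls TSVs, derived cutoffs JSON, ROC table, summary, manifest):

```
melafish full --composition table1 --seed 1 --outdir run1
```

Scoring a pre-enumerated nucleus table instead:

```
melafish score --nuclei nuclei.tsv --specimens specimens.tsv \
               --cutoffs table3 --seed 7 --out-calls calls.tsv
melafish validate --calls calls.tsv --specimens specimens.tsv \
                  --out-summary summary.tsv
```

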