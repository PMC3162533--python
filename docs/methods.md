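# Methods

## The assay

Four FISH probes are co-hybridised to 5 µm sections of melanocytic lesions:
RREB1 (6p25), CCND1 (11q13), MYB (6q23) and the chromosome-6 centromere
reference D6Z1 (here CEP6). Signals are counted per nucleus, and a specimen
is summarised by four abnormal-nucleus fractions:

* f₁ — fraction of nuclei with RREB1 count > 2 (6p25 gain)
* f₂ — fraction with CCND1 count > 2 (11q13 gain)
* f₃ — fraction with RREB1 count strictly greater than CEP6 (locus gain in
  excess of chromosome-6 ploidy)
* f₄ — fraction with MYB count strictly less than CEP6 (relative 6q23 loss)

The specimen is **positive** iff any fᵢ strictly exceeds its cutoff cᵢ.
Every comparison — per-nucleus and per-fraction — is a strict `>` (or `<`
for MYB), and fractions/cutoffs are kept as exact rationals internally, so a
specimen sitting exactly on a cutoff is negative by construction and
boundary behaviour is not at the mercy of floating-point rounding.

Two cutoff presets ship with the package: `table3` = (16%, 19%, 53%, 42%),
the automated-enumeration cutoffs this pipeline reproduces, and
`gerami2009` = (29%, 38%, 55%, 42%), the earlier manually scored published
values. The study text quotes the CCND1 cutoff once as 22% while its cutoff
table prints 19%; the tabulated value is treated as authoritative and the
textual variant is available as the `discussion` preset. Similarly, the
study prose once swaps the dysplastic and melanoma group sizes (167/176);
the tables (dysplastic 176, melanoma 167 — which also match the subtype
sums) are followed throughout.

## Enumeration and selection rules

Scoring mimics the published enumeration protocol:

1. QC-failed (overlapped / poorly hybridised) nuclei are removed first and
   never enter any denominator.
2. Areas are ranked by an **abnormality score** — the fraction of QC-pass
   nuclei satisfying any of the four clauses at the single-nucleus level —
   and the top 3 areas are retained. The protocol says only that the
   "most significant" areas are chosen; re-using the assay's own four
   clauses at nucleus level is the minimal operationalisation consistent
   with it. Ties break lexicographically by area id for reproducibility.
3. Within each retained area 10 nuclei are drawn uniformly without
   replacement (all of them if fewer are available).
4. Specimens yielding fewer than 20 evaluable nuclei are **excluded**: they
   receive no call and leave every denominator.

The selection sizes (3 areas, 10 nuclei, exclusion threshold 20) are
parameters defaulting to the protocol's values.

Nuclei with zero CEP6 signals stay in the denominators of the two
CEP6-relative criteria. The protocol does not address them; dropping them
would silently shrink those denominators relative to the gain criteria, and
a truncated nucleus that lost its reference signal can still legitimately
show RREB1 > CEP6.

## Cutoff derivation

"Maximise specificity over sensitivity" is operationalised per criterion:
sweep a cutoff grid (default step 0.01) and pick the **smallest** grid
cutoff whose single-criterion specificity on the benign set reaches a floor
(default 0.99) — the smallest such cutoff maximises that criterion's
sensitivity subject to the floor. ROC specificity uses `≤` at the cutoff,
mirroring the strict positivity rule. Derivation trains on all benign vs
all melanoma specimens (the study reports no split). The combined OR-rule
sensitivity and specificity at the derived cutoffs are reported alongside;
by the union bound the combined specificity is at least 1 − 4·(1 − floor)
on the training benign set, which the tests check exactly.

## Cohort statistics

Per-subtype and per-group positivity is reported as 100·k/(n − excluded),
rounded **half up** to one decimal in exact arithmetic — this reproduces
printed values such as 6.3% for 2/32, which banker's rounding would print
as 6.2%. Interval estimates are Wilson score intervals (statsmodels).
Sensitivity is the melanoma group's positivity; specificity is the benign
nevus group's negativity — mild-atypia nevi are counted in the benign group,
following the cohort's tabulated grouping rather than the looser "without
atypia" phrasing; the atypical positivity rate pools the moderate- and
severe-atypia rows.

## The synthetic cohort generator

No per-nucleus data are published, so validation runs on a seeded generator
with the statistical structure the assay assumes:

* **Genotypes.** Each specimen either carries one clonal copy-number
  genotype (probability `p_detectable_clone`: melanoma 0.84, dysplastic
  0.09, nevus 0.02 — mirroring the observed 83.8% sensitivity, 9.1%
  dysplastic and 1.9% benign positivity) or is entirely diploid. The
  alteration spectrum contains focal RREB1 gain (4,2,2,2), focal CCND1 gain
  (2,4,2,2), chromosome-6 polysomy (3,2,3,3) — which scales RREB1, MYB and
  CEP6 together and therefore trips RREB1>2 but *not* RREB1>CEP6, exactly
  the distinction the centromere reference exists to make — relative MYB
  loss (2,2,1,2), and a complex genotype (4,4,1,2). Weights
  0.25/0.15/0.20/0.15/0.25 were chosen once so the marginal clause
  prevalences among melanomas approximate the reported per-probe
  sensitivities (~60% RREB1, ~38% CCND1, ~37% MYB); the study gives no
  co-occurrence structure, so the weights are model parameters, not facts.
* **Mixing.** A clone-bearing specimen mixes clonal nuclei into each area
  at a per-area clonal fraction (per-nucleus Bernoulli). The default base
  fraction 0.65 is spread deterministically ±0.15 across the areas of a
  specimen, giving the area-selection step genuine enrichment to find.
  Defaults: 4 areas × 25 nuclei per specimen.
* **Noise.** Observed count = Binomial(true copies, 1 − p_dropout) plus one
  spurious split signal with probability p_split; nuclei fail QC with
  probability p_qc_fail. Defaults 0.10 / 0.02 / 0.05 produce benign
  false-positive nucleus rates low enough that cutoffs on the 16–53% scale
  separate the groups, consistent with the reported 98.1% specificity;
  they are configuration values, not measured quantities.

What the generator does **not** model: spatial structure within areas,
probe-specific hybridisation efficiency differences, tetraploid nuclei and
tetraploidy-rescue scoring, inter-observer area selection variability, and
any subtype-level effect beyond group membership (all nevus subtypes share
one design, so per-subtype positivity differences in synthetic summaries
are sampling noise). Passing calibration tests therefore demonstrates
internal consistency of scoring, derivation and aggregation under the
assumed data-generating process — not performance on real slides.

## Numerical and design choices

* All randomness flows through numpy `SeedSequence` spawning: one stream
  per specimen for generation and scoring, so cohorts and calls are
  bit-reproducible for a fixed seed and stages can be rerun in isolation
  (the CLI derives per-stage seeds from one global seed).
* The calibration check of the whole pipeline runs the default 500-case
  composition over ten seeds: mean sensitivity is required within 5 points
  of 83.8% and every seed's specificity ≥ 95%. With 167 melanomas and
  clone prevalence 0.84, one seed's sensitivity has standard deviation
  ≈ 2.9 points; the mean over ten seeds is the quantity the generator
  pins down.
* The cutoff-recovery check constructs a benign population whose RREB1-gain
  per-nucleus rate is exactly 0.09 with 100 nuclei scored per specimen, so
  the true 99th-percentile specimen fraction is Binom(100, 0.09).ppf(0.99)/100
  = 0.16; the ROC derivation is required to return 0.16 ± 0.02 in ≥ 18/20
  seeds (500 benign + 150 melanoma specimens per seed).
* Degenerate inputs: empty nucleus lists raise (fractions undefined);
  specimens with zero selectable nuclei are excluded; an empty genotype
  spectrum with nonzero clone probability is a configuration error; a
  specificity floor unreachable on the grid is a derivation error naming
  the criterion.

## Known limitations

The generator's group-level parameters are calibrated to the published
summary statistics, so end-to-end agreement with those statistics validates
the scoring/derivation/aggregation machinery rather than providing
independent evidence about the assay. Cutoff derivation offers no
cross-validation or optimism correction (none was performed in the original
design); derived cutoffs are training-set quantities. Subtype-specific
biology (e.g. Spitz nevi's higher positivity) is not modelled.
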