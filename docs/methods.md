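# Methods

This document states the model implemented by `iceffect`, the assumptions it
makes, the parameters it exposes, and the numerical conventions it follows.

## 1. Data model and accounting

**Karyotypes.** The parser accepts the ISCN subset actually occurring in the
cohort: `der(a;b)(q10;q10)` (Robertsonian translocation, 45-chromosome
count), `t(a;b)(...)` (reciprocal translocation), and `inv(a)(...)`
(inversion), with two clauses joined by `/` for a couple in which both
partners carry a rearrangement (classified `compound`, carrier sex `both`).
Anything else (rings, three-way translocations, non-centromeric `der`) is
rejected as unsupported rather than guessed. A `t` between two acrocentric
chromosomes with `q10;q10` breakpoints triggers a warning but keeps its
stated class.

**Excluded chromosomes.** For each case, the union of chromosomes involved
in any of the couple's rearrangements is excluded from all counts.

**Chromosome complements.** Analysis runs over 23 chromosome slots (autosomes
1–22 plus one sex slot; Y maps onto the sex slot). A polar-body sample
(reported as the inferred oocyte equivalent) assesses `23 − k` chromosomes
for `k` excluded chromosomes; a blastomere or trophectoderm sample assesses
`46 − 2k`. These complements, multiplied by per-case sample counts, reproduce
the published per-case chromosome totals exactly (validated on load for all
54 cases; pooled total 10,837).

**Error unit.** One error per aberrant chromosome *label* per sample — the
net per-chromosome-pair copy-number state that array CGH reports — even
though embryo denominators count 46 chromosomes. This convention is forced
by the published tables' arithmetic.

## 2. Matched-control weighting and inference

Each case's control group (same biopsy stage, matched maternal age) is
rescaled to the patient's chromosome count:

```
expected_errors = round_half_up(control_errors / control_chromosomes × patient_chromosomes)
```

computed in exact rational arithmetic (`fractions.Fraction`) so that
half-way cases round deterministically upward (the convention is forced by a
published row where 8/336 × 63 = 1.5 prints as 2). An unrounded mode exists
for sensitivity analysis, since rounding-then-summing differs from
summing-then-rounding by ≈2.4 errors on the full table.

**Test.** The 2×2 table (carrier errors / normal vs pooled expected errors /
expected normal) is tested with the chi-squared statistic with Yates'
correction, clamped at zero: `Σ max(|O−E|−0.5, 0)² / E`, p from the upper
tail of the 1-df chi-squared distribution. The implementation agrees with
`scipy.stats.chi2_contingency(correction=True)` to 6 significant figures on
randomized tables.

**Rates and relative risks** are quoted against the *raw* pooled
control-group rate (errors / chromosomes over the matched groups), not the
weighted-count rate, matching the convention in which the headline figures
(0.051 vs 0.047, +0.4%) are presented; the chi-squared itself runs on the
weighted counts.

**Stratification** groups cases by rearrangement class, biopsy stage, their
cross, and (for Robertsonian cleavage-stage cases) carrier sex. The compound
couple is excluded from stratified inference by default. Strata under a
configurable chromosome count (default 1,000) are flagged under-powered —
this covers the inversion stratum. A sample-level ("embryo-level")
comparison counts a sample abnormal only if a structurally normal chromosome
is aberrant, and reports proportions and their ratio.

**p-values.** The originally printed p-values could not be unambiguously
reconstructed from the aggregate tables; computed p-values are reported, and
no p-value is asserted in tests.

## 3. Synthetic cohort generator

`simulate_cohort(SimConfig, seed)` is deterministic given its seed (single
`numpy` Generator, vectorized draws). Defaults reproduce the study
conditions:

| parameter | default | rationale |
|---|---|---|
| `n_cases` | 54 | study cohort size |
| `stage_mix` | 9/29/16 over PB/blastomere/TE | study stage distribution |
| `stage_rates` | 0.08 / 0.053 / 0.02 | published control stage rates |
| `ice_multiplier` | 1.25 | ≈ published cleavage-stage excess |
| `ice_stages` | {blastomere} | effect detected only at cleavage stage |
| `involved_malseg_rate` | 0.5 | involved chromosomes dominate carrier abnormality |
| `call_accuracy` | 0.94 / 0.98 / 0.95 | published validation accuracies |
| age ramp | logistic, slope 0.25, midpoint 37, anchored at mean age 35.6 | rates rise with maternal age; no per-age data published, so the ramp is a modeling choice |
| `probes_per_chromosome` | 150 | BAC platform density (~3,000 clones genome-wide) |
| `ratio_noise_sd` | 0.1 | keeps caller accuracy ≈ the published 94–98% |
| karyotype pool | packaged study table | cases draw real karyotypes |

Non-involved chromosomes are aberrant independently at
`baseline_rate(stage, age) × ice_multiplier` (carriers, ICE stages) or the
baseline alone (controls and non-ICE stages); involved chromosomes at
`involved_malseg_rate`. Calling error is a symmetric per-chromosome
misclassification channel applied after truth generation.

**Realism and limits.** The generator reproduces the study's marginal
structure (stage mix, rates, matched ages, real karyotypes) but not its
mechanisms: chromosomes malsegregate independently (no meiotic segregation
modes, no mosaicism between biopsied cells, no segmental errors, no
trisomy/monosomy rescue), and the age ramp is smooth rather than estimated.
It is intended for calibration and power experiments, not biological
inference.

**aCGH profiles.** Per chromosome, `probes_per_chromosome` linear ratios are
drawn around class centers 1.0 (expected), 0.5 (net loss), 1.5 (net gain)
with multiplicative lognormal noise `center × exp(N(0, sd))`. The caller
compares the per-chromosome **median** ratio (robust to probe outliers) to
thresholds 0.75/1.25 — the midpoints between class centers — and emits
`NOCALL` below a minimum probe count rather than guessing. The probe-count
default matters: the sample median has log-space standard error
`1.2533·sd/√n`, so at sd 0.1 the "median within 0.05 of its center for ≥99%
of chromosomes" property requires n ≳ 100; at n = 150 the observed rate is
99.96%, and caller accuracy exceeds 99%.

## 4. Numerical and statistical notes

- Weighting uses exact rational arithmetic; `round_half_up` is
  `floor(x + 1/2)` on `Fraction`s, exact for all half-way cases.
- The Yates statistic's clamped correction makes perfectly proportional
  tables give statistic 0, p = 1; a 2×2 with zero errors in both arms (a
  degenerate margin possible in small simulations) is treated as that null
  limit instead of an error.
- **Calibration caveat.** The weighting procedure treats the rescaled
  control count as if it were an observed sample of the patient's size. When
  the control group is much larger than the patient sample — as in the
  study, 204,406 vs 10,837 chromosomes — its rescaled count has lower
  variance than the chi-squared assumes and the test is *conservative*:
  1,000-rep null simulations show rejection rates of 0.011–0.017 at nominal
  α = 0.05 with 2–4× oversized controls, versus 0.051–0.058 with
  matched-size controls. This is a property of the published procedure,
  reported rather than altered; it implies the study's positive findings are
  not inflated by the weighting step.
- Monte-Carlo experiments spawn per-replicate seeds from a
  `numpy.random.SeedSequence` (all below 2³¹); power estimates are
  cross-checked against a closed-form normal-approximation two-proportion
  power formula.

## 5. Known inconsistencies in the source tables

The packaged fixtures transcribe the published tables verbatim. Internal
inconsistencies found while validating (none affects any reported total):

- the cohort description's "20 Robertsonian translocations" vs 19
  Robertsonian events derivable from the patient table (19 + 23 + 3 = 45
  events across 44 couples, one couple carrying two);
- control error counts for three cases are permuted between the control
  table and the weighted table (each table internally consistent; identical
  totals 9,598 and 462);
- the stage-table totals row disagrees with the sum of its own stage rows,
  and its control polar-body errors print 729 vs 730 from the control table
  (rate rounds to 8.0% either way);
- the inversion stratum is described as "528 chromosomes" in prose but sums
  to 374 from the case table.

The pipeline always recomputes from the row-level tables and reports sums.
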