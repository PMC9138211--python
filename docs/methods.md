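# Methods

## Scope and model

The package implements a point-based prediction score (PRIS) for response to
sublingual allergen immunotherapy (SLIT), the outcome indices it is validated
against, and the surrounding statistics. The scientific chain is:

1. **Screening.** Enrolment requires allergic rhinitis, age ≥ 6, controlled
   asthma when asthma is present (ACT at or above a configurable cutoff,
   default 20), no nasal polyposis, no profilin (Bet v2) sensitization, and
   documented positivity on both the skin prick test (wheal ≥ 3 mm, with a
   valid histamine/saline control battery) and specific IgE (≥ 0.35 kUA/L).
2. **Dominance.** Positive sensitizations are ranked by specific IgE
   (ties: wheal, then label). The dominant set is the shortest prefix of the
   ranking whose every member exceeds every non-member by BOTH margins:
   ≥ 5 mm of wheal and ≥ 0.5 log10 of specific IgE. If no prefix separates,
   all positive allergens are co-dominant. The conjunctive reading follows
   the clinical rule as stated ("a difference of wheal diameter … and … half
   a logarithm"); a disjunctive variant would produce smaller dominant sets
   and can be emulated by relaxing one margin to 0 in the thresholds
   registry. "Half a logarithm" is taken as decimal log; natural log would
   make the margin ≈ 1.15× wider on the same scale and has no clinical
   precedent in IgE work, where titres are conventionally log10-spaced.
3. **Scoring.** Eight banded components (age, clinical features, onset,
   sensitization count, symptom-triggering exposures, specific/total IgE
   ratio, CRD band, dominance count) sum to a 20–100 total; bands Q1–Q4 cut
   at 80/60/40. Two inputs the band table does not pin down are resolved as:
   the s/t ratio uses the specific IgE of the highest-sIgE dominant allergen
   (the allergen actually prescribed), and the CRD band is the maximum over
   panel components of the dominant source(s), defaulting to *negative*
   (0 points) when no panel component applies. The clinical-features
   combination "rhinitis + other allergies without asthma" is not tabulated;
   it is scored 6 (the one-comorbidity tier) and flagged in the breakdown's
   notes as extrapolated.
4. **Outcomes.** MSS at a visit is the unweighted mean of all recorded VAS
   items — symptom severity, frequency, exacerbations and on-demand
   medication alike — making it a combined symptom-and-medication score on
   0–100. No weighting scheme is published, and the arithmetic-mean contract
   is invariant to how many items a centre records, though values are not
   comparable across different item inventories. Efficacy is
   ΔMSS-t(%) = (MSS-0 − MSS-t)/MSS-0 × 100, banded at 75/50/25. Group-level
   ΔMSS is the mean of per-patient percentages (not the percentage change of
   group means): the two published group values are mutually consistent only
   under per-patient averaging. Dropouts contribute to baseline tables but
   are excluded from all T12/T24 analyses; nothing is imputed.

## Statistics

* **Power/sample size** for a two-tailed test of zero Pearson correlation
  uses the Fisher z approximation,
  n = ⌈((z₁₋α/₂ + z_power)/atanh(r))² + 3⌉, then steps to the smallest n
  whose analytic power (both rejection tails included) reaches the target.
  For r = 0.3, α = 0.05, power 0.80 this gives n = 85.
* **Simple regression** of ΔMSS-24(%) on PRIS reports R = |correlation| and
  F = R²/(1−R²)·(n−2) on df (1, n−2). With 98 completers the denominator df
  is 96; the validation report carries a note because a df of n−1 is
  sometimes printed for this design elsewhere.
* **Per-parameter regressions** dummy-code each component's observed score
  categories against the lowest-scoring category, with ΔMSS-24 rescaled to a
  0–1 proportion (this is the scale on which category betas of ~0.0–0.2 are
  interpretable); reference rows carry no beta.
* **Repeated-measures one-way ANOVA** over MSS-0/12/24 is the classical
  within-subject sum-of-squares partition, implemented directly (it is three
  lines of algebra) and cross-checked in the tests against an independent
  implementation (pingouin) and a hand SS oracle. Sphericity is uncorrected
  by default (three levels; Greenhouse–Geisser available by flag). Pairwise
  timepoint contrasts are paired t tests, uncorrected by default to match
  how such contrasts are conventionally quoted, with Bonferroni available.
* **Between-band one-way ANOVA** of ΔMSS-24 across PRIS bands uses scipy's
  F test with Tukey HSD post-hoc by default (Bonferroni optional); the
  published analysis names post-hoc comparisons without a method.

## Synthetic cohort generator

The generator emulates the validation study's population: n = 110 by
default, truncated-normal age on [6, 63] calibrated so the emitted integer
ages average 24.87 (SD 10.80), 61.8% male, 50% concomitant (controlled)
asthma, 10.9% dropout, baseline MSS 80.97 ± 8.24, and an allergen mix with
the marginal frequencies of the allergens actually prescribed in that cohort
(wall pellitory : grasses : house dust mite : mugwort : olive : molds ≈
69 : 47 : 19 : 4 : 4 : 1, plus a 0.5 floor weight for tested-but-never-
prescribed sources).

Each patient is drawn in two passes. Pass one samples one category per score
parameter — distributions chosen once to represent a mixed mono-/
poly-sensitized SLIT referral population (e.g. 30% monosensitized, 64% with
a single dominant allergen, consistent with the ~2:1 mono- vs two-allergen
SLIT split of the study) — and then realizes raw measurements consistent
with the draw: dominant allergens sit at wheal 8–11 mm and within 0.2 log10
of each other in specific IgE (so no internal split can separate them),
non-dominant ones at 3 mm and ≥ 0.7 log10 lower (so the boundary always
separates); total IgE is back-solved from the sampled s/t band; a major
molecular component of the first dominant source carries the sampled CRD
band. Infeasible categories (onset band exceeding age, dominance or exposure
count exceeding the sensitization count) are removed before sampling and the
remaining probabilities renormalized, so recomputing the score from the raw
fields reproduces the sampled categories exactly (the test suite requires
≥ 99%).

Pass two draws the response: ΔMSS-24(%) = a + b·PRIS + ε with ε ~ N(0, σ),
clipped to [−25, 100] (clip events logged); ΔMSS-12 lags ΔMSS-24 by
N(gap_mean, gap_sd). VAS items are back-solved from the latent response with
all items equal at a visit — the analyses consume only MSS summaries, so
item-level texture would add parameters without adding information.
`calibrate_link` solves (a, b) from the Monte-Carlo mean and SD of the PRIS
total under the configured category distributions:
b = (σ/σ_PRIS)·r/√(1−r²) yields latent population correlation r, and the
intercept centres the mean response. Defaults target r = 0.62 and a mean
ΔMSS-24 of 67.71%; σ = 14 was back-derived so the total ΔMSS-24 SD (≈ 18
percentage points) matches the dispersion implied by the study's printed
MSS-24 SD, and gap defaults (6.36 ± 20) match its printed ΔMSS-12/24 means
and the near-threshold T12-vs-T24 contrast. Clipping attenuates the
realized correlation slightly below the latent target (by < 0.01 at the
defaults), so tests that need the true population value estimate it from a
single large generated cohort rather than assuming the latent target.

What the generator does **not** emulate: seasonal symptom dynamics, product
differences between SLIT preparations, correlations between score
parameters (age and onset are sampled independently apart from feasibility),
informative dropout (a hook exists via configuration but defaults off), and
item-level VAS heterogeneity. Passing tests therefore demonstrate the
correctness and calibration of the scoring/analysis machinery under the
stated population model, not the clinical validity of the score on new
patients.

## Numerical choices and degenerate inputs

* Specific IgE is floored at 0.01 kUA/L before logs, keeping dominance
  margins finite for untested/undetectable allergens (below any assay's
  reporting range).
* Tie-breaking in the dominance ranking (wheal, then label) makes results
  permutation-invariant; scaling all sIgE by a positive constant leaves the
  dominant set unchanged.
* Printed-table percentages round half-up at the printed precision.
* Zero baseline MSS makes relative change undefined and is rejected rather
  than coerced; constant predictors, single-category parameters and missing
  within-subject cells raise typed errors instead of producing NaNs.
* All clinical cutoffs (3 mm, 0.35, 3.50, 0.05/0.2, 5 mm, 0.5 log, ACT 20)
  live in one overridable, logged thresholds registry.

## Problem sizes

The default test run simulates cohorts of 98–110 patients (200 seeds for the
calibration/pattern checks, a single 50,000-patient cohort as the population
reference, 5,000 for moment checks), 20,000 replicates for Monte-Carlo
power, and 10,000 null replicates per ANOVA for type-I-error calibration;
the whole suite completes in well under a minute on a single core.

## Known limitations

* The score's point values are implemented verbatim and never re-fitted;
  the package deliberately offers no calibration or learning.
* Only the Bet v2 profilin exclusion is modelled; broader cross-reactivity
  (CCDs, other profilins, PR-10 networks) is out of scope.
* The VAS item inventory is configurable but single-centre conventions
  (frequency as one global item, etc.) are assumed rather than enforced.
* The fourth PRIS band (score < 40) is reachable in principle (floor 20) but
  rare under realistic category mixes; analyses handle its absence.
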