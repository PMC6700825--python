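# Methods

## The screening model

The package implements the Bayesian likelihood-ratio risk calculation that
underlies first-trimester combined screening (the same scheme used for
aneuploidy screening). Early PE (delivery < 34 weeks) and late PE
(delivery ≥ 34 weeks) are treated as two fully independent binary problems —
there is no competing-risks or survival formulation; each horizon gets its
own prior, its own marker Gaussians, and its own posterior.

**Prior.** Baseline odds per horizon are multiplied by one positive
likelihood ratio per maternal factor: BMI band (< 25 / 25–30 / ≥ 30 kg/m²),
ethnicity, parity, history of PE, and chronic hypertension. Reference
levels carry LR 1. BMI is banded rather than continuous; a continuous
log-linear prior could be substituted through the same `PriorModel`
interface. The shipped baseline risks (0.12% early, 0.7% late) and LR table
are *placeholders*: the vendor's actual values are unpublished, so ours are
set to epidemiologically plausible magnitudes and scaled so the default
synthetic cohort's mean prior is near the study incidence (0.24% early,
1.07% late, 1.31% overall). Any serious use should refit them.

**MoM.** Expected medians are log-linear in gestational age in *days*
(`log₁₀ median = a + b·GA`); MoM = level / median. PLGF and PAPP-A MoMs are
divided by a covariate factor `10^(w·(weight−53)) · f_ethnicity · f_smoking`;
MAP MoM is GA-adjusted only, mirroring the restriction of covariate
adjustment to the serum markers in the source protocol. Whether MAP should
use a GA regression at all is not documented by the vendor; we ship slope 0
(a population constant) with the regression available by config. Adjusted
log₁₀ MoM values are truncated to [−1, +1] to keep likelihood ratios from
single outliers bounded; the truncation flag is carried through.

**Marker likelihood.** Under each hypothesis the triple
(log₁₀ MoM MAP, PLGF, PAPP-A) is multivariate normal. The LR is a ratio of
densities evaluated in log space via Cholesky factorization; log-LRs are
clipped to ±700 before exponentiation so ratios stay positive and finite in
double precision even for extreme inputs or near-degenerate fitted
covariances. Fitting is group-wise sample means and covariances, with
`pooled` and `diagonal` covariance modes available (it is unknown whether
the vendor uses horizon-specific covariances); a singular fitted covariance
falls back to its diagonal with a warning.

**Posterior.** `odds_post = odds_prior × LR`, converted back to a
probability. "1 in N" uses N = round(1/p) (minimum 1); the screen-positive
rule at cutoff "1:N" is `p ≥ 1/N` — cutoffs are read as probabilities, not
odds, and the boundary is inclusive, the aneuploidy-screening convention.
Both choices are configurable.

## Blood-pressure protocol

MAP per reading is (systolic + 2·diastolic)/3. Each arm's MAP is the mean
of the *last two* readings; the pair is stable when consecutive readings
differ by ≤ 10 mmHg systolic and ≤ 6 mmHg diastolic. The final MAP is the
higher arm. Two interpretations of "last two stable measurements" exist
(last two readings of a stabilized series vs the last stable pair anywhere);
we implement the former, because measurement continues *until* stability, so
recorded series are assumed to end at the stable pair. If the final pair is
nevertheless unstable we compute anyway and flag `stable=False` rather than
error — analysis datasets contain only final series, and discarding them
would silently bias a cohort. Averaging per-reading MAPs equals taking MAP
of averaged pressures (linearity); we average per-reading MAPs.

## Outcome rules

PE: hypertension onset after 20 completed weeks plus proteinuria, early/late
split at delivery before/at-or-after 34.0 weeks (the 34.0 boundary is late).
Onset ≤ 20 weeks is chronic hypertension, classified non-PE with a warning.
The ≥ 2-occasions-4-hours-apart clause is treated as adjudicated upstream:
the cohort schema stores summary fields (onset GA, proteinuria flag), not
visit-level records. SGA: birth weight strictly below the 10th percentile
for GA at delivery, linearly interpolated between weekly rows of a
configurable two-column table. The shipped default table is a smooth
synthetic sex-agnostic curve, because the national reference chart is an
external publication; it is swappable via `PercentileTable.from_csv`.

## The synthetic-cohort generator

The generator emulates the structure of the source cohort, not any
individual-level data:

* **Outcome flow** (fixed-count mode, the default): 3,270 pregnancies with
  exactly 8 early PE (5 SGA), 35 late PE (10 SGA), 84 SGA without PE.
  A probabilistic mode draws group labels with the same expected fractions.
* **Markers**: per-group log₁₀ MoM Gaussians with means = log₁₀ of the
  published group medians and SDs from the published IQRs via
  σ = log₁₀(q3/q1)/1.349 (normal quartile spacing). Early- and late-PE rows
  use their own published distributions regardless of SGA status (the
  early×SGA cross-tabulated marker distributions are not published, and the
  PE-with-SGA row pools horizons). Marker correlations are not published,
  so default covariances are diagonal, with an optional per-group
  correlation block in the config — honesty about an unavailable parameter
  rather than an invented one.
* **Mixture calibration**: the published "unaffected by PE" row is itself a
  mixture of 3,143 truly unaffected and 84 SGA-without-PE pregnancies. The
  bulk-unaffected means are therefore solved (one normal-quantile equation
  per marker, at config-construction time) so that the *mixture* median
  reproduces the published row median; the adjustment is ≈ 0.002 in log₁₀.
* **Closure**: concentrations are back-computed through the shipped median
  model and covariate factors, so the MoM engine recovers the drawn MoMs to
  machine precision; BP series are synthesized (stable final pair straddling
  the target symmetrically, a discarded settling reading, the second arm
  0.5–4 mmHg lower) so the protocol module recovers the intended final MAP;
  outcome fields are written so the PE rule reproduces the group labels and
  birth weights respect the percentile chart on the correct side of p10.
* **Characteristics**: weights lognormal and heights normal from the
  published medians/IQRs with the published PE-group shifts (higher weight
  and BMI, 18.6% vs 0.6% chronic hypertension); smoking 0.06%; IVF 1%;
  everyone ethnicity "chinese". Parity and PE-history rates are not
  published; we use 55% nulliparous (70% in PE) and 1% (15%) prior PE among
  parous women, typical of an urban Chinese screening population.

What passing tests on this generator shows: that the pipeline's arithmetic,
fitting and evaluation machinery are correct and self-consistent under the
published group distributions. What it does not show: performance on real
pregnancies — real marker distributions are not exactly lognormal, markers
are correlated, and the early-PE row's IQRs come from n = 8 and are noisy
(the config uses them verbatim; treat early-PE σ values as fragile).
Detection rates measured on the generator therefore validate the method
under the published summary statistics, not the clinical claim itself.

## Evaluation statistics

* AUC = Mann–Whitney concordant-pair probability (ties ½), with DeLong
  variance for the CI; prior-vs-posterior AUCs compared by paired DeLong
  (no Python package in the stack implements the paired test, so it is
  implemented here and checked against its defining properties and
  brute-force pair counting). A bootstrap alternative was considered and
  dropped: DeLong is deterministic and standard.
* Optimal cutoff: threshold maximizing (sensitivity + specificity)/2, ties
  broken toward lower FPR.
* Fixed-FPR operating points: the smallest score threshold whose empirical
  FPR does not exceed the target (no interpolation — reproducible on finite
  cohorts); DR is the affected fraction at or above it, PPV = TP/(TP+FP).
  In the subgroup report the threshold per horizon is set once on the
  pregnancies unaffected by *both* PE and SGA, and that pool also supplies
  the FP count for PPV (the published table does not define its PPV
  denominator; this is our reading, stated here so it can be changed
  knowingly). Thresholds are also reported as "1:N" cutoffs via
  N = round(1/threshold).
* Binomial CIs: exact Clopper–Pearson via beta quantiles, chosen because it
  reproduces the published intervals digit-for-digit (7/8 → 47.35–99.68%,
  5/5 → 47.82–100%).
* Mann–Whitney group comparisons: exact enumeration when n₁·n₂ ≤ 400 and no
  ties, tie-corrected normal approximation otherwise.

## Problem sizes and seeds

Unit tests run on a proportionally scaled cohort of 800 pregnancies; the
study-flow, calibration and detection-rate checks use the full 3,270 or an
enriched case–control design of 2,000 early-PE + 20,000 unaffected
pregnancies per cohort (an independent train/test pair), sizes at which the
DR at 10% FPR has a Monte-Carlo SD of well under one percentage point.
Every random stage takes an explicit integer seed; a (config, seed) pair
reproduces cohort files and reports byte-for-byte.

## Known limitations

* Prior-model LRs and median-model slopes are placeholders (see above);
  absolute prior risks should not be interpreted clinically.
* No uterine-artery Doppler (UtA-PI) term — the source protocol did not
  measure it.
* The generator assigns SGA labels jointly with the outcome flow rather
  than emerging from a fetal-growth mechanism; non-PE non-SGA deliveries
  are floored at 34 weeks, so isolated non-SGA preterm birth is absent.
* Recorded-risk spreadsheets are read from .xlsx/.csv only (no legacy .xls
  reader in the dependency set).
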