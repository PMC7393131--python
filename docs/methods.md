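# Methods

This note documents the models, conventions and numerical choices behind
`radiometab`, what the synthetic-data generators do and do not emulate,
and the known limitations.

## Radiosensitivity from clonogenic assays

A clonogenic assay plates a known number of cells per dish, irradiates at
graded doses, and counts the colonies that grow out. The plating
efficiency PE is the mean of colonies/cells-plated over unirradiated
(0 Gy) replicates; the surviving fraction at dose d is the mean
colonies/cells-plated at d divided by PE, so SF(0) = 1 by construction.
Doses at which every replicate yields zero colonies are reported missing
rather than zero, because the fit operates on log survival.

**Linear-quadratic fit.** SF(d) = exp(−(αd + βd²)) with α ≥ 0 (1/Gy) and
β ≥ 0 (1/Gy²) is the standard parameterization of radiation
cell-survival curves. We fit by least squares of ln SF against
−(αd + βd²) under the non-negativity constraints (non-negative least
squares on the design [d, d²]), which is simple, convex and exactly
reproducible. The fit is unweighted by default; optional per-dose weights
are supported, and for Poisson-distributed colony counts the natural
choice is the total colony count per dose, which is proportional to the
inverse variance of ln SF. Even so, α and β are strongly collinear on
a 0–8 Gy grid with a 2 Gy step, so single-assay α estimates carry
substantial variance (see "Recovery experiments" below); ≥3 distinct
positive doses are required, and fewer raise an error.

**Mean inactivating dose (Dmid).** Dmid is the area under the survival
curve on a *linear* SF axis, a model-light scalar summary of
radioresistance: larger Dmid means more dose is needed, on average, to
inactivate a cell. Two estimators are provided: `fitted` integrates the
LQ curve by adaptive quadrature (absolute tolerance 1e−8) over
[0, dose_max], and `trapezoid` integrates the measured SF points without
any model. The default integration limit is the maximum assayed dose
(8 Gy in the assay designs this package targets); the run manifest
records which estimator and limit were used. The two estimators agree to
within the trapezoid rule's O(h²) discretization error — about 2.6% at a
2 Gy dose spacing for typical GBM-like curvature, well under 1% at 1 Gy.

**Enhancement ratio.** ER = Dmid(control)/Dmid(treatment) computed over
the same dose range; ER > 1 is radiosensitization, ER < 1
radioprotection, and |ER − 1| ≤ 1e−6 is reported "neutral". For
viability-based assays (neurosphere lines are not amenable to clonogenic
assays) the same ratio is formed from GI50 values: the dose at which
viability crosses 50% of the unirradiated value, located by linear
interpolation between bracketing measured doses. Interpolation (rather
than a four-parameter logistic) is assumption-free and exactly testable;
no extrapolation is performed — a curve that never reaches 50% raises an
error instead of guessing.

## Metabolite panel QC and preprocessing

Quantified peak-area tables (metabolite × sample, with cell line,
condition and replicate annotations) are filtered per replicate group
(metabolite × cell line × condition): a group is set missing when its
replicate mean falls below 3000 ion counts (detection threshold) or its
coefficient of variation sd/mean exceeds 0.5. The CV uses the sample
standard deviation (denominator n−1). The threshold applies to the group
mean, treating it as a detection limit: a group either passes whole or
is wholly missing. A metabolite missing in more than half of its groups
(configurable) is dropped entirely. Every removal is listed in a QC
report with its reason. The filter is idempotent.

Per-sample normalization is off by default because the appropriate basis
(cell number, protein, total ion current) depends on the experiment;
`total_signal`, `median` and `reference_sample` options are provided and
the factors used are always recorded.

Post-irradiation fold changes are ratios of replicate means
(treated/control) per metabolite per cell line, with group averages
(e.g. radioresistant vs radiosensitive line pairs) taken as arithmetic
means of per-line fold changes. Control means ≤ 0 yield missing values;
a line missing either condition is a pairing error, not a silent drop.

Stable-isotope fractional enrichment is the summed area of isotopologues
M+1 and above over the total isotopologue area, per metabolite. No
natural-abundance correction is applied — the values are raw labeled
fractions, appropriate for qualitative statements ("about half the pool
labels") rather than precise flux estimates.

## Pathway regulation scoring and sensitivity correlation

Metabolite levels (replicate means per cell line by default) are
z-transformed per metabolite across cell lines: z = (x − mean)/sd with
the sample sd. Zero-variance metabolites are excluded with a warning,
never emitted as z = 0 (which would silently dilute pathway scores).
Missing values are handled pairwise-complete, with the effective n
recorded. Metabolites with z strictly below −1 are called
down-regulated, strictly above +1 up-regulated; values exactly at the
boundary are "none" (the thresholds are read strictly as "below"/
"above"). Both thresholds live in the run configuration.

For each pathway and cell line, the down (up) score is the number of the
pathway's measured metabolites called down (up) divided by the number
measured — after QC and variance filtering, so n_measured varies by line
when values are missing. Pathway membership comes from a user-supplied
single-membership table; a metabolite mapped to two pathways is an
error, and unmapped metabolites are excluded with a count logged.

Each pathway's score vector is Pearson-correlated with the
radiosensitivity score. We store radioresistance as Dmid and define
sensitivity as −Dmid; correlations are reported against the sensitivity
orientation, so a *positive* r for a down-score means the pathway is
depleted in radiosensitive lines. The orientation is recorded with every
result. Two-sided p-values come from t = r·√((n−2)/(1−r²)) on n−2
degrees of freedom; |r| = 1 returns p = 0. Down and up scores are
corrected as separate Benjamini–Hochberg families (the down direction is
the usual reporting direction), and a pathway is flagged significant
when p < 0.05 and q < 0.1 (both configurable). Zero-variance score
vectors are reported with missing r and do not enter the BH family.

The post-irradiation variant applies the same chain to log2 fold
changes. Standardizing log fold changes (not raw ratios) treats up- and
down-regulation symmetrically; this is a deliberate choice where raw
ratios would skew the z distribution. With very few analysis units the
±1 threshold has hard geometric limits — a clean 2-vs-2 split among four
units peaks at |z| = 0.866 and can never fire a call — so per-line
(rather than per-replicate) analyses of four-line designs mostly detect
single-line excursions. Both units of analysis (cell-line means, or
individual replicates) are supported via `unit_of_analysis`.

## Statistical core

All named procedures are implemented from their defining formulas so
that oracle equivalence is testable; scipy supplies only distribution
tail functions, and reference libraries (lifelines, statsmodels) appear
in the test suite as additional cross-checks, never as the
implementation.

Conventions chosen where the procedures' common descriptions are silent:

* t-test: pooled-variance Student test by default; Welch available.
  Constant equal groups return p = 1 and are flagged degenerate.
* Holm–Šidák: step-down 1 − (1 − p_(i))^(m−i+1) with enforced
  monotonicity; BH: step-up min over j ≥ i of p_(j)·m/j, capped at 1.
* Kaplan–Meier: at tied times, events precede censorings in the risk
  set. The median is the smallest event time with S(t) ≤ 0.5 ("not
  reached" when the curve never falls that far), matching common
  survival software.
* Log-rank: two-sample Mantel–Cox χ² with the hypergeometric variance;
  zero events overall returns p = 1 with a degeneracy flag.
* Cox: univariate, binary covariate, Breslow tie handling, Newton
  iteration (tolerance 1e−8, max 50 steps, damped steps), Wald 95% CI
  from the observed information. Monotone partial likelihood (complete
  separation of event orderings) raises an error with a diagnostic
  rather than returning a huge finite estimate.

## In-vivo and clinical endpoints

Caliper volume is (π/6)·L·W² in mm³; reversed length/width inputs are
swapped (the formula squares the smaller axis). Growth series are
normalized to 100% at the first measured day, which is treated as the
first day of treatment (animals are typically randomized when tumors
reach ~80–100 mm³ and measurement starts then). Tumor tripling time is
the earliest *measured* day at which the volume is at least 3× the
baseline — the inclusive boundary counts, and no interpolation between
measurement days is performed, because the endpoint is defined on
observed days. Animals that never triple are censored at their last
measured day; censoring (rather than exclusion) keeps slow-growing
tumors in the analysis. Bioluminescence series support
last-observation-carried-forward imputation after euthanization; LOCF
never alters an observed value and flags every imputed point.

Tripling records and survival tables feed the same arm-level analysis:
per-arm KM medians and all pairwise log-rank tests. Expression cohorts
are stratified at the median: the high group is expression *strictly
above* the median (ties go low), then KM curves, the log-rank p and the
univariate Cox hazard ratio for high vs low are reported together.

## Synthetic data generators

Every generator is a pure function of its parameters and seed, and its
output validates against the same schemas the readers enforce.

**Metabolite panel.** Per-line Dmid is drawn uniformly on 1.5–5.5 Gy
(spanning sensitive to resistant GBM lines) and standardized to z_D.
Each metabolite of the coupled pathway receives per-line log-scale mean
r_true·z_D + √(1−r_true²)·ε with independent unit-normal ε, so each
coupled metabolite's population correlation with Dmid is r_true (the
pathway mean correlates more strongly, since the independent ε average
out). All other metabolites are independent unit-normal noise on the log
scale. The between-line structure is scaled by 0.4 on the natural-log
scale (~50% between-line CV, realistic for targeted panels; much larger
values make raw intensities so right-skewed that z < −1 becomes
unreachable and down-calls impossible), replicates add lognormal
measurement noise of sd 0.25 (~25% replicate CV, comfortably inside the
0.5 CV QC gate), and everything is exponentiated around a base intensity
of 1e5 ion counts. The default panel has six pathways (guanylates,
adenylates, inosinates, cytidine, glutathione, nucleotide sugar) with
3–6 synthetic metabolites each, 23 lines, triplicates.

What the generator does *not* emulate: correlated noise between
pathways, batch effects, heteroscedastic detector noise,
missing-not-at-random dropout, or skewed Dmid distributions. Passing
recovery tests therefore demonstrates the statistical machinery is
correct and well calibrated under the assumed structure, not that real
panels will show couplings this clean.

**Clonogenic assay.** colonies ~ Poisson(cells·PE·SF_LQ(d)) per
replicate, truncated at cells plated; defaults 500 cells, PE 0.5,
triplicates, doses 0–8 Gy in 2 Gy steps, matching common assay designs.

**Growth cohort.** V(t) = baseline·exp(rate·(t−t₀))·lognormal noise
(sd 0.1) per animal per scheduled day, measured three times weekly from
~90 mm³. Default arms: control tripling in ~11 days, with single
treatments slowing growth by 1.4–2× and the combination by 3×.

**Survival cohort.** Exponential event times with a group hazard ratio
(default baseline median 42 days, HR 0.6 for the indexed group) and
administrative censoring. Optionally an expression covariate is attached
so that the hazard-ratio group is the high-expression stratum, making
the median-split analysis recover the generated HR.

## Recovery experiments and problem sizes

The acceptance suite (tests/test_acceptance.py, scripts/acceptance.py)
uses these problem sizes, chosen to match the study designs the package
targets while keeping a desktop run in minutes:

* oracle equivalence on 200 random small panels (≤10 lines, ≤5 pathways),
  against pure-Python brute-force implementations, tolerance 1e−9;
* null calibration on 1000 global-null panels of 23 lines × 30 pathways
  (observed pathway-level type-I rate ≈ 0.05; BH at 0.1 controls the
  empirical FDR);
* coupling recovery over 100 seeds at r_true = 0.8, n = 23 (the coupled
  pathway ranks first by |r| with q < 0.1 in ≈97% of seeds);
* LQ α recovery over 100 Poisson assays at 500 cells plated. Note the
  information limit: with PE 0.5, triplicates and doses {2,4,6,8} Gy the
  Cramér–Rao bound alone implies a median absolute relative error of
  ≈13% for α = 0.2, so single-assay α estimates are reported with that
  caveat; the count-weighted fit approaches the bound (~15% observed);
* Cox HR recovery over 500 cohorts of 208 subjects at HR 0.6 (mean
  estimate within 0.6 ± 0.05, ~95% CI coverage), and the exponential
  KM median against ln 2/λ at n = 500.

## Known limitations

* The LQ model is the only survival-curve parameterization offered; no
  single-hit multi-target or universal-survival-curve models.
* GI50 requires the viability curve to cross 50% within the assayed
  range; steep-shouldered curves measured on coarse dose grids will
  interpolate linearly across the shoulder.
* The Cox implementation is univariate with a binary covariate — by
  design, for median-split analyses; no multivariable adjustment,
  stratification or competing risks.
* Pathway scores are thresholded fractions; they discard effect
  magnitude by construction, which costs power relative to continuous
  pathway means but matches the intended analysis definition.
* The pipeline assumes single-membership pathway annotation; metabolites
  shared between pathways must be resolved upstream.
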