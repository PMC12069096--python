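# Methods

This note documents the statistical models, the synthetic study conditions,
the numerical choices, and the known limitations of `hgpintake`.

## 1. Censored concentrations and exposure scenarios

Residue assays report a concentration only when it exceeds the analyte's
limit of detection (LOD); below it the observation is left-censored. The
package substitutes LOD/√2 for every non-detect before computing any
distribution statistic — the standard single-value substitution for
moderately censored data. Analytes are retained only when detected in at
least ten samples overall; below that, a distribution estimate would be
almost entirely imputation.

Per analyte and tissue class (separated subcutaneous fat vs "non-fat":
muscle, ground composite, organs), the mean, 95th percentile and maximum of
the detected-plus-imputed sample define the *typical*, *high* and *max*
concentration scenarios. Because mean ≤ P95 ≤ max holds for any sample,
scenario intakes are monotone by construction, which the tests verify on
every synthetic person-day.

Fat vs adjacent-meat differences are screened with a Wilcoxon matched-pairs
signed-rank test. For ≤ 12 non-zero differences the two-sided p-value is
exact: the null distribution of the positive-rank sum is enumerated over
all 2^n sign assignments (midranks under ties); beyond that a normal
approximation with continuity and tie corrections is used. Zero differences
are dropped before ranking.

## 2. Recall disaggregation and single-day intake

Foods are mapped to ingredient recipes (weight fractions summing to one);
an ingredient is beef iff its description contains the substring "beef",
case-insensitively, with no exclusion list. Cooked grams divide by a single
moisture adjustment factor of 0.75 (25% cooking water loss) to give raw
grams, which split into fat and non-fat mass by the ingredient's
nutrient-label fat proportion. Each mass picks up its tissue-class scenario
concentration; summing over ingredients and dividing by 1000 × bodyweight
yields µg HGP per kg bodyweight per day (g × pg/mg ÷ 1000 = µg). The
implementation is vectorized; an explicit per-ingredient loop oracle checks
it to 10⁻⁹ relative on every synthetic person-day.

## 3. The two-part usual-intake model

Daily intake of an episodically consumed food is zero on most days, so the
long-run mean is modelled in two correlated parts for person *i*, day *j*:

* probability: `logit P(R_ij > 0 | i) = x'_ij β₁ + u_1i`
* amount:      `g(R_ij; λ)             = x'_ij β₂ + u_2i + ε_ij`, `R_ij > 0`

with `g(x; λ) = (x^λ − 1)/λ` the Box-Cox transform, `ε_ij ~ N(0, σ²)`, and
`(u_1i, u_2i)` bivariate normal with variances `σ²_u1`, `σ²_u2` and
correlation ρ — people who eat beef more often also tend to eat more per
occasion. Children (1–19) and adults (20+) are always fitted separately.
The fixed-effect basis is identical in both parts: gender, continuous age,
a linear age spline (knot at 11 for children; 29, 39, 49, 59, 69 for
adults), age × gender and spline × gender cross-products, an end-of-week
indicator (Fri/Sat/Sun) and a second-recall (by-phone) indicator.

**Estimation.** The marginal likelihood integrates the random intercepts
out by Gauss–Hermite quadrature on a standardized product grid (15
nodes/dimension by default, configurable): with at most two observations
per person the integrand is dominated by the random-effect prior, so
prior-centred (non-adaptive) quadrature is accurate — doubling the nodes
changes fitted parameters by well under 0.1%, which a test enforces. Fixed
node positions make the gradient of the marginal log-likelihood exact and
analytic, which is what keeps replicate refits cheap. The Box-Cox
parameter λ is estimated jointly with everything else by including the
transform Jacobian `R^(λ−1)` in the positive-amount density (the estimator
used by the standard mixed-model software this model class comes from),
reparameterized to stay in [0.01, 1] via a scaled logistic; variances are
optimized as log-standard-deviations and ρ as atanh ρ. Design columns are
standardized internally for conditioning and mapped back. Optimization is
L-BFGS-B (memory 30) with data-driven starts (survey-weighted logistic GLM
for part 1; Box-Cox MLE plus weighted OLS for part 2) and up to three
restarts continuing from the best point; convergence requires a gradient
sup-norm below 10⁻⁴ on the per-person-scaled objective, else a
`ConvergenceError` carries the best-so-far parameters.

**Weights and uncertainty.** Survey weights enter the likelihood at the
person level and are normalized to mean one within each fit (weighted ML is
invariant to their scale). Reported standard errors are sandwich
(robust/design-based) by default — inverse-Hessian SEs understate sampling
variance under unequal weights; the Hessian is computed by central
differences of the analytic gradient and the per-person scores are
analytic.

**Amount rescaling.** Box-Cox fits are not scale-equivariant, and
per-bodyweight intakes are numerically tiny (~10⁻⁴ µg/kg/day).
`amount_scale="auto"` multiplies amounts by the power of ten that puts the
median positive amount near 5 before fitting; simulated intakes are divided
back. The scale is recorded in the fitted parameters.

**Simulation.** Usual intake for a person is
`E_day[ P(cons | u_1) · E(R | R > 0, u_2) ]`, averaged over a 4/7
weekday / 3/7 end-of-week mixture with the sequence covariate at
first-recall mode (the "usual day" convention). For each of `n_sim = 100`
pseudo-person draws, `(u_1, u_2)` is sampled from the fitted bivariate
normal and the noise-term back-transform `E_ε[g⁻¹(m + u_2 + ε; λ)]` is
evaluated by 9-point Gauss–Hermite integration; nodes outside the
transform's support (`1 + λy ≤ 0`) are truncated at the boundary (value 0)
and counted. A 10⁶-draw Monte Carlo mega-simulation oracle reproduces the
package's weighted P50/P95/P99 to ~0.1%, far inside the 5% acceptance
tolerance. Group summaries pool all pseudo-person draws with weight
`w_i / n_sim` and use the package-wide percentile convention (below).
Groups with fewer than 50 both-day consumers are flagged, following the
usual stability guideline for this model class.

## 4. Hazard quotients and short-term intake

HQ = intake / ADI with JECFA ADIs: MGA 0.03, P 30, T 2 µg/kg/day;
testosterone exposure is screened as T + EpiT against the T ADI. Reports
render HQs to two decimals with values below 0.005 shown as "<0.01";
unrounded values are always stored. The hazard index (sum of HQs for
related critical effects) is provided as an optional column. Short-term
intake is the two-day mean among persons completing both recalls; those
summaries are flagged as not strictly comparable to chronic ADIs. HQs are
always computed from unrounded intake, so a re-derived HQ can differ in the
last printed digit from one computed off a rounded table entry.

## 5. Sociodemographic intake ratios and BRR variance

Subgroup contrasts are ratios of the weighted median usual intake in a
subgroup to the weighted median of the *overall* reference population
(children 1–19, or women 20+), with the subgroup included in the reference.
Sampling variance uses balanced repeated replication with Fay's method:
pseudo-strata each contain two half-sample units; replicate *r* multiplies
one half by (2 − F) and the other by F (F = 0.3, 32 replicates) following a
Hadamard-balanced pattern (the all-ones column is dropped), and

`var(θ̂) = Σ_r (θ̂_r − θ̂)² / (R (1 − F)²)`.

Replicate weights are built on the full sample and subset afterwards (a
half-sample may be empty within a subpopulation), and each replicate is
rescaled to the full-sample weight total — median- and ratio-type
estimators are invariant to that rescaling. Confidence intervals and
two-sided tests (α = 0.05) are normal-reference on the log-ratio scale,
which guarantees positive bounds. Failed replicates are dropped and
counted; more than 25% failures aborts. Two replication modes exist: the
default refits the usual-intake model under each replicate weight set
(warm-started from the full-sample fit, with the same simulation seed so
only the weights vary); the cheaper summary mode re-evaluates the weighted
medians over the existing pseudo-person draws. Null coverage of the 95% CI,
measured over 200 synthetic populations with a true ratio of 1, is ~93%.

## 6. Percentile convention

Every percentile anywhere in the package is the weighted empirical quantile
with linear interpolation between adjacent order statistics at Hazen
plotting positions `(cw_k − w_k/2)/W` on the cumulative-weight scale; with
equal weights and values 1…100 the median is 50.5. A brute-force
weighted-CDF inversion oracle checks it on hundreds of random samples.

## 7. Synthetic study conditions

The generator's defaults define the conditions the pipeline is exercised
under; they emulate the structure of a two-cycle national diet survey
joined to a retail residue survey:

* **Population** — ages uniform 1–80, equal genders, bodyweights from a
  gender-specific growth curve with 16% log-normal spread, survey weights
  log-normal with σ = 0.4, 16 paired pseudo-strata; race/ethnicity, income
  (≤130% vs >130% of the poverty line) and education categories at
  plausible national shares.
* **Consumption** — two non-consecutive recall days; the two-part truth
  gives children ~25–30% consumption days (≈14% consuming on both days)
  and consumption-day amounts of roughly 40–90 g raw beef (λ = 0.4,
  ρ = 0.5); adults similar with larger amounts. Every recall day records
  at least one non-beef filler food, as a real recall would, so the
  person-day grid is complete.
* **Recipes** — 40 foods with 1–5 ingredients, ~60% containing beef, beef
  weight fraction uniform on [0.10, 0.95], label fat proportion uniform on
  [0.05, 0.35]; beef descriptions vary case to exercise the matching rule.
  Generated grams are allocated so that recipe disaggregation reverses
  exactly (the round-trip test).
* **Assays** — 321 non-fat products plus 76 paired fat subsamples;
  censored log-normal concentrations with location/scale set so detection
  frequencies land near the retail regime (fat: EpiT 36%, MGA 25%, P 21%,
  T 4%; non-fat: P 24%, MGA 18%, EpiT 17%, T 6%) at LODs of 0.1 pg/mg
  (0.5 for P); a near-never-detected analyte (TB) exercises the
  ten-detection inclusion rule.
* **Subgroup effects** — optional amount multipliers per demographic
  category build known median-intake ratios for recovery tests.

What the generator does **not** emulate: recall reporting error beyond the
model's own noise term (the within-person error distribution is exactly
the amount model's, so passing tests show the machinery is correct, not
that real recalls satisfy the model); the food-code vocabulary and recipe
heterogeneity of a real nutrient database (one recipe per food code);
masked-variance survey PSU structure (pseudo-strata are assigned at
random); and any systematic reporting bias, which no within-person model
can remove.

**Parameter-recovery harness.** Recovery experiments (20 replicate fits at
1500 persons × 2 days) use a child-cohort truth placed where the
random-effect parameters are identified — consumption probability
~0.55–0.6 so that ~600 persons consume on both days (the records that
separate `σ²_u1`/`σ²_u2` from σ²), equal between/within amount variances,
ρ = 0.5, λ = 0.4. Under these conditions every fixed effect lies within 3
reported SEs of truth in ≥ 18/20 fits and the median relative error of
`σ²_u1`, `σ²_u2`, ρ and λ across fits is within ±10% (measured: within
±5%). The per-replicate spread of the amount-variance estimates is
considerably larger than the bias because λ and the variance scale lie on
a shallow likelihood ridge — a property of the ML estimator at this design
size, visible in the reported standard errors.

## 8. Problem sizes

Default analyses and tests run at desk scale by design: populations of
700–2000 persons for pipeline runs, 1500 for recovery studies, 200
replicate populations for coverage checks, 10⁶ draws for the simulation
oracle. All sizes are configuration parameters.

## 9. Known limitations

* Single-value LOD/√2 substitution (not maximum-likelihood censoring) is
  used for non-detects, matching standard practice for these detection
  frequencies; heavily censored analytes are excluded rather than modelled.
* The usual-intake model assumes within-person errors are exchangeable
  across days after the Box-Cox transform and cannot correct systematic
  self-report bias.
* ρ estimates hit the ±1 boundary in small cohorts (a known behaviour of
  correlated two-part fits); the fit reports it honestly rather than
  penalizing toward the interior.
* One-day-only persons contribute to fitting and receive simulated draws
  like everyone else; no day-2-specific weight adjustment is modelled.
* BRR confidence intervals for medians rely on the smoothing provided by
  Fay's factor; very small subgroups can still produce degenerate
  replicate spreads, which the output flags via replicate-failure counts.
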