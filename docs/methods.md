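# Methods

## Model

All estimation is ordinary least squares on person-level trial data. With a
binary treatment indicator TX and optional covariates X₁…Xₚ, three outcomes
are regressed on the same design matrix:

* cost:   `c_i = b0 + b_TX TX_i + Σ b_j X_ji + ε`, so `b_TX` estimates ΔC;
* effect: `e_i = …`, so `b_TX` estimates ΔE;
* net benefit at willingness-to-pay λ: `NB_i = λ e_i − c_i` regressed the
  same way, so `b_TX` estimates `INB(λ) = λΔE − ΔC`.

Because NB is a fixed linear combination of the two outcomes and the design
is shared, the NB fit is *algebraically determined* by the cost and effect
fits: coefficients combine as `λ b_E − b_C`, residuals as `λ r_E − r_C`, and
the residual variance composes as

    s²_NB(λ) = λ² s²_E − 2λ s_EC + s²_C,

where `s_EC = Σ r_C r_E / df` is the residual cost-effect covariance. This
composition is what makes the INB confidence interval account for the
correlation between a patient's cost and effect; the package asserts these
identities in its test suite rather than assuming them. The TX-coefficient
sampling covariance is `Cov(ΔĈ, ΔÊ) = s_EC · g_TX` with
`g_TX = [(X'X)⁻¹]_TX,TX`.

Standard errors are classical homoskedastic OLS with t-reference p-values
(df = n − p − 1); this matches the simple-regression machinery the framework
is usually presented with. Costs are right-skewed, so these are
CLT-justified rather than exact; a heteroskedasticity-robust (HC1) option
exists (`robust=True`) but is off by default. p-values use the t rather than
the normal reference; at the sample sizes of interest (n ≥ 150) the
difference is negligible, but it is the documented choice.

The covariate list is forced identical across the cost, effect and NB
regressions of one analysis — otherwise the linear identities above (and the
Fieller geometry built on them) would not hold.

### Solver

OLS is solved by singular value decomposition, not normal equations. Rank is
detected with the machine-epsilon-scaled cutoff `s_max · max(n, p) · eps`;
a deficient design raises an error naming the columns with non-trivial
loadings in the null space, rather than silently pseudo-inverting. An
outcome fit to rounding noise (residual sum of squares below
`n · (10⁻¹² · max(1, max|y|))²`) is snapped to zero residual variance so
degenerate inputs (constant outcomes, zero-noise synthetic data) report
exact zeros and p-values of 1 for null coefficients.

## ICER policy

The ICER ΔC/ΔE is computed and displayed (rounded to the nearest dollar;
full precision kept internally) only in the sign-consistent quadrants of the
cost-effectiveness plane: *trade-off* (ΔC > 0, ΔE > 0) and
*cost-saving-less-effective* (ΔC < 0, ΔE < 0). In the mixed-sign quadrants
(*dominant*, *dominated*) a negative ratio carries no decision-relevant
ordering, so the quadrant label is reported and the ratio suppressed; the
INB remains available at every λ, which is the framework's answer to such
"challenging" findings. ΔE = 0 yields an explicit "undefined" label.

## WTP sweep and Fieller limits

`sweep_inb` runs one NB regression per grid point (default grid $0–$500,000
in $50,000 steps, configurable); the grid is for tabulation only. The
zero-crossing (point ICER) and the CI-bound crossings are computed from the
closed-form line `λΔE − ΔC` and SE function `√(λ²v_E − 2λv_EC + v_C)`:

* the WTP where the **upper** INB bound crosses zero is the **lower**
  Fieller limit of the ICER; the lower bound's crossing is the upper limit;
* the upper bound is convex in λ and the lower bound concave (line ± t times
  the square root of a non-negative quadratic), so each has one vertex and
  is monotone on either side. The implementation locates the vertex
  (bounded scalar minimization), brackets each side, and runs Brent's method
  to machine tolerance — a safeguarded root-finder immune to grid spacing
  and to narrow double crossings;
* the search domain is λ ≥ 0 (negative thresholds have no decision
  meaning). A bound that never crosses there is reported as *unbounded*
  (`None`), which is exactly Fieller's behaviour when ΔE is not
  significantly different from zero at the chosen level. With zero sampling
  variance the limits collapse to the point ICER.

`extrapolate_inb` restates a tabulated INB at any other WTP using the line's
slope (each $1 of WTP changes INB by ΔE dollars), rounding to the nearest
dollar for reporting. Whole-dollar rounding (not truncation) is used for all
dollar display quantities, including the ICER.

## CEACs and the bootstrap

The parametric CEAC converts the NB regression's two-sided p-value p₂ to the
one-sided probability that INB > 0: `1 − p₂/2` when the estimate is
positive, `p₂/2` when negative, 0.5 at exactly zero. Equivalently it is the
t-CDF of the TX t-statistic, so at the point ICER the curve passes through
0.5, at λ = 0 it equals the one-sided probability that ΔC < 0, and as
λ → ∞ it approaches the one-sided probability that ΔE > 0. Note the shape
implication for a dominated treatment (ΔE < 0, ΔC > 0): the curve stays
below 0.5 at every λ but *rises* toward that effect-only tail probability,
because the INB's standard error grows faster in λ than the estimate falls.

The bootstrap resamples patients with replacement *within arm*, preserving
the randomized arm sizes (the resampling unit is the patient; stratification
by arm reflects the design). ΔC and ΔE are recomputed per replicate via
arm-mean differences (unadjusted) or a refit of the shared design
(adjusted). The bootstrap CEAC is the fraction of replicates with
`λΔE* − ΔC* > 0`, ties counting one half; INB intervals are percentile
intervals (BCa is deliberately out of scope — percentile is the simplest
defensible default and agrees with the t interval under approximate
normality, which the tests check at 10% relative tolerance). Replicates with
zero within-arm variance are retained and flagged, never redrawn. All draws
come from `numpy.random.default_rng(seed)` with a required explicit seed;
arm-0 indices are drawn before arm-1 indices, making replicate streams
bit-reproducible on a platform.

## Subgroups

`interaction_fit` adds a subgroup dummy G and a TX×G term to the NB
regression: `b_TX` is the reference-stratum INB, `b_TXxG` the between-stratum
INB difference, and the non-reference stratum's INB is
`b_TX + b_TXxG` with delta-method SE
`√(Var(b_TX) + Var(b_TXxG) + 2Cov)` read from the coefficient covariance —
exact under OLS. `stratified_analysis` runs independent sweeps per stratum.
Without extra covariates the interaction model is saturated in (TX, G), so
the two routes give identical point estimates (asserted at 10⁻⁸ relative in
tests); their SEs legitimately differ (pooled versus per-stratum residual
variance) and are not asserted equal. Continuous moderators use the same
TX×X design with the combined INB reported at user-specified moderator
values; no automatic dichotomization. Reference levels are first-appearance
and relabeling exactly swaps `b_TX` with the combined INB while flipping the
interaction's sign.

No multiplicity correction is applied across subgroups: these are
hypothesis-generating analyses, and the package reports them as such.

## Synthetic-trial generator

`synthdata.generate` emulates the structure such analyses consume: a
randomized two-arm trial with optional biomarker strata, right-skewed costs,
approximately normal QALY effects and within-patient cost-effect
correlation. Per stratum and arm, a shared latent standard normal factor z
induces correlation ρ between the effect disturbance and the cost
disturbance; effects are `mean + σ_E · a_e`, and costs pass the latent
normal through one of three families with the arm mean preserved exactly in
expectation:

* lognormal (default; dispersion = SD of log cost, mean-corrected via
  `μ_log = ln(mean) − σ²/2`),
* gamma (dispersion = coefficient of variation, Gaussian-copula transform),
* normal (dispersion = coefficient of variation).

ρ is specified on the latent scale; for the non-normal families the
observed-scale correlation is attenuated by the monotone transform, which is
acceptable because nothing downstream assumes a particular observed ρ —
only that cost and effect are genuinely correlated. Optional numeric
covariates add mean-centered linear shifts to both outcomes, leaving the
configured increments untouched.

### Preset and chosen constants

The `co17_like_preset` models a two-stratum biomarker trial: strata of 150
("MUT") and 216 ("WT") patients split evenly across arms, with incremental
truths ΔC = $13,787 / $30,843 and ΔE = −0.0172 / 0.1769 QALYs. The source
trial context reports only increments, so the remaining constants are this
package's choices, fixed once at plausible magnitudes for chemotherapy-
refractory metastatic colorectal cancer over ~18 months: control-arm mean
cost $12,000 and mean effect 0.28 QALYs (≈4.6 months median survival at
utility ≈0.7), log-cost SD 0.7 (cost CV ≈ 0.8, strongly right-skewed),
effect SD 0.18 QALYs, latent ρ = 0.3. They are descriptive defaults, not
estimates of any real trial. The prevalence-weighted whole-sample truths
implied by the preset (ΔE ≈ 0.0773, ΔC ≈ $23,854 at 216/366) deliberately
differ from a pooled ALL row that would also include patients of unknown
biomarker status; only the two known strata are modeled.

What passing tests on this generator do show: unbiased recovery of
configured increments, nominal (0.92–0.98 at the 95% level, n = 2000/arm)
INB interval coverage, correct interaction/stratification algebra, and
parametric-bootstrap CEAC agreement under approximate normality. What they
do not show: performance under censoring or administrative truncation of
costs (not simulated, out of scope), heavy-tailed cost behaviour beyond the
lognormal, informative missingness (the data model rejects missing values
outright), or non-random treatment assignment.

## Problem sizes in checks

The repeated-simulation checks use R = 200 replicates at n = 2000 per arm
per stratum for truth recovery and coverage, and n = 500/arm with B = 5000
replicates for bootstrap-parametric CEAC agreement (sup-norm tolerance
0.03, about four Monte-Carlo SDs of a binomial proportion at B = 5000).
These sizes make the Monte-Carlo error a small fraction of the asserted
tolerances while keeping the default test run fast.

## Data handling decisions

* Missing cost or effect values are a hard error, never imputed or silently
  dropped — complete-case analysis is the assumed input, and silent drops
  would bias ΔC and ΔE.
* Negative costs are rejected by default (likely data errors) with an
  explicit override for genuine credits.
* Categorical covariates are dummy-coded against a first-appearance
  reference level, making adjusted fits reproducible for a given file order.
* CSV round-trips are bit-exact: floats are written as shortest
  round-trippable decimals and re-parsed with a correctly-rounded converter.
* Negative WTP values are rejected everywhere (no decision meaning).

## Known limitations

* No censored-cost or survival-aware estimation; person-level totals are
  taken at face value.
* No GLMs for skewed costs (gamma regression etc.) and no simultaneous
  (seemingly-unrelated) estimation of the cost and effect equations; plain
  OLS is the contract.
* Percentile bootstrap only; BCa intervals would be a natural extension.
* The CEAC tie rule and one-sided conversion assume a symmetric two-sided
  p-value split, which is exact for the t reference used here.
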