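# Methods

## The dataset

The packaged table holds weight-normalized clearance (CL, mL/h/kg) and
subcutaneous bioavailability (SC%F, %) for 25 humanized/fully-human
IgG antibodies across Sprague Dawley rat, cynomolgus monkey, and human.
Values are curated study-level summaries (population-PK or NCA
estimates at dose-linear levels); missing cells are genuinely absent
and are never imputed.  Three SC%F values above 100% are retained as
experimentally determined; a censor-at-100 toggle exists for
sensitivity analysis.  Absolute clearance uses fixed typical body
weights — rat 0.3 kg, monkey 3 kg, human 70 kg — and the conversion
L/day = (mL/h/kg) x kg x 24/1000.  The absolute-CL unit convention
(L/day with BW in kg) was chosen because it makes the fitted allometric
coefficients (~0.007 L/day at 1 kg) consistent with observed
species-typical clearances.

Record order is the curated table's row order, and every subsetting
operation is order-stable, so bootstrap indexing is reproducible.

## Non-compartmental analysis

Reference NCA software leaves several rules configurable; the package
fixes and documents them:

* **λz selection** — log-linear OLS over every terminal subset of the
  last k >= 3 post-Tmax points; the subset with maximal adjusted R² wins,
  ties (within 1e-4) going to the larger subset; the slope must be
  negative.  For SC profiles only post-Tmax points are eligible.
* **AUC** — linear trapezoid on rising/flat segments, logarithmic
  trapezoid on declines ("linear-up/log-down"), exact for exponential
  decline; AUC₀–∞ = AUC₀–tlast + C_last/λz.
* **Quality gate** — a result fails when λz is missing or the
  extrapolated fraction reaches 25% (boundary excluded).
* **BLQ** — points below the LLOQ (default 10 ng/mL, the lower bound of
  a typical total-IgG ELISA curve) never enter regressions or AUC;
  excluded (ADA/manual) points never enter any computation.
* **ADA screen** — a surrogate for visual review: fit a
  mono-exponential trend to usable post-Tmax points up to the 336 h
  anchor, project it forward, and flag the maximal contiguous terminal
  run of points (never before 168 h) that fall below 0.25 x the
  projection *and* below the projection's lower 3-SE prediction bound.
  The two-condition design is deliberate: the anchor window holds few
  points and, for SC profiles, is biased shallow by the absorption
  tail, so a pure ratio rule at the conventional 0.5 trips on ordinary
  assay noise at long extrapolation distances (measured ~20% of clean
  profiles at 20% CV), while genuine ADA-accelerated decline reduces
  exposure by orders of magnitude and clears both conditions.  The
  threshold, anchor, and z are configuration parameters.

Bioavailability is the ratio of arithmetic-mean AUC₀–∞ across animals,
SC over IV, x100, requiring equal nominal per-kg dose in both arms
(dose normalization is available but off by default).

## Allometric mixed-effects model

Structural model per antibody i and species j:

    CL_ij = alpha_TV * exp(eta_i) * BW_j^beta_TV * (1 + eps_ij)

with eta_i ~ N(0, omega²) shared across an antibody's species
observations and proportional residual eps_ij ~ N(0, sigma²) on the
untransformed CL scale (a log-transform-both-sides variant exists as a
sensitivity option).  A second random effect on the exponent
(beta_i = beta_TV * e^(eta2,i)) is supported for model comparison.
Every antibody with at least one observation in the species set
contributes a cluster.

**Estimation.**  The marginal likelihood integrates the random effect
per antibody.  With a single scalar effect the integral is
one-dimensional, so the primary estimator is *adaptive Gauss–Hermite
quadrature* (default 31 nodes) centered and scaled at the per-antibody
posterior mode found by damped Newton iterations with analytic
derivatives; at these node counts the quadrature is converged to well
below 0.01 OFV units (checked against 63 nodes).  A Laplace
approximation — the same machinery with one node — serves as the fast
path for bootstrap resampling; on this class of data it agrees with the
quadrature to within about one OFV unit (and within 0.5 on the
synthetic suites), which is immaterial for the ΔOFV ≥ 3.841 decisions
made here but is the reason quadrature, not Laplace, is the default.
Two-dimensional random effects use tensor-product adaptive quadrature
(15 nodes per dimension).

The objective function value (OFV) is -2 x log marginal likelihood with
all 2*pi constants included; only differences between nested models are
interpreted, so the constant convention is immaterial.  Outer
optimization is Nelder–Mead on (log alpha, beta, log omega², log
sigma²) started from pooled log-log least squares with omega² = 0.2,
sigma² = 0.1, with polish restarts on non-convergence.  Variance
parameters carry a 1e-10 floor: for exactly power-law data (the
degenerate sigma -> 0 limit) the floor keeps alpha identified — without
it the per-antibody etas can absorb any coefficient offset — and it is
orders of magnitude below any realistic estimate.

**Uncertainty.**  Standard errors come from the observed information
(central-difference Hessian of OFV/2 on the estimation scale) with
delta-method transformation; 95% CIs are Wald intervals on the log
scale for alpha/omega²/sigma² and the identity scale for beta.
Cluster bootstrap (resampling whole antibodies with replacement,
dataset size preserved, failed replicates counted) provides percentile
intervals; the resampling pool is every cluster in the model.

**Model comparison.**  Nested models differing by one parameter are
compared at the chi-square 1-df 5% threshold: the richer model is
selected iff OFV drops by at least 3.841.  When the exponent random
effect omega²(beta) is added to the final models, the fitted solution
is inspected for residual-variance collapse (sigma² falling several-fold
with a near-zero omega²(beta)), the signature of the two-random-
effects-for-two-observations interpolation degeneracy; the comparison
report flags such solutions.  On the packaged dataset three of the four
species sets show no improvement; the rat–human set reaches a
degenerate mode of this kind (ΔOFV ≈ 8 with sigma² collapsing 16-fold),
which classical linearization-based estimators do not find and which
fails the usual "reasonable parameter estimates" screen.

**Scaling.**  Human CL from a single species uses
CL_human = CL_species * (BW_human/BW_species)^beta in absolute units —
equivalently, per-kg CL transforms with exponent beta - 1.  The 2-fold
accuracy band on observed/scaled ratios is inclusive at both ends
([0.5, 2.0]).  Headline within-2-fold counts are invariant to whether
the fitted or the two-decimal rounded exponent is used, but the mean
observed/scaled ratio is not (rat: 1.04 at the fitted 0.9157 vs 1.02 at
0.92); report tables therefore show both.

## Correlation analyses

Spearman's rho uses average ranks; the two-sided p-value is computed by
exact enumeration of the rank-permutation null for n <= 9 without ties
(full enumeration beyond that is combinatorially infeasible and all
packaged-data pairs are larger anyway) and by the t approximation
otherwise.  The 95% CI uses the Fisher z transform with
SE = sqrt(1.06/(n-3)) and is reported as approximate.  OLS regressions
report r², slope, intercept, and the slope t-test p.  The
within-species CL-vs-SC%F regressions use log10(CL) as the predictor,
matching the semi-log structure of that relationship.

## Synthetic data

The study simulator emulates the de novo rat design: 3 mg/kg IV bolus
and SC, N = 3 per route, sampling at 1–1008 h (16 points).  Disposition
is a closed-form two-compartment model; defaults (CL 0.3 mL/h/kg, Vc 50
and Vp 30 mL/kg, Q 1.5 mL/h/kg, ka 0.02 1/h, F 0.62) give a terminal
half-life near two weeks so the schedule yields well under 25% AUC
extrapolation.  Assay noise is multiplicative log-normal
(median-preserving, CV default 15%); values below the LLOQ are flagged
censored.  ADA is modeled as a step increase of the terminal
elimination rate (default 10-fold) from a late onset (default 336 h)
in a Bernoulli subset of animals (default incidence 0.3) — enough to
exercise the detection screen, with no claim about any particular
study's immunogenicity.  Ground-truth AUCs are analytic
(dose/CL and F x dose/CL), so recovery tests have closed-form oracles;
the closed-form profiles themselves are validated against an
independent ODE integration in the test suite.

The allometric generator draws from the structural model exactly
(defaults alpha 0.007 L/day, beta 0.90, omega 0.45, sigma 0.28,
25 antibodies), truncating residuals at CL > 0 and refusing sigma large
enough to truncate more than 1% of draws.

What the generators do *not* emulate — target-mediated disposition,
ADA washout of the measured analyte, inter-animal kinetic variability
beyond assay noise, injection-site effects — bounds what passing tests
show: they validate the estimators against the stated generative
models, not against every feature of real study data.

## Problem sizes and reproducibility

All fixture analyses are deterministic; simulation-based checks use
fixed seeds and the same seed reproduces byte-identical outputs.  The
test suite runs the estimator-consistency checks at 50 replicates of
the study-scale design (23 antibodies, 2 species) plus one large-sample
(n = 200, 3 species) recovery, and bootstrap stability at 400
replicates per model with the Laplace fast path; the CLI default
remains 2000 replicates.

## Known limitations

* The dataset is a curated snapshot; a handful of published summary
  numbers derived from adjacent snapshots of the same study data
  (one species' bioavailability summary, one within-species regression)
  are not exactly recoverable from the table and are documented as such
  in the test suite.
* No covariates on the allometric coefficient are modeled, and
  antibodies with engineered FcRn-affinity modifications (YTE/LS) are
  outside the model's scope.
* Wald intervals on variance components at n ~ 25 clusters are rough;
  prefer the bootstrap percentiles.
* The ADA screen is a surrogate for expert visual review tuned for
  late-onset, strong acceleration; mild or early-onset ADA will not be
  flagged.
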