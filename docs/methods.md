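# Methods

This note documents the models implemented in `medgrowth`, the estimation
machinery, the synthetic-trial generator's calibration, and the choices
made where the design was genuinely open. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## 1. Latent profile analysis

The baseline battery has 18 continuous indicators and one binary
indicator (previous suicide attempt). The K-class model assumes local
independence within class: continuous indicator *j* is normal with
class-specific mean μ_kj and a variance σ_j² **shared across classes**;
the binary indicator is Bernoulli with class-specific probability p_kj.
Class-invariant variances are the common parsimonious LPA default; a
class-varying-variance option is deliberately not offered in v1.

Estimation is EM, best of `n_starts = 20` random-responsibility
initialisations, convergence at a relative log-likelihood change below
1e−6 (max 500 iterations). The ascent property is asserted at every
iteration. Missing indicator entries contribute nothing to the casewise
likelihood (the product runs over observed entries only), which is the
mixture analogue of FIML under MAR. Bernoulli probabilities are clipped
to [1e−4, 1 − 1e−4] to keep the likelihood bounded.

Label switching is resolved by sorting classes ascending on the mean of
the first continuous indicator (clinician-rated residual symptoms), so
class 2 is always the higher-severity profile. Selection tables report
log-likelihood, AIC, BIC, relative entropy
1 − Σᵢₖ(−p̂ᵢₖ ln p̂ᵢₖ)/(n ln K), and the smallest class fraction for
K = 1…K_max; the BIC minimiser is flagged. Classification is modal
(argmax posterior, ties toward the lower class). Distal variables
(quality of life) never enter the mixture likelihood; they are compared
across modal classes by pooled-SD Cohen's d (normal-theory CI) or an
odds ratio (Haldane-corrected, Woolf CI).

An independent cross-check in the test suite fits the same model with R
`mclust` (model "EEI" — equal diagonal covariances) on a complete
continuous fixture and compares log-likelihood, weights and means.

## 2. Latent growth curve models

BDI-II totals at months λ = (0, 3, 9, 12, 18, 24) load on latent
intercept/slope/quadratic factors: implied mean Λα and covariance
ΛΨΛᵀ + Θ, with Λ columns (1, λ_t, λ_t²) truncated to the chosen shape.
Residual structures: one free θ (homoscedastic), six free θ_t, or six
free θ_t plus a lag-power correlation Θ_jk = √(θ_j θ_k)·ρ^|j−k| over the
**occasion index** (not month gaps) — the adjacency convention used by
mainstream SEM software. Shapes and residual structures nest
(intercept ⊂ linear ⊂ quadratic; homoscedastic ⊂ heteroscedastic ⊂
heteroscedastic-AR), which `compare_models` exploits for LRTs; when the
smaller model fixes a variance at the boundary the χ² reference is
conservative, and the comparison table's information criteria are the
primary selection device.

**Estimation.** The FIML log-likelihood sums, over each case's observed
occasions, the MVN log-density under the implied sub-moments. Because
the mean is linear in α, α is profiled out by GLS for any covariance;
the profile likelihood is then maximised over covariance parameters by
L-BFGS-B with **analytic gradients** (the envelope theorem makes the
gradient at the GLS optimum exact without mean-parameter derivatives).
Sufficient statistics are precomputed per missingness pattern and
batched by observed dimension, so a likelihood evaluation costs a few
small batched matrix operations regardless of n. Parameterisation
guarantees positive-definiteness at every iterate: Ψ via a Cholesky
factor with log-diagonal, θ_t via logs, ρ via tanh. The squared-time
loading column is internally scaled by 1/10 for conditioning; all
reported quantities are back-transformed to points/month².

Numerical choices: convergence at ftol 1e−15 / projected-gradient 1e−8;
5 starts by default (perturbations of a moment-based start); variance
estimates reaching the 1e−8 floor are reported as 0 with a boundary
flag. Wald tests of factor variances use a delta method on the
transformed parameters with a numerical Hessian of the profile
likelihood; the two-sided normal reference is conservative at the
boundary, and non-significant variances can be refit fixed to zero via
`factor_variance_constraints`. The default pipeline compares
intercept-only (free intercept variance), linear (slope variance fixed),
and quadratic (slope and quadratic variances fixed) shapes, all with
heteroscedastic-AR residuals.

## 3. Moderated mediation

Linkage to the profiles is **stepwise**: classify first (modal
assignment), then fit the structural model as a multi-group model
conditional on class. Classification error is not propagated
(BCH/ML-three-step corrections are out of scope); with the default
generator's separation the modal error rate is ≈ 6–8%, so group-specific
paths are mildly attenuated toward each other — visible in the worked
example, where the fitted a-paths (≈ 6.1, 12.9) sit slightly inside the
generating (5.03, 13.87).

Per profile *g*: the mediator equation M = a0_g + a_g·X (+ covariates)
and the structural slope equation η₁ = β0_g + b_g·M + c′_g·X
(+ covariates) + ζ₁, with the quadratic factor retained in the
measurement model (mean α₂ shared across groups, variance fixed at zero)
but not treated as a structural outcome. The intercept factor keeps a
free variance ψ00 and the slope disturbance variance ψ11 is estimated;
the residual structure follows the growth spec (heteroscedastic-AR by
default), shared across groups.

**Estimation.** The model requires an observed mediator and exposure per
case (missing-mediator cases are dropped and counted; the generator
never produces them). Conditional on M and X the joint likelihood
factorises: the mediator equation is fitted per group by OLS (exact ML
for a normal disturbance; statsmodels provides the Wald machinery), and
the BDI series contributes a patterned-Gaussian FIML likelihood whose
mean — linear in (α0_g, β0_g, b, c′, α₂, covariate terms) — is profiled
by GLS exactly as in the growth module. Moderation of the b- and
c′-paths is always Wald-tested on a fully free fit; the primary
coefficients follow the `MedModSpec` equality flags, which default to shared b
and c′ (the configuration supported when the free-fit moderation tests
are null, as under the default generator). Covariate coefficients are
group-specific in both equations, so each covariate adds two parameters
per equation.

Derived quantities are construction identities: IE_g = a_g·b_g, index =
IE₂ − IE₁ (= (a₂ − a₁)·b under shared b), projected change = IE × months.
The total effect c refits the model without the mediator. R² is
1 − disturbance/total implied variance per equation per group (for the
slope equation, explained variance comes from the within-group empirical
covariance of (M, X, covariates) with the fitted coefficients).

**Bootstrap.** Nonparametric case resampling, stratified by arm, with
profile labels travelling with the resampled cases (classification
uncertainty again not propagated — a documented limitation). Each draw
refits the whole model warm-started at the original solution; failed
draws are dropped and counted, with >10% failures aborting. Intervals
are percentile bounds taken as order statistics of the draws;
significance is "zero outside the CI". Default B = 1000 (a warning below
that; hard floor 200), fully reproducible given the seed. No
multiple-testing correction is applied anywhere in the chain.

## 4. Synthetic-trial generator

The generator draws, per participant: class ~ Bernoulli(π₂ = 0.5)
(class proportions are not identifiable from published summaries, so an
even split is the default); balanced 1:1 arm assignment; class-conditional
indicators (shared SDs across classes; the differing indicators separated
by moderate-to-large standardised gaps, protective factors mildly
reversed); ΔFFMQ from the mediator equation; growth factors from
MVN(α_g, Ψ) with the slope shifted by b·ΔFFMQ + c′·arm + N(0, σ_slope²);
BDI series from the quadratic curve plus MVN residuals with the
lag-power structure. Observed BDI values are rounded to integers and
clipped to [0, 63] **at the observation step only** — latent quantities
are never truncated. Follow-up waves are masked independently with
probabilities (0.821, 0.691, 0.764, 0.686, 0.793); the baseline wave is
never deleted. An independent-mask mechanism is MCAR, the ignorable
special case of the MAR assumption the estimators rely on. Arm-dependent
covariates (practice level, ADM discontinuation) match the published
arm-wise frequencies and are conditionally independent of the mediator
given arm.

Calibration anchors taken from published quantities: n = 424; class
baseline means (10.71, 19.37); linear and quadratic factor means −0.30
and 0.01; conditional a-paths (5.03, 13.87); shared b = −0.03 and
c′ = 0.37; the retention vector. Quantities never published (indicator
scales, Ψ, Θ, σ_m, σ_slope, π₂) are flagged as calibrated guesses; the
defaults are ψ00 = 16, σ_slope = 0.08 points/month, σ_m = 5 FFMQ points,
θ_t = (9, 10, 12, 12, 14, 16), ρ = 0.3.

Two published anchors cannot be jointly honoured at these scales.
Matching the published mediator R² (0.02/0.15) forces σ_m ≈ 16, but with
b = −0.03 that fans the 24-month trajectories so widely that well over
5% of observations would be floor-clipped — incompatible with keeping
the bounded instrument nearly linear, which the whole Gaussian chain
assumes. The generator therefore prioritises realistic trajectory spread
and < 5% clipping (asserted in the tests); its implied mediator R²
(≈ 0.25 in the severe class) and slope R² are consequently larger than
the published values. Note that α₁ = −0.30 enters the generator as the
*pre-shift* slope base; the implied marginal slope mean under the
defaults is α₁ + b·E[M] + c′/2 ≈ −0.257, and recovery tests use that
closed form as the oracle.

What passing tests show — and do not show. The generator produces
Gaussian within-class indicator distributions, exact local independence,
a correctly specified growth law, and ignorable missingness. Real trial
data have skewed bounded scales, item-level structure, indicator
correlations within class, and dropout that may correlate with symptom
level. Passing recovery and coverage tests therefore certifies the
estimators under the assumed model, not robustness to violations of it.

## 5. Problem sizes used in the test suite

Simulation-based checks are sized to run comfortably on one CPU: the
implied-moment oracle uses 10⁶ simulated trajectories; parameter
recovery uses single datasets of n = 2000–5000; the index
recovery/coverage study uses 50 replicates at the trial's n = 424 with
B = 200 bootstrap draws per replicate; the FIML bias check uses 12
replicates. All stochastic tests are seeded and deterministic.

## 6. Known limitations

- Two-group moderation only for the index (the fit accepts G ≥ 2, the
  index requires exactly 2).
- No classification-error correction in the stepwise linkage; labels are
  held fixed under resampling.
- No MNAR mechanisms, no item-level simulation, no survival outcomes.
- Percentile intervals only (no BCa); Wald variance tests are boundary-
  conservative.
- The heteroscedastic-AR structure uses occasion-lag exponents; a
  month-gap exponent is a documented alternative, not implemented in v1.
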