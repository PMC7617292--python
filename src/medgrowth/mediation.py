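"""Latent-profile-moderated mediation of depressive-symptom change.

Structural model, per latent profile g:

    mediator:  ΔFFMQ = a0_g + a_g·arm (+ covariates) + e_M
    growth:    BDI_t = η₀ + η₁ λ_t + η₂ λ_t² + ε_t
               η₁    = β0_g + b_g·ΔFFMQ + c′_g·arm (+ covariates) + ζ₁

Conditional indirect effects are the coefficient products IE_g = a_g·b_g;
the index of moderated mediation is IE₂ − IE₁; inference for products uses
the nonparametric percentile bootstrap (case resampling stratified by arm).

Estimation is full-information maximum likelihood over each case's
observed BDI-II occasions, conditional on an observed mediator and
exposure: the joint likelihood then factorises into a per-group mediator
regression (exact ML by ordinary least squares) and a conditional
patterned-Gaussian growth likelihood whose mean coefficients are profiled
out by GLS (see :mod:`medgrowth.growth`). Cases with a missing mediator
are dropped with a count. Coefficients are unstandardised throughout.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .growth import (
    GrowthSpec,
    _QUAD_SCALE,
    _compute_pattern_stats,
    _fit_profiled,
    _theta_block,
)
from .simulate import BDI_COLUMNS

_LOGVAR_LB = np.log(1e-8)


@dataclass(frozen=True)
class MedModSpec:
    """Configuration of the moderated-mediation model."""

    growth: GrowthSpec = field(
        default_factory=lambda: GrowthSpec(
            shape="quadratic",
            residuals="heteroscedastic_ar1",
            factor_variance_constraints=("quad",),
        )
    )
    mediator: str = "delta_ffmq"
    exposure: str = "arm"
    equal_b: bool = True
    equal_cprime: bool = True
    covariates: tuple[str, ...] = ()
    bootstrap_draws: int = 1000
    bootstrap_seed: int = 0
    stratify: bool = True

    def __post_init__(self):
        if self.bootstrap_draws < 1:
            raise ValueError("bootstrap_draws must be >= 1")
        if self.growth.shape == "intercept":
            raise ValueError("the structural outcome is the linear slope; "
                             "growth shape must include a slope factor")


@dataclass
class MedModFit:
    """Fitted moderated-mediation solution (unstandardised coefficients)."""

    spec: MedModSpec
    groups: tuple[int, ...]
    n_per_group: tuple[int, ...]
    # mediator equation
    a0_g: np.ndarray
    a_g: np.ndarray
    a_se_g: np.ndarray
    sigma_m_g: np.ndarray            # ML disturbance SDs
    a_diff: float
    a_diff_se: float
    a_diff_p: float
    # growth/structural side
    alpha0_g: np.ndarray             # intercept-factor means per group
    beta0_g: np.ndarray              # slope-equation intercepts per group
    b_g: np.ndarray
    b_se_g: np.ndarray
    cprime_g: np.ndarray
    cprime_se_g: np.ndarray
    alpha2: float
    psi00: float
    psi11: float                     # slope disturbance variance
    theta_t: np.ndarray
    rho: float
    # moderation tests from the fully free fit
    b_diff: float
    b_diff_se: float
    b_diff_p: float
    cprime_diff: float
    cprime_diff_se: float
    cprime_diff_p: float
    # derived effects
    ie_g: np.ndarray
    index: float
    r2_mediator_g: np.ndarray
    r2_slope_g: np.ndarray
    loglik: float
    converged: bool
    n_dropped: int
    covariate_coefs: dict = field(default_factory=dict)
    # internal warm-start state for bootstrap refits
    _omega: np.ndarray | None = field(default=None, repr=False)


@dataclass
class BootstrapResult:
    """Percentile-bootstrap draws and intervals for the mediation quantities."""

    B: int
    seed: int
    draws: dict[str, np.ndarray]
    ci: dict[str, tuple[float, float]]
    significant: dict[str, bool]
    n_failed: int

    def table(self) -> pd.DataFrame:
        rows = []
        for name, (lo, hi) in self.ci.items():
            rows.append(dict(quantity=name, boot_mean=float(np.mean(self.draws[name])),
                             ci_low=lo, ci_high=hi, significant=self.significant[name]))
        return pd.DataFrame(rows)


# -- assembly helpers ---------------------------------------------------------

def _prepare(dataset: pd.DataFrame, labels, spec: MedModSpec):
    labels = np.asarray(labels)
    if len(labels) != len(dataset):
        raise ValueError("labels must align with dataset rows")
    m = dataset[spec.mediator].to_numpy(dtype=float)
    x = dataset[spec.exposure].to_numpy(dtype=float)
    covs = np.column_stack([dataset[c].to_numpy(dtype=float) for c in spec.covariates]) \
        if spec.covariates else np.empty((len(dataset), 0))
    Y = dataset[BDI_COLUMNS].to_numpy(dtype=float)
    ok = np.isfinite(m) & np.isfinite(x)
    if covs.shape[1]:
        ok &= np.isfinite(covs).all(axis=1)
    n_dropped = int((~ok).sum())
    return (m[ok], x[ok], covs[ok], Y[ok], labels[ok], n_dropped)


def _mean_design(m, x, covs, groups, labels, spec: MedModSpec, lam, qcol):
    """Feature matrix F and basis stack for the conditional growth mean.

    Coefficient layout: [α0_g ...] [β0_g ...] [b terms] [c′ terms] [α2]
    [covariate slope terms ...]; b/c′ are single coefficients when shared,
    per-group otherwise; covariate slope coefficients are per group.
    """
    G = len(groups)
    T = len(lam)
    gi = np.searchsorted(groups, labels)
    onehot = np.eye(G)[gi]

    features = [onehot[:, k] for k in range(G)]          # α0_g and β0_g carriers
    n_b = 1 if spec.equal_b else G
    n_c = 1 if spec.equal_cprime else G
    features += [m if spec.equal_b else m * onehot[:, k] for k in (range(1) if spec.equal_b else range(G))]
    features += [x if spec.equal_cprime else x * onehot[:, k] for k in (range(1) if spec.equal_cprime else range(G))]
    features += [np.ones(len(m))]                        # quadratic carrier
    n_cov = covs.shape[1]
    for j in range(n_cov):
        for k in range(G):
            features.append(covs[:, j] * onehot[:, k])
    F = np.column_stack(features)

    k_total = 2 * G + n_b + n_c + 1 + n_cov * G
    q = F.shape[1]
    bases = np.zeros((q, T, k_total))
    col = 0
    # group indicator features carry both α0_g (ones column) and β0_g (λ column)
    for k in range(G):
        bases[k, :, col + k] = 1.0                       # α0_g
        bases[k, :, G + k] = lam                         # β0_g
    col = 2 * G
    for r in range(n_b):                                 # b · M → slope
        bases[G + r, :, col + r] = lam
    col += n_b
    for r in range(n_c):                                 # c′ · X → slope
        bases[G + n_b + r, :, col + r] = lam
    col += n_c
    bases[G + n_b + n_c, :, col] = qcol                  # α2 (scaled column)
    col += 1
    for j in range(n_cov):
        for k in range(G):
            bases[G + n_b + n_c + 1 + j * G + k, :, col] = lam
            col += 1
    layout = dict(alpha0=slice(0, G), beta0=slice(G, 2 * G),
                  b=slice(2 * G, 2 * G + n_b),
                  cprime=slice(2 * G + n_b, 2 * G + n_b + n_c),
                  alpha2=2 * G + n_b + n_c,
                  cov=slice(2 * G + n_b + n_c + 1, k_total))
    return F, bases, layout


def _medmod_cov_fn(spec: MedModSpec, lam):
    """Σ = ψ00·J + ψ11·λλᵀ + Θ(θ, ρ) with derivative stack."""
    T = len(lam)
    J = np.ones((T, T))
    LL = np.outer(lam, lam)
    residuals = spec.growth.residuals
    n_theta = spec.growth.n_theta
    has_rho = spec.growth.has_rho

    def cov_fn(omega):
        psi00 = np.exp(omega[0])
        psi11 = np.exp(omega[1])
        Theta, theta_derivs, _ = _theta_block(
            omega[2:2 + n_theta], omega[-1] if has_rho else None, T, residuals)
        Sigma = psi00 * J + psi11 * LL + Theta
        derivs = [psi00 * J, psi11 * LL] + theta_derivs
        return Sigma, np.stack(derivs)

    return cov_fn, 2 + n_theta + (1 if has_rho else 0)


def _growth_side(m, x, covs, Y, labels, groups, spec, omega0=None, n_starts=3,
                 seed=0):
    lam = np.asarray(spec.growth.times, dtype=float)
    qcol = lam**2 * _QUAD_SCALE
    F, bases, layout = _mean_design(m, x, covs, groups, labels, spec, lam, qcol)
    stats = _compute_pattern_stats(Y, F)
    cov_fn, n_omega = _medmod_cov_fn(spec, lam)

    if omega0 is None:
        base_var = np.nanvar(Y[:, 0])
        base_var = base_var if np.isfinite(base_var) and base_var > 1 else 25.0
        omega0 = np.concatenate([
            [np.log(base_var / 2), np.log(0.01)],
            np.log(np.full(spec.growth.n_theta, base_var / 2)),
            [np.arctanh(0.2)] if spec.growth.has_rho else [],
        ])
        cold = True
    else:
        cold = False
        n_starts = 1
    bounds = [(_LOGVAR_LB, 12.0), (_LOGVAR_LB, 8.0)]
    bounds += [(np.log(1e-6), 12.0)] * spec.growth.n_theta
    if spec.growth.has_rho:
        bounds.append((np.arctanh(-0.99), np.arctanh(0.99)))

    res, beta, A = _fit_profiled(stats, bases, cov_fn, omega0, bounds,
                                 n_starts, seed, perturb=0.3 if cold else 0.0,
                                 ftol=1e-13 if cold else 1e-11)
    beta_cov = np.linalg.inv(A)
    return res, beta, beta_cov, layout, cov_fn


def _mediator_side(m, x, covs, labels, groups):
    a0, a, a_se, sigma, r2, ll, cov_coefs = [], [], [], [], [], [], []
    for g in groups:
        sel = labels == g
        if sel.sum() < 10:
            raise ValueError(f"group {g} has fewer than 10 cases")
        X = sm.add_constant(np.column_stack([x[sel]] + ([covs[sel]] if covs.shape[1] else [])))
        fit = sm.OLS(m[sel], X).fit()
        n_g = int(sel.sum())
        a0.append(fit.params[0])
        a.append(fit.params[1])
        a_se.append(fit.bse[1])
        s2 = float(fit.ssr / n_g)                        # ML variance
        sigma.append(np.sqrt(s2))
        r2.append(float(fit.rsquared))
        ll.append(-0.5 * n_g * (np.log(2 * np.pi * s2) + 1.0))
        cov_coefs.append(np.asarray(fit.params[2:]))
    return (np.array(a0), np.array(a), np.array(a_se), np.array(sigma),
            np.array(r2), float(np.sum(ll)), cov_coefs)


def fit_medmod(dataset: pd.DataFrame, labels, spec: MedModSpec | None = None,
               seed: int = 0, _warm: MedModFit | None = None) -> MedModFit:
    """Fit the latent-profile-moderated mediation model.

    ``labels`` are modal profile assignments (or the simulation-only true
    class); they are held fixed, i.e. classification uncertainty is not
    propagated. Moderation of the b- and c′-paths is always Wald-tested on
    a fully free fit; the reported primary coefficients follow the
    ``equal_b`` / ``equal_cprime`` constraints in ``spec``.
    """
    spec = spec or MedModSpec()
    for c in spec.covariates:
        if c not in dataset.columns:
            raise KeyError(f"unknown covariate column {c!r}")
    m, x, covs, Y, labels, n_dropped = _prepare(dataset, labels, spec)
    groups = tuple(int(g) for g in np.unique(labels))
    if len(groups) < 2:
        raise ValueError("need at least two profile groups")

    (a0_g, a_g, a_se_g, sigma_m_g, r2_m_g, ll_med, cov_coefs_m) = \
        _mediator_side(m, x, covs, labels, groups)

    # contrasts: group 2 − group 1 (first two groups)
    def _diff(vals, cov_block):
        d = float(vals[1] - vals[0])
        se = float(np.sqrt(cov_block[0, 0] + cov_block[1, 1] - 2 * cov_block[0, 1]))
        return d, se, 2 * norm.sf(abs(d / se)) if se > 0 else np.nan

    if _warm is None:
        # fully free fit for the moderation Wald tests
        free_spec = dataclasses.replace(spec, equal_b=False, equal_cprime=False)
        res_f, beta_f, cov_f, lay_f, _ = _growth_side(
            m, x, covs, Y, labels, groups, free_spec, seed=seed)
        b_idx = range(*lay_f["b"].indices(len(beta_f)))
        c_idx = range(*lay_f["cprime"].indices(len(beta_f)))
        b_diff, b_diff_se, b_diff_p = _diff(
            beta_f[lay_f["b"]], cov_f[np.ix_(b_idx, b_idx)])
        cprime_diff, cprime_diff_se, cprime_diff_p = _diff(
            beta_f[lay_f["cprime"]], cov_f[np.ix_(c_idx, c_idx)])
        omega_warm = res_f.x
    else:
        # bootstrap refit: moderation Wald tests are not resampled
        b_diff = b_diff_se = b_diff_p = np.nan
        cprime_diff = cprime_diff_se = cprime_diff_p = np.nan
        omega_warm = _warm._omega

    # primary fit under the MedModSpec equality constraints
    if spec.equal_b or spec.equal_cprime or _warm is not None:
        res, beta, beta_cov, layout, _ = _growth_side(
            m, x, covs, Y, labels, groups, spec,
            omega0=omega_warm, seed=seed)
    else:
        res, beta, beta_cov, layout = res_f, beta_f, cov_f, lay_f

    G = len(groups)
    b_vals = beta[layout["b"]]
    b_ses = np.sqrt(np.diag(beta_cov)[layout["b"]])
    c_vals = beta[layout["cprime"]]
    c_ses = np.sqrt(np.diag(beta_cov)[layout["cprime"]])
    b_g = np.repeat(b_vals, G) if spec.equal_b else b_vals
    b_se_g = np.repeat(b_ses, G) if spec.equal_b else b_ses
    cprime_g = np.repeat(c_vals, G) if spec.equal_cprime else c_vals
    cprime_se_g = np.repeat(c_ses, G) if spec.equal_cprime else c_ses

    omega = res.x
    psi00 = float(np.exp(omega[0]))
    psi11 = float(np.exp(omega[1]))
    n_theta = spec.growth.n_theta
    theta_t = np.exp(omega[2:2 + n_theta])
    if n_theta == 1:
        theta_t = np.repeat(theta_t, len(spec.growth.times))
    rho = float(np.tanh(omega[-1])) if spec.growth.has_rho else 0.0

    a_diff = float(a_g[1] - a_g[0])
    a_diff_se = float(np.hypot(a_se_g[0], a_se_g[1]))
    a_diff_p = 2 * norm.sf(abs(a_diff / a_diff_se)) if a_diff_se > 0 else np.nan

    ie_g = a_g * b_g
    index = float(ie_g[1] - ie_g[0])

    # slope-equation R² per group from model-implied variances
    r2_slope = []
    for k, g in enumerate(groups):
        sel = labels == g
        Z = np.column_stack([m[sel], x[sel]] + ([covs[sel]] if covs.shape[1] else []))
        coefs = np.concatenate([[b_g[k], cprime_g[k]],
                                beta[layout["cov"]][k::G] if covs.shape[1] else []])
        explained = float(coefs @ np.cov(Z, rowvar=False, ddof=0) @ coefs) \
            if Z.shape[1] > 1 else float(coefs[0] ** 2 * np.var(Z[:, 0]))
        total = explained + psi11
        if total <= 0:
            raise ZeroDivisionError("implied slope variance is zero")
        r2_slope.append(explained / total)

    loglik = float(ll_med - res.fun)

    return MedModFit(
        spec=spec, groups=groups,
        n_per_group=tuple(int((labels == g).sum()) for g in groups),
        a0_g=a0_g, a_g=a_g, a_se_g=a_se_g, sigma_m_g=sigma_m_g,
        a_diff=a_diff, a_diff_se=a_diff_se, a_diff_p=a_diff_p,
        alpha0_g=beta[layout["alpha0"]], beta0_g=beta[layout["beta0"]],
        b_g=b_g, b_se_g=b_se_g, cprime_g=cprime_g, cprime_se_g=cprime_se_g,
        alpha2=float(beta[layout["alpha2"]] * _QUAD_SCALE),
        psi00=psi00, psi11=psi11, theta_t=theta_t, rho=rho,
        b_diff=b_diff, b_diff_se=b_diff_se, b_diff_p=b_diff_p,
        cprime_diff=cprime_diff, cprime_diff_se=cprime_diff_se,
        cprime_diff_p=cprime_diff_p,
        ie_g=ie_g, index=index,
        r2_mediator_g=r2_m_g, r2_slope_g=np.array(r2_slope),
        loglik=loglik, converged=bool(res.success), n_dropped=n_dropped,
        covariate_coefs=dict(mediator=cov_coefs_m,
                             slope=beta[layout["cov"]].tolist()),
        _omega=omega,
    )


# -- derived quantities -------------------------------------------------------

def conditional_indirect_effects(fit: MedModFit) -> np.ndarray:
    """IE_g = a_g · b_g, in BDI-II points/month per arm contrast."""
    return fit.a_g * fit.b_g


def index_of_moderated_mediation(fit: MedModFit) -> float:
    """Difference of conditional indirect effects, IE₂ − IE₁ (two groups)."""
    if len(fit.groups) != 2:
        raise ValueError("index of moderated mediation requires exactly 2 groups")
    ie = conditional_indirect_effects(fit)
    return float(ie[1] - ie[0])


def projected_change(ie: float, months: float) -> float:
    """Expected outcome change over a horizon attributable to the mediated path."""
    if months < 0:
        raise ValueError("months must be >= 0")
    return float(ie * months)


def total_effect(dataset: pd.DataFrame, labels, spec: MedModSpec | None = None,
                 seed: int = 0) -> dict:
    """Total arm → slope effect c from the model refit without the mediator."""
    spec = spec or MedModSpec()
    m, x, covs, Y, labels, _ = _prepare(dataset, labels, spec)
    groups = tuple(int(g) for g in np.unique(labels))

    lam = np.asarray(spec.growth.times, dtype=float)
    qcol = lam**2 * _QUAD_SCALE
    # reuse the mean design with the mediator column zeroed out: the b
    # coefficient then multiplies a zero feature, so drop it by refitting a
    # design built on a constant-zero mediator and removing its column.
    totspec = dataclasses.replace(spec, equal_b=True, equal_cprime=True)
    F, bases, layout = _mean_design(np.zeros_like(m), x, covs, groups, labels,
                                    totspec, lam, qcol)
    keep = [i for i in range(bases.shape[2])
            if i != range(*layout["b"].indices(bases.shape[2]))[0]]
    bases = bases[:, :, keep]
    stats = _compute_pattern_stats(Y, F)
    cov_fn, _ = _medmod_cov_fn(totspec, lam)
    base_var = np.nanvar(Y[:, 0])
    base_var = base_var if np.isfinite(base_var) and base_var > 1 else 25.0
    omega0 = np.concatenate([
        [np.log(base_var / 2), np.log(0.01)],
        np.log(np.full(spec.growth.n_theta, base_var / 2)),
        [np.arctanh(0.2)] if spec.growth.has_rho else [],
    ])
    bounds = [(_LOGVAR_LB, 12.0), (_LOGVAR_LB, 8.0)]
    bounds += [(np.log(1e-6), 12.0)] * spec.growth.n_theta
    if spec.growth.has_rho:
        bounds.append((np.arctanh(-0.99), np.arctanh(0.99)))
    res, beta, A = _fit_profiled(stats, bases, cov_fn, omega0, bounds, 3, seed)
    beta_cov = np.linalg.inv(A)
    G = len(groups)
    c_idx = 2 * G          # after removing the b column, c′ slot holds c
    c = float(beta[c_idx])
    c_se = float(np.sqrt(beta_cov[c_idx, c_idx]))
    z = c / c_se if c_se > 0 else np.nan
    return dict(c=c, se=c_se, z=z, p=2 * norm.sf(abs(z)) if np.isfinite(z) else np.nan,
                loglik=float(-res.fun))


def adjust_covariates(spec: MedModSpec, covariates) -> MedModSpec:
    """Spec whose mediator and slope equations both include the covariates."""
    covariates = tuple(covariates)
    for c in covariates:
        if not isinstance(c, str) or not c:
            raise ValueError("covariates must be non-empty column names")
    if not covariates:
        return spec
    return dataclasses.replace(spec, covariates=spec.covariates + covariates)


def variance_explained(fit: MedModFit) -> pd.DataFrame:
    """Per-group R² for the mediator and slope equations."""
    rows = []
    for k, g in enumerate(fit.groups):
        rows.append(dict(group=g, r2_mediator=float(fit.r2_mediator_g[k]),
                         r2_slope=float(fit.r2_slope_g[k])))
    return pd.DataFrame(rows)


# -- percentile bootstrap -----------------------------------------------------

def _draw_quantities(fit: MedModFit) -> dict[str, float]:
    out = {}
    for k, g in enumerate(fit.groups):
        out[f"a{g}"] = float(fit.a_g[k])
        out[f"ie{g}"] = float(fit.ie_g[k])
    out["a_diff"] = fit.a_diff
    out["b"] = float(fit.b_g[0]) if fit.spec.equal_b else float(np.mean(fit.b_g))
    out["cprime"] = float(fit.cprime_g[0]) if fit.spec.equal_cprime else float(np.mean(fit.cprime_g))
    out["index"] = fit.index
    return out


def percentile_bounds(draws: np.ndarray, level: float = 0.95):
    """Percentile interval endpoints as order statistics of the draws."""
    srt = np.sort(draws)
    B = len(srt)
    alpha = (1.0 - level) / 2.0
    lo = srt[min(max(int(np.ceil(alpha * B - 1e-9)) - 1, 0), B - 1)]
    hi = srt[min(int(np.ceil((1.0 - alpha) * B - 1e-9)) - 1, B - 1)]
    return float(lo), float(hi)


def bootstrap_ci(dataset: pd.DataFrame, labels, spec: MedModSpec | None = None,
                 warn=None) -> BootstrapResult:
    """Nonparametric case-resampling bootstrap of the mediation quantities.

    Participants are resampled with replacement within arm (stratified);
    profile labels travel with the resampled cases. Each draw refits the
    full model warm-started at the original solution; failed draws are
    dropped and counted, and more than 10% failures aborts.
    """
    import warnings

    spec = spec or MedModSpec()
    B = spec.bootstrap_draws
    if B < 200:
        raise ValueError("need at least 200 draws for reporting")
    if B < 1000:
        warnings.warn("fewer than 1000 bootstrap draws", stacklevel=2)

    labels = np.asarray(labels)
    base_fit = fit_medmod(dataset, labels, spec)
    rng = np.random.default_rng(spec.bootstrap_seed)
    arm = dataset[spec.exposure].to_numpy()
    strata = [np.flatnonzero(arm == v) for v in np.unique(arm)] if spec.stratify \
        else [np.arange(len(dataset))]

    names = list(_draw_quantities(base_fit))
    draws = {k: [] for k in names}
    n_failed = 0
    for _ in range(B):
        idx = np.concatenate([rng.choice(s, size=len(s), replace=True) for s in strata])
        try:
            fit = fit_medmod(dataset.iloc[idx], labels[idx], spec, _warm=base_fit)
            if not fit.converged:
                raise RuntimeError("refit did not converge")
        except (RuntimeError, ValueError, np.linalg.LinAlgError):
            n_failed += 1
            if n_failed > 0.10 * B:
                raise RuntimeError(
                    f"bootstrap aborted: {n_failed} failed draws out of {B}")
            continue
        for k, v in _draw_quantities(fit).items():
            draws[k].append(v)

    draws = {k: np.asarray(v) for k, v in draws.items()}
    ci = {k: percentile_bounds(v) for k, v in draws.items()}
    significant = {k: not (lo <= 0.0 <= hi) for k, (lo, hi) in ci.items()}
    return BootstrapResult(B=B, seed=spec.bootstrap_seed, draws=draws, ci=ci,
                           significant=significant, n_failed=n_failed)
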