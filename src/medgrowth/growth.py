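"""Latent growth curve models for the six-occasion BDI-II series.

The repeated measures load on latent intercept/linear/quadratic factors
with fixed time loadings λ_t = (0, 3, 9, 12, 18, 24) months. Estimation is
full-information maximum likelihood (FIML): each participant contributes
the multivariate-normal log-density of their observed occasions under the
model-implied moments, which is valid under missingness at random.

Fitting profiles the mean parameters out analytically (they enter the
implied mean linearly, so for any covariance they have a closed-form GLS
solution) and maximises the resulting profile likelihood over covariance
parameters by quasi-Newton iteration with analytic gradients. Variance
parameters are log-transformed and the residual autocorrelation
tanh-transformed, so the implied covariance is positive definite at every
iterate. The squared-time loading column is internally scaled by 1/10 for
conditioning; reported quadratic quantities are on the natural
points/month² scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2, norm

from .simulate import BDI_COLUMNS, TIMES

_QUAD_SCALE = 0.1
_SHAPES = ("intercept", "linear", "quadratic")
_RESIDUALS = ("homoscedastic", "heteroscedastic", "heteroscedastic_ar1")
_FACTOR_NAMES = ("intercept", "slope", "quad")
_LOGVAR_LB = np.log(1e-4)  # variance floor 1e-8 on the SD-like chol diagonal


@dataclass(frozen=True)
class GrowthSpec:
    """Trajectory shape and residual structure of a latent growth curve model."""

    shape: str = "quadratic"
    residuals: str = "heteroscedastic_ar1"
    times: tuple[float, ...] = TIMES
    factor_variance_constraints: tuple[str, ...] = ()

    def __post_init__(self):
        if self.shape not in _SHAPES:
            raise ValueError(f"shape must be one of {_SHAPES}")
        if self.residuals not in _RESIDUALS:
            raise ValueError(f"residuals must be one of {_RESIDUALS}")
        for f in self.factor_variance_constraints:
            if f not in _FACTOR_NAMES:
                raise ValueError(f"unknown factor {f!r}")

    @property
    def n_factors(self) -> int:
        return _SHAPES.index(self.shape) + 1

    @property
    def factor_names(self) -> tuple[str, ...]:
        return _FACTOR_NAMES[: self.n_factors]

    @property
    def free_factors(self) -> tuple[str, ...]:
        return tuple(f for f in self.factor_names
                     if f not in self.factor_variance_constraints)

    def loadings(self) -> np.ndarray:
        """Natural-scale loading matrix Λ, one column per growth factor."""
        t = np.asarray(self.times, dtype=float)
        cols = [np.ones_like(t), t, t**2][: self.n_factors]
        return np.column_stack(cols)

    @property
    def n_theta(self) -> int:
        return 1 if self.residuals == "homoscedastic" else len(self.times)

    @property
    def has_rho(self) -> bool:
        return self.residuals == "heteroscedastic_ar1"


@dataclass
class GrowthParams:
    """Natural-scale parameters of a latent growth curve model."""

    alpha: np.ndarray     # factor means, length = spec.n_factors
    psi: np.ndarray       # factor covariance, (p, p)
    theta_t: np.ndarray   # residual variances, one per occasion
    rho: float = 0.0


@dataclass
class GrowthFit:
    spec: GrowthSpec
    alpha: np.ndarray
    alpha_se: np.ndarray
    psi: np.ndarray
    theta_t: np.ndarray
    rho: float
    loglik: float
    n_params: int
    aic: float
    bic: float
    n_cases: int
    converged: bool
    n_starts_used: int
    variance_tests: pd.DataFrame      # Wald tests of factor variances > 0
    boundary_flags: tuple[str, ...] = ()

    @property
    def params(self) -> GrowthParams:
        return GrowthParams(self.alpha, self.psi, self.theta_t, self.rho)


# -- implied moments ----------------------------------------------------------

def residual_matrix(theta_t, rho, n_occ=None) -> np.ndarray:
    """Θ with Θ_jk = sqrt(θ_j θ_k) ρ^|j−k| over occasion lag."""
    theta = np.atleast_1d(np.asarray(theta_t, dtype=float))
    if n_occ is not None and theta.size == 1:
        theta = np.repeat(theta, n_occ)
    sd = np.sqrt(theta)
    lag = np.abs(np.subtract.outer(np.arange(theta.size), np.arange(theta.size)))
    corr = np.where(lag == 0, 1.0, float(rho) ** lag)
    return np.outer(sd, sd) * corr


def implied_moments(params: GrowthParams, spec: GrowthSpec):
    """Model-implied mean vector Λα and covariance ΛΨΛᵀ + Θ."""
    lam = spec.loadings()
    psi = np.asarray(params.psi, dtype=float)
    if np.min(np.linalg.eigvalsh((psi + psi.T) / 2)) < -1e-10:
        raise ValueError("psi must be positive semi-definite")
    mu = lam @ np.asarray(params.alpha, dtype=float)
    rho = params.rho if spec.has_rho else 0.0
    theta = residual_matrix(params.theta_t, rho, n_occ=len(spec.times))
    return mu, lam @ psi @ lam.T + theta


# -- casewise FIML log-likelihood (reference implementation) ------------------

def _outcome_matrix(dataset) -> np.ndarray:
    if isinstance(dataset, pd.DataFrame):
        return dataset[BDI_COLUMNS].to_numpy(dtype=float)
    return np.asarray(dataset, dtype=float)


def fiml_loglik(params: GrowthParams, dataset, spec: GrowthSpec) -> float:
    """Sum over cases of the MVN log-density over each case's observed occasions."""
    Y = _outcome_matrix(dataset)
    mu, Sigma = implied_moments(params, spec)
    obs = np.isfinite(Y)
    if not obs.any(axis=1).all():
        raise ValueError("every case needs at least one observed occasion")
    total = 0.0
    for pattern, rows in _group_patterns(obs).items():
        ix = np.flatnonzero(np.asarray(pattern))
        sub = Y[np.ix_(rows, ix)]
        mu_p = mu[ix]
        S_p = Sigma[np.ix_(ix, ix)]
        try:
            L = np.linalg.cholesky(S_p)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError("singular implied sub-covariance") from exc
        dev = sub - mu_p
        z = np.linalg.solve(L, dev.T)
        logdet = 2.0 * np.log(np.diag(L)).sum()
        d = len(ix)
        total += float(
            -0.5 * (z**2).sum()
            - 0.5 * len(rows) * (d * np.log(2 * np.pi) + logdet)
        )
    return total


def _group_patterns(obs: np.ndarray) -> dict:
    patterns: dict[tuple, list[int]] = {}
    for i, row in enumerate(map(tuple, obs)):
        patterns.setdefault(row, []).append(i)
    return patterns


# -- patterned sufficient statistics and profiled likelihood engine -----------
# Shared with the moderated-mediation module: a Gaussian model
# y_i ~ N(X_i β, Σ_{pattern(i)}) with X_i = Σ_r F[i, r] · B_r for fixed basis
# matrices B_r. Per missingness pattern we precompute weighted sufficient
# statistics, so each likelihood evaluation loops over patterns, not cases.

@dataclass
class _PatternBlock:
    """Patterns sharing an observed-dimension count, stacked for batched linalg."""

    IX: np.ndarray        # (m, d) observed column indices per pattern
    n: np.ndarray         # (m,) weighted case counts
    Fss: np.ndarray       # (m, q, q) Σ w f fᵀ
    FY: np.ndarray        # (m, q, d) Σ w f ⊗ y_obs
    YY: np.ndarray        # (m, d, d) Σ w y yᵀ


def _compute_pattern_stats(Y, F, weights=None) -> list[_PatternBlock]:
    Y = np.asarray(Y, dtype=float)
    F = np.asarray(F, dtype=float)
    w = np.ones(len(Y)) if weights is None else np.asarray(weights, dtype=float)
    obs = np.isfinite(Y)
    by_dim: dict[int, list] = {}
    for pattern, rows in _group_patterns(obs).items():
        ix = np.flatnonzero(np.asarray(pattern))
        if ix.size == 0:
            continue
        rows = np.asarray(rows)
        wr = w[rows]
        if wr.sum() <= 0:
            continue
        Yp = Y[np.ix_(rows, ix)]
        Fp = F[rows]
        Fw = Fp * wr[:, None]
        by_dim.setdefault(ix.size, []).append(
            (ix, float(wr.sum()), Fw.T @ Fp, Fw.T @ Yp, (Yp * wr[:, None]).T @ Yp))
    blocks = []
    for d, items in by_dim.items():
        blocks.append(_PatternBlock(
            IX=np.stack([it[0] for it in items]),
            n=np.array([it[1] for it in items]),
            Fss=np.stack([it[2] for it in items]),
            FY=np.stack([it[3] for it in items]),
            YY=np.stack([it[4] for it in items]),
        ))
    return blocks


def _profiled_nll(omega, stats, bases, cov_fn, grad: bool = True):
    """Negative profile log-likelihood over covariance parameters.

    Mean coefficients are concentrated out by GLS; the gradient with respect
    to the covariance parameters is exact at the GLS optimum (envelope
    theorem), so no mean-parameter derivatives are needed. Patterns are
    processed in dimension-batched blocks.
    """
    Sigma, dSigma = cov_fn(omega)
    k = bases.shape[2]
    A = np.zeros((k, k))
    rhs = np.zeros(k)
    cache = []
    for bl in stats:
        S = Sigma[bl.IX[:, :, None], bl.IX[:, None, :]]          # (m, d, d)
        sign, logdet = np.linalg.slogdet(S)
        if np.any(sign <= 0):
            raise np.linalg.LinAlgError("implied sub-covariance not positive definite")
        Sinv = np.linalg.inv(S)
        B = bases[:, bl.IX, :].transpose(1, 0, 2, 3)             # (m, q, d, k)
        V = np.einsum("mde,mqek->mqdk", Sinv, B)                 # Σ⁻¹ B_r
        A += np.einsum("mrs,mrdk,msdl->kl", bl.Fss, B, V)
        rhs += np.einsum("mqdk,mqd->k", V, bl.FY)
        cache.append((bl, Sinv, logdet, B))
    try:
        beta = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("mean design is rank-deficient") from exc

    nll = 0.0
    g = np.zeros(len(omega)) if grad else None
    log2pi = np.log(2 * np.pi)
    for bl, Sinv, logdet, B in cache:
        d = bl.IX.shape[1]
        u = np.einsum("mqdk,k->mqd", B, beta)                    # per-feature means
        C = np.einsum("mrd,mre->mde", u, bl.FY)                  # Σ w μ yᵀ
        Q = np.einsum("mrs,mrd,mse->mde", bl.Fss, u, u)
        E = bl.YY - C - C.transpose(0, 2, 1) + Q                 # scatter at β̂
        SiE = np.einsum("mde,mef->mdf", Sinv, E)
        tr = np.einsum("mdd->m", SiE)
        nll += 0.5 * float(np.sum(bl.n * (d * log2pi + logdet) + tr))
        if grad:
            R = np.einsum("mdf,mfe->mde", SiE, Sinv) - bl.n[:, None, None] * Sinv
            dS = dSigma[:, bl.IX[:, :, None], bl.IX[:, None, :]]  # (j, m, d, d)
            g += -0.5 * np.einsum("mab,jmab->j", R, dS)
    return (nll, g, beta, A) if grad else (nll, None, beta, A)


def _fit_profiled(stats, bases, cov_fn, omega0, bounds, n_starts, seed,
                  perturb=0.3, maxiter=500, ftol=1e-15, gtol=1e-8):
    """Multi-start quasi-Newton maximisation of the profiled likelihood."""
    rng = np.random.default_rng(seed)

    def objective(om):
        try:
            nll, g, _, _ = _profiled_nll(om, stats, bases, cov_fn)
        except np.linalg.LinAlgError:
            return 1e12, np.zeros_like(om)
        if not np.isfinite(nll):
            return 1e12, np.zeros_like(om)
        return nll, g

    best = None
    starts = [np.asarray(omega0, dtype=float)]
    for _ in range(n_starts - 1):
        starts.append(omega0 + perturb * rng.standard_normal(len(omega0)))
    for om0 in starts:
        res = optimize.minimize(
            objective, om0, jac=True, method="L-BFGS-B", bounds=bounds,
            options=dict(maxiter=maxiter, ftol=ftol, gtol=gtol),
        )
        if best is None or res.fun < best.fun:
            best = res
    nll, _, beta, A = _profiled_nll(best.x, stats, bases, cov_fn)
    return best, beta, A


# -- covariance builders ------------------------------------------------------

def _theta_block(omega_theta, rho_raw, n_occ, residuals):
    """Residual covariance and its derivative stack w.r.t. transformed params."""
    derivs = []
    if residuals == "homoscedastic":
        theta = np.exp(omega_theta[0])
        Theta = theta * np.eye(n_occ)
        derivs.append(Theta.copy())
        rho = 0.0
    else:
        theta = np.exp(omega_theta)
        rho = np.tanh(rho_raw) if rho_raw is not None else 0.0
        Theta = residual_matrix(theta, rho)
        for j in range(n_occ):
            D = np.zeros((n_occ, n_occ))
            D[j, :] += 0.5 * Theta[j, :]
            D[:, j] += 0.5 * Theta[:, j]
            derivs.append(D)
        if rho_raw is not None:
            lag = np.abs(np.subtract.outer(np.arange(n_occ), np.arange(n_occ)))
            sd = np.sqrt(theta)
            with np.errstate(divide="ignore", invalid="ignore"):
                G = np.where(lag >= 1, lag * float(rho) ** np.clip(lag - 1, 0, None), 0.0)
            D = np.outer(sd, sd) * G * (1.0 - rho**2)
            derivs.append(D)
    return Theta, derivs, rho


def _growth_cov_fn(spec: GrowthSpec, lam_scaled, free_idx):
    """Return cov_fn(omega) -> (Σ, dΣ stack) for an unconditional growth model."""
    n_occ = len(spec.times)
    pf = len(free_idx)
    n_chol = pf * (pf + 1) // 2
    tril = list(zip(*np.tril_indices(pf)))
    Lam_f = lam_scaled[:, free_idx]

    def cov_fn(omega):
        Lmat = np.zeros((pf, pf))
        for (a, b), w in zip(tril, omega[:n_chol]):
            Lmat[a, b] = np.exp(w) if a == b else w
        Theta, theta_derivs, _ = _theta_block(
            omega[n_chol:n_chol + spec.n_theta],
            omega[-1] if spec.has_rho else None,
            n_occ, spec.residuals,
        )
        Sigma = Lam_f @ Lmat @ Lmat.T @ Lam_f.T + Theta
        derivs = []
        for (a, b) in tril:
            u = Lam_f[:, a]
            v = Lam_f @ Lmat[:, b]
            D = np.outer(u, v) + np.outer(v, u)
            if a == b:
                D = D * Lmat[a, a]
            derivs.append(D)
        derivs.extend(theta_derivs)
        return Sigma, np.stack(derivs)

    return cov_fn, n_chol, tril


def _chol_to_psi(omega, tril, n_chol, pf):
    Lmat = np.zeros((pf, pf))
    for (a, b), w in zip(tril, omega[:n_chol]):
        Lmat[a, b] = np.exp(w) if a == b else w
    return Lmat @ Lmat.T


# -- fitting ------------------------------------------------------------------

def fit_lgcm(dataset, spec: GrowthSpec, n_starts: int = 5, seed: int = 0,
             max_iter: int = 500) -> GrowthFit:
    """Fit a latent growth curve model by profiled FIML.

    Reports Wald tests of each free factor variance against zero (delta
    method on the transformed parameters; two-sided normal reference —
    conservative at the boundary) so non-significant variances can be
    refit fixed to zero via ``spec.factor_variance_constraints``.
    """
    Y = _outcome_matrix(dataset)
    keep = np.isfinite(Y).any(axis=1)
    Y = Y[keep]
    n = len(Y)
    if n < 10:
        raise ValueError("need at least 10 cases with observed outcomes")

    p = spec.n_factors
    scales = np.array([1.0, 1.0, _QUAD_SCALE][:p])
    lam_scaled = spec.loadings() * scales
    free_idx = [i for i, f in enumerate(spec.factor_names) if f in spec.free_factors]
    if not free_idx:
        raise ValueError("at least one factor variance must be free")

    F = np.ones((n, 1))
    bases = lam_scaled[None, :, :]                 # q=1, (T, k=p)
    stats = _compute_pattern_stats(Y, F)

    cov_fn, n_chol, tril = _growth_cov_fn(spec, lam_scaled, free_idx)

    # moment-based starting values
    base_var = np.nanvar(Y[:, 0]) if np.isfinite(Y[:, 0]).any() else 25.0
    omega0 = []
    for (a, b) in tril:
        omega0.append(0.5 * np.log(max(base_var / 2, 1e-2)) if a == b == 0
                      else (np.log(0.1) if a == b else 0.0))
    wave_var = np.nanvar(Y, axis=0)
    wave_var = np.where(np.isfinite(wave_var) & (wave_var > 0), wave_var, base_var)
    if spec.residuals == "homoscedastic":
        omega0.append(float(np.log(np.mean(wave_var) / 2)))
    else:
        omega0.extend(np.log(wave_var / 2))
    if spec.has_rho:
        omega0.append(np.arctanh(0.2))
    omega0 = np.asarray(omega0)

    bounds = []
    for i, (a, b) in enumerate(tril):
        bounds.append((_LOGVAR_LB, 10.0) if a == b else (-50.0, 50.0))
    bounds += [(np.log(1e-6), 12.0)] * spec.n_theta
    if spec.has_rho:
        bounds.append((np.arctanh(-0.99), np.arctanh(0.99)))

    res, beta, A = _fit_profiled(stats, bases, cov_fn, omega0, bounds,
                                 n_starts, seed, maxiter=max_iter)
    omega = res.x

    # back-transform
    psi_free = _chol_to_psi(omega, tril, n_chol, len(free_idx))
    psi_scaled = np.zeros((p, p))
    psi_scaled[np.ix_(free_idx, free_idx)] = psi_free
    psi = psi_scaled * np.outer(scales, scales)
    if spec.residuals == "homoscedastic":
        theta_t = np.repeat(np.exp(omega[n_chol]), len(spec.times))
    else:
        theta_t = np.exp(omega[n_chol:n_chol + spec.n_theta])
    rho = float(np.tanh(omega[-1])) if spec.has_rho else 0.0
    alpha = beta * scales
    alpha_cov = np.linalg.inv(A)
    alpha_se = np.sqrt(np.diag(alpha_cov)) * scales

    loglik = -res.fun
    n_params = p + n_chol + spec.n_theta + (1 if spec.has_rho else 0)

    variance_tests, boundary = _variance_walds(
        omega, stats, bases, cov_fn, tril, n_chol, free_idx, spec, scales)

    return GrowthFit(
        spec=spec, alpha=alpha, alpha_se=alpha_se, psi=psi, theta_t=theta_t,
        rho=rho, loglik=loglik, n_params=n_params,
        aic=2 * n_params - 2 * loglik, bic=n_params * np.log(n) - 2 * loglik,
        n_cases=n, converged=bool(res.success), n_starts_used=n_starts,
        variance_tests=variance_tests, boundary_flags=tuple(boundary),
    )


def _variance_walds(omega, stats, bases, cov_fn, tril, n_chol, free_idx, spec,
                    scales):
    """Delta-method Wald tests for each free factor variance."""
    pf = len(free_idx)
    try:
        H = _numerical_hessian(
            lambda om: _profiled_nll(om, stats, bases, cov_fn, grad=False)[0], omega)
        cov = np.linalg.pinv(H)
    except np.linalg.LinAlgError:
        cov = np.full((len(omega), len(omega)), np.nan)
    rows, boundary = [], []
    for fi, factor_pos in enumerate(free_idx):
        name = spec.factor_names[factor_pos]
        def psi_ff(om, fi=fi):
            return _chol_to_psi(om, tril, n_chol, pf)[fi, fi]
        est = psi_ff(omega) * scales[factor_pos] ** 2
        grad = _numerical_gradient(psi_ff, omega) * scales[factor_pos] ** 2
        var = float(grad @ cov @ grad)
        se = np.sqrt(var) if var > 0 else np.nan
        at_bound = est < 1e-6
        if at_bound:
            boundary.append(name)
            est = 0.0
        z = est / se if se and np.isfinite(se) and se > 0 else np.nan
        rows.append(dict(factor=name, variance=est, se=se, z=z,
                         p=2 * norm.sf(abs(z)) if np.isfinite(z) else np.nan,
                         boundary=at_bound))
    return pd.DataFrame(rows), boundary


def _numerical_gradient(fn, x, h=1e-5):
    g = np.zeros(len(x))
    for i in range(len(x)):
        e = np.zeros(len(x)); e[i] = h
        g[i] = (fn(x + e) - fn(x - e)) / (2 * h)
    return g


def _numerical_hessian(fn, x, h=1e-4):
    k = len(x)
    H = np.zeros((k, k))
    f0 = fn(x)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h
            ej = np.zeros(k); ej[j] = h
            H[i, j] = H[j, i] = (
                fn(x + ei + ej) - fn(x + ei - ej) - fn(x - ei + ej) + fn(x - ei - ej)
            ) / (4 * h * h)
    return H


# -- model comparison ---------------------------------------------------------

def _nested(a: GrowthSpec, b: GrowthSpec) -> bool:
    """True when model a is nested in model b."""
    if a.times != b.times:
        return False
    shape_ok = _SHAPES.index(a.shape) <= _SHAPES.index(b.shape)
    resid_ok = _RESIDUALS.index(a.residuals) <= _RESIDUALS.index(b.residuals)
    free_ok = set(a.free_factors) <= set(b.free_factors)
    return shape_ok and resid_ok and free_ok


def compare_models(fits: list[GrowthFit]) -> pd.DataFrame:
    """Information criteria plus likelihood-ratio tests for nested pairs.

    The LRT χ² uses df = Δ(number of parameters); when the smaller model
    fixes variance parameters on the boundary of the larger model's space
    the χ² reference is conservative.
    """
    rows = []
    for i, fit in enumerate(fits):
        row = dict(
            model=f"{fit.spec.shape}/{fit.spec.residuals}",
            loglik=fit.loglik, n_params=fit.n_params,
            aic=fit.aic, bic=fit.bic,
            lrt_vs=None, lrt_stat=np.nan, lrt_df=np.nan, lrt_p=np.nan,
        )
        # LRT against the largest preceding model this one nests, or vice versa
        for j in range(i - 1, -1, -1):
            small, big = (fits[j], fit) if _nested(fits[j].spec, fit.spec) else \
                         ((fit, fits[j]) if _nested(fit.spec, fits[j].spec) else (None, None))
            if small is None:
                continue
            stat = max(2.0 * (big.loglik - small.loglik), 0.0)
            df = big.n_params - small.n_params
            row["lrt_vs"] = f"{fits[j].spec.shape}/{fits[j].spec.residuals}"
            row["lrt_stat"] = stat
            row["lrt_df"] = df
            row["lrt_p"] = float(chi2.sf(stat, df)) if df > 0 else (1.0 if stat == 0 else 0.0)
            break
        rows.append(row)
    table = pd.DataFrame(rows)
    best = table["bic"].idxmin()
    table["best_bic"] = False
    table.loc[best, "best_bic"] = True
    return table
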