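"""Latent profile analysis over a mixed continuous/binary indicator battery.

Finite-mixture model with class-specific means for continuous indicators,
variances shared across classes (local independence), and class-specific
Bernoulli probabilities for binary indicators. Estimated by EM with
multiple random starts; per-case missing indicator entries are handled by
taking the casewise likelihood over observed entries only, consistent with
full-information maximum likelihood under missingness at random.

Class labels follow a fixed convention: classes are sorted ascending by
the mean of the first continuous indicator (a symptom-intensity marker),
so "class 2" is the higher-severity profile. Labels are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .simulate import BINARY_INDICATOR, INDICATOR_COLUMNS

_PROB_FLOOR = 1e-4  # Bernoulli probabilities bounded away from {0, 1}
_VAR_FLOOR = 1e-8


@dataclass
class ProfileModel:
    """A fitted K-class latent profile solution."""

    K: int
    weights: np.ndarray               # (K,)
    means: np.ndarray                 # (K, J_cont)
    variances: np.ndarray             # (J_cont,) shared across classes
    probs: np.ndarray                 # (K, J_bin)
    continuous_cols: list[str]
    binary_cols: list[str]
    loglik: float
    n_params: int
    aic: float
    bic: float
    entropy_rel: float
    posteriors: np.ndarray            # (n, K)
    converged: bool
    n_iter: int
    loglik_history: np.ndarray = field(repr=False, default=None)
    degenerate_classes: tuple[int, ...] = ()

    @property
    def smallest_class_fraction(self) -> float:
        return float(np.min(self.weights))


def _split_columns(indicators: pd.DataFrame, binary_cols=None):
    if binary_cols is None:
        binary_cols = [c for c in indicators.columns if c == BINARY_INDICATOR]
    binary_cols = list(binary_cols)
    continuous_cols = [c for c in indicators.columns if c not in binary_cols]
    return continuous_cols, binary_cols


def _case_log_densities(Xc, Mc, Xb, Mb, means, variances, probs):
    """n×K matrix of casewise class-conditional log-densities over observed entries."""
    n = Xc.shape[0]
    K = means.shape[0]
    out = np.zeros((n, K))
    if Xc.shape[1]:
        inv_var = 1.0 / variances
        log_norm = np.log(2.0 * np.pi * variances)
        Xc0 = np.where(Mc, Xc, 0.0)
        for k in range(K):
            d = Xc0 - means[k]
            ll = -0.5 * (d * d * inv_var + log_norm)
            out[:, k] += np.where(Mc, ll, 0.0).sum(axis=1)
    if Xb.shape[1]:
        Xb0 = np.where(Mb, Xb, 0.0)
        for k in range(K):
            p = probs[k]
            ll = Xb0 * np.log(p) + (1.0 - Xb0) * np.log1p(-p)
            out[:, k] += np.where(Mb, ll, 0.0).sum(axis=1)
    return out


def _em_once(Xc, Mc, Xb, Mb, K, max_iter, tol, rng):
    n = Xc.shape[0]
    Jc, Jb = Xc.shape[1], Xb.shape[1]

    # random-responsibility initialisation
    resp = rng.dirichlet(np.ones(K), size=n)
    weights = resp.mean(axis=0)
    means, variances, probs = _m_step(Xc, Mc, Xb, Mb, resp)

    history = []
    prev = -np.inf
    converged = False
    for it in range(1, max_iter + 1):
        logdens = _case_log_densities(Xc, Mc, Xb, Mb, means, variances, probs)
        joint = logdens + np.log(weights)
        case_ll = logsumexp(joint, axis=1)
        loglik = float(case_ll.sum())
        # EM ascent property: guaranteed analytically, asserted numerically
        if loglik < prev - 1e-8 * max(1.0, abs(prev)):
            raise RuntimeError(f"EM log-likelihood decreased at iteration {it}")
        history.append(loglik)
        resp = np.exp(joint - case_ll[:, None])
        if prev > -np.inf and (loglik - prev) <= tol * abs(loglik):
            converged = True
            prev = loglik
            break
        prev = loglik
        weights = resp.mean(axis=0)
        weights = np.clip(weights, 1e-12, None)
        weights /= weights.sum()
        means, variances, probs = _m_step(Xc, Mc, Xb, Mb, resp)
    return dict(
        weights=weights, means=means, variances=variances, probs=probs,
        loglik=prev, resp=resp, converged=converged, n_iter=len(history),
        history=np.asarray(history),
    )


def _m_step(Xc, Mc, Xb, Mb, resp):
    K = resp.shape[1]
    Jc, Jb = Xc.shape[1], Xb.shape[1]
    means = np.zeros((K, Jc))
    variances = np.ones(Jc)
    probs = np.full((K, Jb), 0.5)
    if Jc:
        Xc0 = np.where(Mc, Xc, 0.0)
        sq = np.zeros(Jc)
        denom_tot = Mc.sum(axis=0).astype(float)
        for k in range(K):
            w = resp[:, k][:, None] * Mc
            denom = np.clip(w.sum(axis=0), 1e-12, None)
            means[k] = (resp[:, k][:, None] * Xc0).sum(axis=0) / denom
            d = Xc0 - means[k]
            sq += np.where(Mc, resp[:, k][:, None] * d * d, 0.0).sum(axis=0)
        variances = np.clip(sq / np.clip(denom_tot, 1e-12, None), _VAR_FLOOR, None)
    if Jb:
        Xb0 = np.where(Mb, Xb, 0.0)
        for k in range(K):
            w = resp[:, k][:, None] * Mb
            denom = np.clip(w.sum(axis=0), 1e-12, None)
            probs[k] = (resp[:, k][:, None] * Xb0).sum(axis=0) / denom
        probs = np.clip(probs, _PROB_FLOOR, 1.0 - _PROB_FLOOR)
    return means, variances, probs


def fit_lpa(
    indicators: pd.DataFrame,
    K: int,
    binary_cols=None,
    n_starts: int = 20,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
) -> ProfileModel:
    """Fit a K-class latent profile model by EM, best of ``n_starts`` starts.

    Parameters
    ----------
    indicators
        Data frame of baseline indicators only (continuous plus binary).
    K
        Number of latent classes, >= 1.
    binary_cols
        Names of binary columns; defaults to the standard battery's single
        binary indicator when present.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    continuous_cols, binary_cols = _split_columns(indicators, binary_cols)
    Xc = indicators[continuous_cols].to_numpy(dtype=float)
    Xb = indicators[binary_cols].to_numpy(dtype=float)
    Mc, Mb = np.isfinite(Xc), np.isfinite(Xb)
    n = len(indicators)
    if n < K:
        raise ValueError("need at least K rows")

    rng = np.random.default_rng(seed)
    best = None
    failures = []
    n_starts = 1 if K == 1 else n_starts
    for _ in range(n_starts):
        try:
            res = _em_once(Xc, Mc, Xb, Mb, K, max_iter, tol, rng)
        except (RuntimeError, FloatingPointError) as exc:  # pragma: no cover
            failures.append(str(exc))
            continue
        if best is None or res["loglik"] > best["loglik"]:
            best = res
    if best is None:
        raise RuntimeError(f"all {n_starts} EM starts failed: {failures[:3]}")
    if not best["converged"]:
        raise RuntimeError(f"EM did not converge within {max_iter} iterations")

    # label-switching convention: ascending mean of the first continuous indicator
    order = np.argsort(best["means"][:, 0]) if continuous_cols else np.arange(K)
    weights = best["weights"][order]
    means = best["means"][order]
    probs = best["probs"][order]
    posteriors = best["resp"][:, order]

    n_params = (K - 1) + K * len(continuous_cols) + len(continuous_cols) + K * len(binary_cols)
    loglik = best["loglik"]
    entropy = relative_entropy(posteriors) if K >= 2 else 1.0
    degenerate = tuple(int(k + 1) for k in np.flatnonzero(weights < 1.0 / n))
    return ProfileModel(
        K=K,
        weights=weights,
        means=means,
        variances=best["variances"],
        probs=probs,
        continuous_cols=continuous_cols,
        binary_cols=binary_cols,
        loglik=loglik,
        n_params=n_params,
        aic=2 * n_params - 2 * loglik,
        bic=n_params * np.log(n) - 2 * loglik,
        entropy_rel=entropy,
        posteriors=posteriors,
        converged=best["converged"],
        n_iter=best["n_iter"],
        loglik_history=best["history"],
        degenerate_classes=degenerate,
    )


def loglik_at(model: ProfileModel, indicators: pd.DataFrame) -> float:
    """Direct evaluation of Σ_i log Σ_k π_k f_k(x_i) at the fitted parameters."""
    Xc = indicators[model.continuous_cols].to_numpy(dtype=float)
    Xb = indicators[model.binary_cols].to_numpy(dtype=float)
    logdens = _case_log_densities(
        Xc, np.isfinite(Xc), Xb, np.isfinite(Xb),
        model.means, model.variances, model.probs,
    )
    return float(logsumexp(logdens + np.log(model.weights), axis=1).sum())


def select_profiles(
    indicators: pd.DataFrame,
    K_max: int,
    binary_cols=None,
    n_starts: int = 20,
    seed: int = 0,
    **fit_kwargs,
) -> pd.DataFrame:
    """Fit K = 1..K_max models and tabulate fit indices; flags the BIC minimiser."""
    if K_max < 2:
        raise ValueError("K_max must be >= 2")
    rows = []
    models = {}
    for K in range(1, K_max + 1):
        try:
            m = fit_lpa(indicators, K, binary_cols=binary_cols,
                        n_starts=n_starts, seed=seed + K, **fit_kwargs)
            models[K] = m
            rows.append(dict(
                K=K, loglik=m.loglik, n_params=m.n_params, aic=m.aic, bic=m.bic,
                entropy_rel=m.entropy_rel,
                smallest_class_fraction=m.smallest_class_fraction,
                error="",
            ))
        except RuntimeError as exc:
            rows.append(dict(K=K, loglik=np.nan, n_params=np.nan, aic=np.nan,
                             bic=np.nan, entropy_rel=np.nan,
                             smallest_class_fraction=np.nan, error=str(exc)))
    table = pd.DataFrame(rows)
    best_bic = table["bic"].idxmin()
    table["best_bic"] = False
    table.loc[best_bic, "best_bic"] = True
    table.attrs["models"] = models
    return table


def relative_entropy(posteriors: np.ndarray) -> float:
    """Normalised classification-certainty diagnostic, 1 − H/(n ln K) ∈ [0, 1]."""
    P = np.asarray(posteriors, dtype=float)
    n, K = P.shape
    if K < 2:
        raise ValueError("relative entropy requires K >= 2")
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("posterior rows must sum to 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(P > 0, -P * np.log(P), 0.0)
    return float(1.0 - terms.sum() / (n * np.log(K)))


def modal_assignment(posteriors: np.ndarray) -> np.ndarray:
    """Most-probable class per row (1-based); ties break toward the lower index."""
    P = np.asarray(posteriors, dtype=float)
    return np.argmax(P, axis=1) + 1


def profile_zscores(model: ProfileModel, indicators: pd.DataFrame) -> pd.DataFrame:
    """Class-specific indicator means on a pooled z-score scale (plot-ready).

    Continuous indicators standardise class means by the pooled sample mean
    and SD; binary indicators put class proportions on the same scale using
    the pooled proportion and its Bernoulli SD.
    """
    rows = []
    for j, col in enumerate(model.continuous_cols):
        x = indicators[col].to_numpy(dtype=float)
        x = x[np.isfinite(x)]
        mu, sd = float(np.mean(x)), float(np.std(x, ddof=0))
        if sd <= 0:
            raise ValueError(f"indicator {col!r} has zero variance")
        for k in range(model.K):
            rows.append(dict(indicator=col, kind="continuous", class_=k + 1,
                             class_value=model.means[k, j],
                             z=(model.means[k, j] - mu) / sd))
    for j, col in enumerate(model.binary_cols):
        x = indicators[col].to_numpy(dtype=float)
        x = x[np.isfinite(x)]
        p = float(np.mean(x))
        sd = float(np.sqrt(p * (1 - p)))
        if sd <= 0:
            raise ValueError(f"indicator {col!r} has zero variance")
        for k in range(model.K):
            rows.append(dict(indicator=col, kind="binary", class_=k + 1,
                             class_value=model.probs[k, j],
                             z=(model.probs[k, j] - p) / sd))
    return pd.DataFrame(rows)


def compare_distal(dataset: pd.DataFrame, labels, distal_columns,
                   binary_cols=()) -> pd.DataFrame:
    """Effect sizes for distal variables across two modal classes.

    Continuous columns get a pooled-SD standardised mean difference
    (Cohen's d, class 2 minus class 1) with a normal-theory 95% CI; binary
    columns get an odds ratio with a Woolf-type CI. Distal variables never
    enter the mixture likelihood.
    """
    import statsmodels.api as sm

    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("compare_distal requires exactly two classes")
    rows = []
    for col in distal_columns:
        x = dataset[col].to_numpy(dtype=float)
        g1 = x[(labels == classes[0]) & np.isfinite(x)]
        g2 = x[(labels == classes[1]) & np.isfinite(x)]
        if len(g1) < 2 or len(g2) < 2:
            raise ValueError(f"need >= 2 observed cases per class for {col!r}")
        n1, n2 = len(g1), len(g2)
        if col in binary_cols:
            tab = np.array([
                [np.sum(g2 == 1), np.sum(g2 == 0)],
                [np.sum(g1 == 1), np.sum(g1 == 0)],
            ]) + 0.5  # Haldane correction
            t22 = sm.stats.Table2x2(tab)
            rows.append(dict(column=col, measure="odds_ratio",
                             estimate=t22.oddsratio,
                             ci_low=t22.oddsratio_confint()[0],
                             ci_high=t22.oddsratio_confint()[1],
                             n1=n1, n2=n2))
        else:
            sp = np.sqrt(((n1 - 1) * np.var(g1, ddof=1) + (n2 - 1) * np.var(g2, ddof=1))
                         / (n1 + n2 - 2))
            d = (np.mean(g2) - np.mean(g1)) / sp
            se = np.sqrt((n1 + n2) / (n1 * n2) + d**2 / (2 * (n1 + n2)))
            rows.append(dict(column=col, measure="cohens_d", estimate=d,
                             ci_low=d - 1.959963984540054 * se,
                             ci_high=d + 1.959963984540054 * se,
                             n1=n1, n2=n2))
    return pd.DataFrame(rows)


def indicator_frame(dataset: pd.DataFrame) -> pd.DataFrame:
    """Slice the standard indicator battery out of a wide trial table."""
    return dataset[INDICATOR_COLUMNS]
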