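"""Synthetic two-arm trial generator.

Emulates the statistical structure the downstream analysis chain assumes:
a two-class latent profile over a baseline indicator battery, an
arm -> mindfulness-skills-change (ΔFFMQ) effect that differs by class,
a ΔFFMQ -> linear-slope effect on the latent depressive-symptom trajectory,
a quadratic latent growth curve for BDI-II over six occasions with
heteroscedastic lag-correlated residuals, and per-wave missingness at
printed follow-up retention rates.

Latent quantities are never truncated; observed BDI-II totals are rounded
to integers and clipped to the instrument range [0, 63] at the observation
step only.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: BDI-II assessment occasions, months since randomisation.
TIMES = (0.0, 3.0, 9.0, 12.0, 18.0, 24.0)

#: BDI-II instrument range.
BDI_MIN, BDI_MAX = 0, 63

#: Continuous baseline profile indicators (name -> (mean class 1, mean class 2, shared SD)).
#: Class 2 ("higher severity") is worse on symptom/history/rumination/stigma
#: indicators by a moderate-to-large margin and mildly worse elsewhere.
CONTINUOUS_INDICATORS: dict[str, tuple[float, float, float]] = {
    "hamd": (4.0, 7.0, 3.0),
    "mops_abuse": (5.0, 10.0, 5.0),
    "age_onset": (25.0, 22.0, 10.0),
    "n_prev_episodes": (5.0, 8.5, 3.5),
    "last_episode_severity": (6.4, 7.0, 1.1),
    "chronicity_months": (6.0, 9.0, 8.0),
    "n_comorbid": (0.5, 0.9, 0.9),
    "rum_negative": (20.0, 27.0, 7.0),
    "rum_unresolved": (14.0, 20.0, 6.0),
    "self_blame": (8.0, 12.5, 4.5),
    "lack_acceptance": (9.0, 11.0, 4.5),
    "early_warning": (5.0, 4.7, 1.5),
    "act_awareness": (26.0, 24.0, 6.0),
    "self_efficacy": (30.0, 28.0, 5.5),
    "contentment": (4.5, 4.1, 1.2),
    "joy": (4.8, 4.5, 1.2),
    "relationship_satisfaction": (28.0, 26.0, 7.0),
    "stigmatisation": (18.0, 24.0, 6.0),
}

#: The single binary indicator: previous suicide attempt.
BINARY_INDICATOR = "suicide_attempt"

INDICATOR_COLUMNS = list(CONTINUOUS_INDICATORS) + [BINARY_INDICATOR]

#: Distal quality-of-life column (never used to form profiles).
DISTAL_COLUMN = "qol"

BDI_COLUMNS = [f"bdi_m{int(t)}" for t in TIMES]


@dataclass
class SimulationConfig:
    """Generating parameters for a synthetic trial.

    Defaults are calibrated to the printed quantities of the source trial
    where those exist (class intercepts, growth-factor means, conditional
    a-paths, retention); everything else is a documented realistic choice.
    """

    n: int = 424
    pi2: float = 0.5
    indicator_means: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {k: (v[0], v[1]) for k, v in CONTINUOUS_INDICATORS.items()}
    )
    indicator_sds: dict[str, float] = field(
        default_factory=lambda: {k: v[2] for k, v in CONTINUOUS_INDICATORS.items()}
    )
    binary_probs: tuple[float, float] = (0.15, 0.40)
    # growth-factor means: intercept per class; linear and quadratic shared
    alpha0_g: tuple[float, float] = (10.71, 19.37)
    alpha1: float = -0.30
    alpha2: float = 0.01
    # factor covariance: intercept variance is the only nonzero entry by default
    psi: np.ndarray = field(default_factory=lambda: np.diag([16.0, 0.0, 0.0]))
    # mediator equation: delta_ffmq = a0_g + a_g * arm + N(0, sigma_m^2)
    a0_g: tuple[float, float] = (0.0, 0.0)
    a_g: tuple[float, float] = (5.03, 13.87)
    sigma_m: float = 5.0
    # structural slope equation: eta1 += b_g * delta_ffmq + cprime_g * arm + N(0, sigma_slope^2)
    b_g: tuple[float, float] = (-0.03, -0.03)
    cprime_g: tuple[float, float] = (0.37, 0.37)
    sigma_slope: float = 0.08
    # residual structure: six variances, lag-power correlation over occasion index
    theta_t: tuple[float, ...] = (9.0, 10.0, 12.0, 12.0, 14.0, 16.0)
    rho: float = 0.3
    # follow-up retention probabilities for months 3, 9, 12, 18, 24
    retention_t: tuple[float, ...] = (0.821, 0.691, 0.764, 0.686, 0.793)
    # mean FFMQ total at baseline and its SD (pre score; post = pre + delta)
    ffmq_pre_mean: float = 120.0
    ffmq_pre_sd: float = 15.0
    # distal quality of life (mean class 1, mean class 2, shared SD)
    qol: tuple[float, float, float] = (60.0, 53.0, 11.0)
    # arm-conditional covariate distributions
    practice_probs: tuple[tuple[float, ...], tuple[float, ...]] = (
        (0.892, 0.050, 0.040, 0.018),  # m-ADM arm
        (0.339, 0.220, 0.221, 0.220),  # MBCT-tapering-support arm
    )
    adm_discontinued_probs: tuple[float, float] = (0.236, 0.627)
    seed: int = 0

    def validate(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if not 0.0 <= self.pi2 <= 1.0:
            raise ValueError("pi2 must lie in [0, 1]")
        if len(self.theta_t) != len(TIMES):
            raise ValueError(f"theta_t must have length {len(TIMES)}")
        if any(t < 0 for t in self.theta_t) or self.sigma_m < 0 or self.sigma_slope < 0:
            raise ValueError("variances and SDs must be non-negative")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [-1, 1]")
        if len(self.retention_t) != len(TIMES) - 1:
            raise ValueError(f"retention_t must have length {len(TIMES) - 1}")
        if any(not 0.0 <= r <= 1.0 for r in self.retention_t):
            raise ValueError("retention probabilities must lie in [0, 1]")
        if any(not 0.0 <= p <= 1.0 for p in self.binary_probs):
            raise ValueError("binary_probs must lie in [0, 1]")
        psi = np.asarray(self.psi, dtype=float)
        if psi.shape != (3, 3):
            raise ValueError("psi must be 3x3")
        if np.min(np.linalg.eigvalsh((psi + psi.T) / 2)) < -1e-10:
            raise ValueError("psi must be positive semi-definite")


def default_config(**overrides) -> SimulationConfig:
    """Return the default calibrated configuration; keyword overrides replace fields."""
    cfg = SimulationConfig(**overrides)
    cfg.validate()
    return cfg


def residual_covariance(theta_t, rho) -> np.ndarray:
    """Heteroscedastic lag-power residual covariance Θ_jk = sqrt(θ_j θ_k) ρ^|j−k|."""
    theta = np.asarray(theta_t, dtype=float)
    sd = np.sqrt(theta)
    lags = np.abs(np.subtract.outer(np.arange(len(theta)), np.arange(len(theta))))
    with np.errstate(invalid="ignore"):
        corr = np.where(lags == 0, 1.0, float(rho) ** lags)
    return np.outer(sd, sd) * corr


def _loadings(times=TIMES) -> np.ndarray:
    lam = np.asarray(times, dtype=float)
    return np.column_stack([np.ones_like(lam), lam, lam**2])


def generate_dataset(config: SimulationConfig) -> pd.DataFrame:
    """Draw one synthetic trial as a wide per-participant table.

    Rows follow the documented schema: id, arm, six BDI-II totals, FFMQ
    pre/post and change, the indicator battery, distal quality of life,
    sensitivity covariates and the true latent class (simulation-only).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n

    true_class = rng.binomial(1, config.pi2, size=n) + 1  # 1- or 2-indexed class
    g = true_class - 1

    # 1:1 randomisation: balanced permuted assignment
    arm = np.zeros(n, dtype=int)
    arm[rng.permutation(n)[: n // 2]] = 1

    cols: dict[str, np.ndarray] = {
        "participant_id": np.arange(1, n + 1),
        "arm": arm,
    }

    # baseline indicator battery, class-conditional
    for name, (m1, m2) in config.indicator_means.items():
        mu = np.where(g == 0, m1, m2)
        cols[name] = mu + config.indicator_sds[name] * rng.standard_normal(n)
    p_bin = np.where(g == 0, config.binary_probs[0], config.binary_probs[1])
    cols[BINARY_INDICATOR] = rng.binomial(1, p_bin)

    q1, q2, qsd = config.qol
    cols[DISTAL_COLUMN] = np.where(g == 0, q1, q2) + qsd * rng.standard_normal(n)

    # mediator: change in mindfulness skills
    a0 = np.asarray(config.a0_g)[g]
    a = np.asarray(config.a_g)[g]
    delta = a0 + a * arm + config.sigma_m * rng.standard_normal(n)
    ffmq_pre = config.ffmq_pre_mean + config.ffmq_pre_sd * rng.standard_normal(n)
    cols["ffmq_pre"] = ffmq_pre
    cols["ffmq_post"] = ffmq_pre + delta
    cols["delta_ffmq"] = delta

    # latent growth factors
    alpha0 = np.asarray(config.alpha0_g)[g]
    alpha = np.column_stack(
        [alpha0, np.full(n, config.alpha1), np.full(n, config.alpha2)]
    )
    psi = np.asarray(config.psi, dtype=float)
    eta = alpha + rng.multivariate_normal(np.zeros(3), psi, size=n, method="svd")
    b = np.asarray(config.b_g)[g]
    cprime = np.asarray(config.cprime_g)[g]
    eta[:, 1] += b * delta + cprime * arm + config.sigma_slope * rng.standard_normal(n)

    # observed BDI-II series
    lam = _loadings()
    theta = residual_covariance(config.theta_t, config.rho)
    eps = rng.multivariate_normal(np.zeros(len(TIMES)), theta, size=n, method="svd")
    bdi_latent = eta @ lam.T + eps
    bdi_obs = np.clip(np.rint(bdi_latent), BDI_MIN, BDI_MAX)
    for j, col in enumerate(BDI_COLUMNS):
        cols[col] = bdi_obs[:, j]

    # covariates conditional on arm only
    practice = np.empty(n, dtype=int)
    for x in (0, 1):
        mask = arm == x
        probs = np.asarray(config.practice_probs[x], dtype=float)
        practice[mask] = rng.choice(4, size=mask.sum(), p=probs / probs.sum())
    cols["practice_level"] = practice
    p_disc = np.asarray(config.adm_discontinued_probs)[arm]
    cols["adm_discontinued"] = rng.binomial(1, p_disc)

    cols["true_class"] = true_class
    data = pd.DataFrame(cols)

    mask_seed = int(rng.integers(0, 2**31 - 1))
    return apply_missingness(data, config.retention_t, seed=mask_seed)


def apply_missingness(dataset: pd.DataFrame, retention_t, seed: int) -> pd.DataFrame:
    """Mask follow-up BDI-II waves independently with probability 1 − retention.

    The baseline wave is never deleted; masking draws depend on nothing in
    the data, so the mechanism is ignorable for likelihood-based fitting.
    """
    retention = np.asarray(retention_t, dtype=float)
    if retention.shape != (len(TIMES) - 1,):
        raise ValueError(f"retention_t must have length {len(TIMES) - 1}")
    if np.any((retention < 0) | (retention > 1)):
        raise ValueError("retention probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out = dataset.copy()
    n = len(out)
    for col, r in zip(BDI_COLUMNS[1:], retention):
        missing = rng.random(n) >= r
        vals = out[col].to_numpy(dtype=float, copy=True)
        vals[missing] = np.nan
        out[col] = vals
    return out


def implied_bdi_means(config: SimulationConfig) -> np.ndarray:
    """Closed-form marginal mean of the latent BDI-II series at each occasion.

    Averages the class- and arm-conditional growth means over the mixing
    proportion and the 1:1 randomisation; ignores clipping/rounding.
    """
    lam = _loadings()
    pis = (1.0 - config.pi2, config.pi2)
    mu = np.zeros(len(TIMES))
    for gi, pig in enumerate(pis):
        for x in (0, 1):
            e_m = config.a0_g[gi] + config.a_g[gi] * x
            e_eta1 = config.alpha1 + config.b_g[gi] * e_m + config.cprime_g[gi] * x
            alpha = np.array([config.alpha0_g[gi], e_eta1, config.alpha2])
            mu += pig * 0.5 * (lam @ alpha)
    return mu


def implied_marginal_slope_mean(config: SimulationConfig) -> float:
    """Closed-form marginal mean of the latent linear slope η₁ under the config."""
    pis = (1.0 - config.pi2, config.pi2)
    total = 0.0
    for gi, pig in enumerate(pis):
        for x in (0, 1):
            e_m = config.a0_g[gi] + config.a_g[gi] * x
            total += pig * 0.5 * (
                config.alpha1 + config.b_g[gi] * e_m + config.cprime_g[gi] * x
            )
    return total


def clipped_fraction(config: SimulationConfig, n: int = 20000, seed: int = 12345) -> float:
    """Monte-Carlo fraction of observed BDI-II values altered by range clipping."""
    cfg = dataclasses.replace(config, n=n, seed=seed, retention_t=(1.0,) * 5)
    cfg.validate()
    rng = np.random.default_rng(seed)
    g = rng.binomial(1, cfg.pi2, size=n)
    arm = rng.binomial(1, 0.5, size=n)
    delta = np.asarray(cfg.a0_g)[g] + np.asarray(cfg.a_g)[g] * arm
    delta = delta + cfg.sigma_m * rng.standard_normal(n)
    alpha = np.column_stack(
        [np.asarray(cfg.alpha0_g)[g], np.full(n, cfg.alpha1), np.full(n, cfg.alpha2)]
    )
    eta = alpha + rng.multivariate_normal(np.zeros(3), np.asarray(cfg.psi, float), size=n, method="svd")
    eta[:, 1] += np.asarray(cfg.b_g)[g] * delta + np.asarray(cfg.cprime_g)[g] * arm
    eta[:, 1] += cfg.sigma_slope * rng.standard_normal(n)
    latent = eta @ _loadings().T + rng.multivariate_normal(
        np.zeros(len(TIMES)), residual_covariance(cfg.theta_t, cfg.rho), size=n, method="svd"
    )
    return float(np.mean((latent < BDI_MIN - 0.5) | (latent > BDI_MAX + 0.5)))


# -- flat key-value config round-trip ----------------------------------------

def save_config(config: SimulationConfig, path) -> None:
    """Write the config as a flat ``key = value`` text file."""
    lines = []
    for f in dataclasses.fields(config):
        value = getattr(config, f.name)
        if isinstance(value, np.ndarray):
            value = value.tolist()
        elif isinstance(value, dict):
            value = {k: list(v) if isinstance(v, tuple) else v for k, v in value.items()}
        lines.append(f"{f.name} = {value!r}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_config(path) -> SimulationConfig:
    """Read a config written by :func:`save_config`."""
    import ast

    kwargs = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, raw = line.partition("=")
            kwargs[key.strip()] = ast.literal_eval(raw.strip())
    for key in ("alpha0_g", "a0_g", "a_g", "b_g", "cprime_g", "binary_probs",
                "theta_t", "retention_t", "qol", "adm_discontinued_probs"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    if "practice_probs" in kwargs:
        kwargs["practice_probs"] = tuple(tuple(p) for p in kwargs["practice_probs"])
    if "indicator_means" in kwargs:
        kwargs["indicator_means"] = {
            k: tuple(v) for k, v in kwargs["indicator_means"].items()
        }
    if "psi" in kwargs:
        kwargs["psi"] = np.asarray(kwargs["psi"], dtype=float)
    cfg = SimulationConfig(**kwargs)
    cfg.validate()
    return cfg
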