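"""Dataset reading/writing, validation, and the end-to-end pipeline.

The on-disk format is a wide CSV, one row per participant, with the
documented column names (id, arm, bdi_m0 ... bdi_m24, ffmq_pre, ffmq_post,
delta_ffmq, the indicator battery, qol, practice_level, adm_discontinued,
optional true_class). Missing cells — empty strings, "NA", "NaN" — all map
to a single NaN sentinel at ingest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import growth, mediation, profiles, simulate
from .simulate import (
    BDI_COLUMNS,
    BDI_MAX,
    BDI_MIN,
    INDICATOR_COLUMNS,
    SimulationConfig,
    default_config,
    generate_dataset,
)

logger = logging.getLogger("medgrowth")

_MISSING_TOKENS = ["", "NA", "NaN", "nan", "N/A", "null", "."]

MANDATORY_COLUMNS = ["participant_id", "arm", *BDI_COLUMNS]

#: BDI-II severity bands (inclusive bounds).
SEVERITY_BANDS = (
    (0, 13, "minimal"),
    (14, 19, "mild"),
    (20, 28, "moderate"),
    (29, 63, "severe"),
)


def classify_bdi(score) -> str:
    """Severity band label for an integer BDI-II total."""
    s = int(score)
    if s != score or not BDI_MIN <= s <= BDI_MAX:
        raise ValueError(f"BDI-II total must be an integer in [0, 63], got {score}")
    for lo, hi, label in SEVERITY_BANDS:
        if lo <= s <= hi:
            return label
    raise AssertionError("unreachable")


def write_dataset(dataset: pd.DataFrame, path) -> None:
    dataset.to_csv(path, index=False)


def read_dataset(path, manifest: dict | None = None) -> pd.DataFrame:
    """Read and validate a wide trial CSV.

    Raises on missing mandatory columns or out-of-range values, naming the
    offending rows. The ingest report (counts of missing cells per column)
    is attached as ``frame.attrs["ingest_report"]``.
    """
    df = pd.read_csv(path, na_values=_MISSING_TOKENS, keep_default_na=False)
    missing_cols = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"missing mandatory columns: {missing_cols}")

    problems = []
    arm = df["arm"]
    bad_arm = df.index[~arm.isin([0, 1])].tolist()
    if bad_arm:
        problems.append(f"arm not in {{0,1}} at rows {bad_arm[:10]}")
    for col in BDI_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.notna() & ((vals < BDI_MIN) | (vals > BDI_MAX))].tolist()
        if bad:
            problems.append(f"{col} outside [{BDI_MIN}, {BDI_MAX}] at rows {bad[:10]}")
        df[col] = vals
    if problems:
        raise ValueError("validation failed: " + "; ".join(problems))

    df.attrs["ingest_report"] = {c: int(df[c].isna().sum()) for c in df.columns}
    if manifest:
        for key in ("continuous", "binary"):
            for c in manifest.get(key, []):
                if c not in df.columns:
                    raise ValueError(f"manifest column {c!r} not in file")
    return df


def severity_band_counts(dataset: pd.DataFrame, column: str = "bdi_m0") -> pd.Series:
    """Participant counts per BDI-II severity band for one occasion."""
    vals = dataset[column].dropna().astype(int)
    bands = pd.Categorical(
        [classify_bdi(v) for v in vals],
        categories=[b[2] for b in SEVERITY_BANDS],
    )
    return pd.Series(bands).value_counts().reindex([b[2] for b in SEVERITY_BANDS],
                                                   fill_value=0)


# -- pipeline -----------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    input_path: str | None = None
    simulation: SimulationConfig | None = None
    manifest: dict = field(default_factory=lambda: {
        "continuous": [c for c in INDICATOR_COLUMNS if c != simulate.BINARY_INDICATOR],
        "binary": [simulate.BINARY_INDICATOR],
    })
    k_max: int = 3
    growth_residuals: str = "heteroscedastic_ar1"
    bootstrap_draws: int = 1000
    sensitivity_covariates: tuple[str, ...] = ("practice_level", "adm_discontinued")
    out_dir: str = "medgrowth_run"
    seed: int = 0
    verbosity: int = 1

    def __post_init__(self):
        if (self.input_path is None) == (self.simulation is None):
            raise ValueError("exactly one of input_path / simulation must be set")


def _setup_logging(out_dir: Path, verbosity: int) -> None:
    level = {0: logging.WARNING, 1: logging.INFO}.get(verbosity, logging.DEBUG)
    logger.setLevel(level)
    logger.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for handler in (logging.StreamHandler(),
                    logging.FileHandler(out_dir / "run.log", mode="w")):
        handler.setFormatter(fmt)
        logger.addHandler(handler)


def run_pipeline(config: RunConfig) -> dict:
    """Execute profiles → growth-model selection → moderated mediation → sensitivity.

    Writes all result tables (CSV), a profile z-score figure, and a JSON
    manifest with seeds, draw counts, timings and convergence codes.
    Returns the result bundle as a dict.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out, config.verbosity)
    manifest: dict = {"seed": config.seed, "stages": {}, "versions": _versions()}
    bundle: dict = {}
    stage = "input"
    try:
        t0 = time.perf_counter()
        if config.simulation is not None:
            sim = dataclasses.replace(config.simulation, seed=config.seed)
            data = generate_dataset(sim)
            simulate.save_config(sim, out / "simulation_config.txt")
            logger.info("simulated %d participants (seed=%d)", len(data), config.seed)
        else:
            data = read_dataset(config.input_path, config.manifest)
            logger.info("read %d participants from %s", len(data), config.input_path)
        write_dataset(data, out / "dataset.csv")
        bundle["dataset"] = data
        manifest["stages"][stage] = dict(n=len(data), seconds=time.perf_counter() - t0)

        # descriptive severity bands at baseline
        bands = severity_band_counts(data)
        bands.rename("count").to_csv(out / "baseline_severity_bands.csv")

        stage = "profiles"
        t0 = time.perf_counter()
        ind = data[config.manifest["continuous"] + config.manifest["binary"]]
        selection = profiles.select_profiles(
            ind, K_max=config.k_max, binary_cols=config.manifest["binary"],
            seed=config.seed)
        selection.drop(columns=[]).to_csv(out / "profile_selection.csv", index=False)
        lpa = profiles.fit_lpa(ind, K=2, binary_cols=config.manifest["binary"],
                               seed=config.seed)
        labels = profiles.modal_assignment(lpa.posteriors)
        zscores = profiles.profile_zscores(lpa, ind)
        zscores.to_csv(out / "profile_zscores.csv", index=False)
        _zscore_figure(zscores, out / "profile_zscores.png")
        if "qol" in data.columns:
            distal = profiles.compare_distal(data, labels, ["qol"])
            distal.to_csv(out / "distal_comparison.csv", index=False)
            bundle["distal"] = distal
        bundle.update(selection=selection, lpa=lpa, labels=labels, zscores=zscores)
        manifest["stages"][stage] = dict(
            entropy=lpa.entropy_rel, weights=lpa.weights.tolist(),
            seconds=time.perf_counter() - t0)
        logger.info("LPA: 2-class entropy %.3f, weights %s",
                    lpa.entropy_rel, np.round(lpa.weights, 3))

        stage = "growth"
        t0 = time.perf_counter()
        fits = [growth.fit_lgcm(
                    data,
                    growth.GrowthSpec(shape=s, residuals=config.growth_residuals,
                                      factor_variance_constraints=c),
                    seed=config.seed)
                for s, c in (("intercept", ()), ("linear", ("slope",)),
                             ("quadratic", ("slope", "quad")))]
        comparison = growth.compare_models(fits)
        comparison.to_csv(out / "growth_comparison.csv", index=False)
        best = fits[int(comparison["bic"].idxmin())]
        pd.DataFrame(dict(factor=best.spec.factor_names, mean=best.alpha,
                          se=best.alpha_se)).to_csv(out / "growth_means.csv",
                                                    index=False)
        bundle.update(growth_fits=fits, growth_comparison=comparison,
                      growth_best=best)
        manifest["stages"][stage] = dict(
            best=str(comparison.loc[comparison["best_bic"], "model"].iloc[0]),
            convergence=[f.converged for f in fits],
            seconds=time.perf_counter() - t0)

        stage = "mediation"
        t0 = time.perf_counter()
        spec = mediation.MedModSpec(bootstrap_draws=config.bootstrap_draws,
                                    bootstrap_seed=config.seed)
        fit = mediation.fit_medmod(data, labels, spec, seed=config.seed)
        boot = mediation.bootstrap_ci(data, labels, spec)
        table2 = mediation_table(fit, boot)
        table2.to_csv(out / "mediation_table.csv", index=False)
        tot = mediation.total_effect(data, labels, spec, seed=config.seed)
        bundle.update(medmod=fit, bootstrap=boot, total=tot, mediation_table=table2)
        manifest["stages"][stage] = dict(
            B=boot.B, boot_seed=boot.seed, failed_draws=boot.n_failed,
            converged=fit.converged, dropped_missing_mediator=fit.n_dropped,
            seconds=time.perf_counter() - t0)
        logger.info("mediation: index %.3f CI (%.3f, %.3f)",
                    fit.index, *boot.ci["index"])

        stage = "sensitivity"
        t0 = time.perf_counter()
        adj_spec = mediation.adjust_covariates(spec, config.sensitivity_covariates)
        adj_fit = mediation.fit_medmod(data, labels, adj_spec, seed=config.seed)
        adj_boot = mediation.bootstrap_ci(data, labels, adj_spec)
        adj_table = mediation_table(adj_fit, adj_boot)
        adj_table.to_csv(out / "mediation_table_adjusted.csv", index=False)
        bundle.update(medmod_adjusted=adj_fit, bootstrap_adjusted=adj_boot)
        manifest["stages"][stage] = dict(
            covariates=list(config.sensitivity_covariates), B=adj_boot.B,
            failed_draws=adj_boot.n_failed, seconds=time.perf_counter() - t0)
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        logger.error("pipeline failed at stage %s: %s", stage, exc)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    bundle["manifest"] = manifest
    return bundle


def mediation_table(fit, boot) -> pd.DataFrame:
    """Tabulate paths, moderation contrasts, conditional effects and the index."""
    g1, g2 = fit.groups
    rows = [
        ("a-path LP1 (arm→ΔFFMQ)", fit.a_g[0], fit.a_se_g[0], f"a{g1}"),
        ("a-path LP2 (arm→ΔFFMQ)", fit.a_g[1], fit.a_se_g[1], f"a{g2}"),
        ("a-path moderation (a2−a1)", fit.a_diff, fit.a_diff_se, "a_diff"),
        ("b-path (ΔFFMQ→slope)", fit.b_g[0], fit.b_se_g[0], "b"),
        ("b-path moderation (b2−b1)", fit.b_diff, fit.b_diff_se, None),
        ("c'-path (direct arm→slope)", fit.cprime_g[0], fit.cprime_se_g[0], "cprime"),
        ("c'-path moderation", fit.cprime_diff, fit.cprime_diff_se, None),
        ("indirect effect LP1", fit.ie_g[0], np.nan, f"ie{g1}"),
        ("indirect effect LP2", fit.ie_g[1], np.nan, f"ie{g2}"),
        ("index of moderated mediation", fit.index, np.nan, "index"),
    ]
    out = []
    for label, est, se, boot_key in rows:
        lo, hi = (boot.ci.get(boot_key, (np.nan, np.nan)) if boot_key else (np.nan, np.nan))
        out.append(dict(quantity=label, estimate=est, se=se,
                        boot_ci_low=lo, boot_ci_high=hi,
                        significant=boot.significant.get(boot_key, None) if boot_key else None))
    table = pd.DataFrame(out)
    r2 = pd.DataFrame([
        dict(quantity=f"R2(mediator) LP{g}", estimate=fit.r2_mediator_g[k],
             se=np.nan, boot_ci_low=np.nan, boot_ci_high=np.nan, significant=None)
        for k, g in enumerate(fit.groups)
    ] + [
        dict(quantity=f"R2(slope) LP{g}", estimate=fit.r2_slope_g[k],
             se=np.nan, boot_ci_low=np.nan, boot_ci_high=np.nan, significant=None)
        for k, g in enumerate(fit.groups)
    ])
    return pd.concat([table, r2], ignore_index=True)


def _zscore_figure(zscores: pd.DataFrame, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 4))
    for k, sub in zscores.groupby("class_"):
        ax.plot(sub["indicator"], sub["z"], marker="o", label=f"profile {k}")
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_ylabel("standardised mean / proportion (z)")
    ax.tick_params(axis="x", rotation=90)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _versions() -> dict:
    import scipy
    import statsmodels

    from . import __version__

    return dict(medgrowth=__version__, numpy=np.__version__,
                pandas=pd.__version__, scipy=scipy.__version__,
                statsmodels=statsmodels.__version__)
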