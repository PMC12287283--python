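"""Readers, validation, run configuration and the pipeline driver."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import clock as clock_mod
from .ddpcr import apply_no_rt_subtraction, concentration_table, size_fraction_profile
from .errors import ConfigurationError, InvalidInputError
from .fit import (
    MCMCConfig,
    PriorConfig,
    build_dataset,
    compare_models_loo,
    convergence_diagnostics,
    fit_decay_model,
    summarize_decay,
)

__all__ = [
    "MONOPLEX_COLUMNS",
    "DUPLEX_COLUMNS",
    "ValidationReport",
    "RunConfig",
    "read_ddpcr_table",
    "run_pipeline",
]

logger = logging.getLogger("enadecay")

MONOPLEX_COLUMNS = [
    "sample_id",
    "marker",
    "component",
    "carboy",
    "time_nominal_h",
    "time_actual_h",
    "tech_rep",
    "pore_size_um",
    "droplets_total",
    "droplets_positive",
    "filt_vol_L",
    "dilution_d",
]
DUPLEX_COLUMNS = [
    "sample_id",
    "marker",
    "component",
    "carboy",
    "time_nominal_h",
    "time_actual_h",
    "tech_rep",
    "pore_size_um",
    "droplets_total",
    "n_both",
    "n_a_only",
    "n_b_only",
    "n_neither",
    "filt_vol_L",
    "dilution_d",
]


@dataclass
class ValidationReport:
    n_rows: int
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def read_ddpcr_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    control_carboy: int = 4,
) -> tuple[pd.DataFrame, ValidationReport]:
    """Read and validate one long-format well table (monoplex or duplex).

    ``column_map`` renames dialect columns onto the package schema before
    validation. Rows violating count invariants (W > U, duplex categories not
    summing to the droplet total) are reported by row number and rejected;
    positive droplets in control-carboy wells raise warnings only.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"input file not found: {path}")
    df = pd.read_csv(path, comment="#")
    if column_map:
        df = df.rename(columns=dict(column_map))
    is_duplex = "n_both" in df.columns
    required = DUPLEX_COLUMNS if is_duplex else MONOPLEX_COLUMNS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ConfigurationError(f"{path.name}: missing required columns {missing}")
    report = ValidationReport(n_rows=len(df))
    if is_duplex:
        cats = df[["n_both", "n_a_only", "n_b_only", "n_neither"]]
        bad_sum = cats.sum(axis=1) != df["droplets_total"]
        for i in df.index[bad_sum]:
            report.errors.append(f"row {i}: duplex categories do not sum to droplets_total")
        if (cats < 0).any(axis=None):
            for i in df.index[(cats < 0).any(axis=1)]:
                report.errors.append(f"row {i}: negative category count")
        pos = cats[["n_both", "n_a_only", "n_b_only"]].sum(axis=1)
    else:
        bad = (df["droplets_positive"] > df["droplets_total"]) | (df["droplets_positive"] < 0)
        for i in df.index[bad]:
            report.errors.append(
                f"row {i}: droplets_positive={df.loc[i, 'droplets_positive']} outside "
                f"[0, {df.loc[i, 'droplets_total']}]"
            )
        pos = df["droplets_positive"]
    if (df["droplets_total"] <= 0).any():
        for i in df.index[df["droplets_total"] <= 0]:
            report.errors.append(f"row {i}: droplets_total must be > 0")
    ctrl_pos = (df["carboy"] == control_carboy) & (pos > 0)
    for i in df.index[ctrl_pos]:
        report.warnings.append(f"row {i}: control-carboy well has positive droplets")
    for col in ("filt_vol_L", "dilution_d"):
        if df[col].isna().any():
            for i in df.index[df[col].isna()]:
                report.errors.append(f"row {i}: missing {col}")
    if not report.ok:
        raise InvalidInputError(
            f"{path.name}: {len(report.errors)} invalid rows; first: {report.errors[:5]}"
        )
    return df, report


@dataclass
class RunConfig:
    """Single source of truth for a pipeline run."""

    wells_csv: str
    duplex_csv: str | None = None
    output_dir: str = "results"
    models: tuple[str, ...] = ("biphasic", "single_exponential")
    primary_model: str = "biphasic"
    seed: int = 1
    n_chains: int = 4
    warmup: int = 1000
    draws: int = 2000
    thin: int = 4
    rhat_threshold: float = 1.005
    ess_threshold: float = 500.0
    pore_screen_threshold: float = 0.95
    include_baseline: bool = False
    control_carboy: int = 4
    ln_c0_sd: float = 3.0
    t_x_bounds: tuple[float, float] = (12.0, 96.0)
    order_constraint: bool = False
    clock_grid_max_h: float = 24.0
    clock_grid_step_h: float = 0.5

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(RunConfig)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "models" in data:
            data["models"] = tuple(data["models"])
        if "t_x_bounds" in data:
            data["t_x_bounds"] = tuple(data["t_x_bounds"])
        return RunConfig(**data)

    def mcmc(self) -> MCMCConfig:
        return MCMCConfig(self.n_chains, self.warmup, self.draws, self.thin)

    def priors(self) -> PriorConfig:
        return PriorConfig(
            ln_c0_sd=self.ln_c0_sd,
            t_x_bounds=self.t_x_bounds,
            order_constraint=self.order_constraint,
        )

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stamp(config: RunConfig) -> str:
    return f"# config_sha256={config.digest()} seed={config.seed}\n"


def _write_csv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_stamp(config))
        df.to_csv(fh, index=False, float_format="%.10g")


def _screen(mono: pd.DataFrame, config: RunConfig) -> dict:
    """Pore-size screening on the earliest timepoint, per carboy."""
    t0 = mono.loc[mono["time_nominal_h"] >= 0, "time_nominal_h"].min()
    sel = mono[
        (mono["time_nominal_h"] == t0)
        & (mono["marker"] == "Cytb")
        & (mono["component"] == "eDNA")
        & (mono["carboy"] != config.control_carboy)
    ]
    out = {"timepoint_h": float(t0), "carboys": {}, "pore_sizes": sorted(sel["pore_size_um"].unique())}
    if sel["pore_size_um"].nunique() < 2:
        out["verdict"] = "single pore size present; nothing to screen"
        return out
    conc = concentration_table(sel)
    all_pass = True
    for carboy, sub in conc.groupby("carboy"):
        by_pore = sub.groupby("pore_size_um")["concentration_copies_per_L"].mean().to_dict()
        prof = size_fraction_profile(by_pore, threshold=config.pore_screen_threshold)
        out["carboys"][int(carboy)] = {
            "fractions": {f"{k:g}": v for k, v in prof.fractions.items()},
            "dominant_pore_um": prof.dominant_pore_um,
            "dominant_fraction": prof.dominant_fraction,
            "passes": prof.passes_screen,
        }
        all_pass &= prof.passes_screen
    out["verdict"] = (
        "restrict analysis to the dominant pore fraction" if all_pass else "no restriction"
    )
    out["all_pass"] = all_pass
    return out


def run_pipeline(config: RunConfig, stages: Sequence[str] = ("screen", "fit", "compare", "clock")) -> dict:
    """Execute screen → fit → compare → summarize → clocks; write all outputs.

    Returns a results dict with the in-memory artifacts; every written file
    carries the config hash and seed. Convergence failure sets
    ``results['converged'] = False`` (callers decide the exit status).
    """
    t_start = time.time()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    results: dict = {"config_digest": config.digest(), "seed": config.seed}
    try:
        mono, rep_m = read_ddpcr_table(config.wells_csv, control_carboy=config.control_carboy)
        logger.info("read %d monoplex wells (%d warnings)", rep_m.n_rows, len(rep_m.warnings))
        duplex = None
        if config.duplex_csv:
            duplex, rep_d = read_ddpcr_table(config.duplex_csv, control_carboy=config.control_carboy)
            logger.info("read %d duplex wells (%d warnings)", rep_d.n_rows, len(rep_d.warnings))
        results["validation_warnings"] = rep_m.warnings + (rep_d.warnings if duplex is not None else [])

        if "screen" in stages:
            results["screen"] = _screen(mono, config)
            (outdir / "screen.json").write_text(
                json.dumps({"_meta": {"config": config.digest(), "seed": config.seed}, **results["screen"]}, indent=2, default=str)
            )
            logger.info("pore-size screen: %s", results["screen"].get("verdict"))

        mono_adj, nort_log = apply_no_rt_subtraction(mono)
        if len(nort_log):
            _write_csv(nort_log, outdir / "no_rt_adjustments.csv", config)
        conc = concentration_table(mono_adj[mono_adj["time_nominal_h"] >= 0])
        _write_csv(conc, outdir / "concentrations.csv", config)

        if not ({"fit", "compare", "clock"} & set(stages)):
            return results

        dataset = build_dataset(
            mono_adj,
            duplex,
            control_carboy=config.control_carboy,
            include_baseline=config.include_baseline,
        )
        for w in dataset.validation_warnings:
            logger.warning("%s", w)

        fits = []
        for model_id in config.models:
            logger.info("fitting model %s", model_id)
            t0 = time.time()
            draws = fit_decay_model(
                dataset, model_id, config.priors(), config.mcmc(), seed=config.seed
            )
            logger.info("model %s fitted in %.1f s", model_id, time.time() - t0)
            fits.append((model_id, draws))
        by_id = dict(fits)
        primary = by_id.get(config.primary_model, fits[0][1])
        results["fits"] = by_id

        diag = convergence_diagnostics(
            primary, config.rhat_threshold, config.ess_threshold
        )
        results["diagnostics"] = diag
        results["converged"] = bool(diag.attrs["all_ok"])
        diag_payload = {
            "_meta": {"config": config.digest(), "seed": config.seed},
            "max_rhat": float(diag["rhat"].max()),
            "min_ess_bulk": float(diag["ess_bulk"].min()),
            "all_ok": results["converged"],
        }
        (outdir / "diagnostics.json").write_text(json.dumps(diag_payload, indent=2))
        _write_csv(diag, outdir / "diagnostics.csv", config)
        if not results["converged"]:
            logger.warning(
                "convergence diagnostics failed (max R-hat %.4f, min ESS %.0f)",
                diag_payload["max_rhat"],
                diag_payload["min_ess_bulk"],
            )

        if "compare" in stages:
            if len(fits) > 1:
                loo = compare_models_loo(fits)
                results["loo"] = loo
                _write_csv(loo.reset_index(names="model"), outdir / "loo.csv", config)
                logger.info("LOO ranking: %s", list(loo.index))
            else:
                logger.warning("single-model menu: skipping LOO comparison")

        summary = summarize_decay(primary)
        results["summary"] = summary
        _write_csv(summary, outdir / "fit_summary.csv", config)

        if "clock" in stages:
            grid = np.arange(0.0, config.clock_grid_max_h + config.clock_grid_step_h / 2, config.clock_grid_step_h)
            slopes = {}
            comps = set(primary.components())
            for spec in (clock_mod.BRIDGE_TO_CYTB, clock_mod.ERRNA_PROPORTION_16S):
                needed = {spec.numerator, *spec.denominator}
                if not needed <= comps:
                    logger.warning("skipping clock %s: components missing", spec.label)
                    continue
                traj = clock_mod.ratio_trajectory(primary, spec, grid)
                slope = clock_mod.clock_slope(traj)
                slopes[spec.label] = dataclasses.asdict(slope)
                safe = spec.label.replace(":", "_").replace("(", "").replace(")", "").replace(" ", "_")
                _write_csv(traj.table, outdir / f"clock_{safe}.csv", config)
                results.setdefault("clocks", {})[spec.label] = (traj, slope)
            (outdir / "clock_slopes.json").write_text(
                json.dumps({"_meta": {"config": config.digest(), "seed": config.seed}, **slopes}, indent=2)
            )

        # draws archive (flattened, parquet when available)
        try:
            frames = []
            for gid, g in primary.groups.items():
                nc, nd, ndim = g.draws.shape
                flat = g.draws.reshape(nc * nd, ndim)
                frame = pd.DataFrame(flat, columns=g.param_names)
                frame.insert(0, "draw", np.tile(np.arange(nd), nc))
                frame.insert(0, "chain", np.repeat(np.arange(nc), nd))
                frames.append(frame.set_index(["chain", "draw"]))
            pd.concat(frames, axis=1).reset_index().to_parquet(outdir / "draws.parquet")
        except ImportError:  # pragma: no cover - pyarrow present in practice
            logger.warning("no parquet engine; skipping draws archive")

        logger.info("pipeline finished in %.1f s", time.time() - t_start)
        return results
    finally:
        logger.removeHandler(handler)
        handler.close()
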