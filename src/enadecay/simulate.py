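"""Synthetic mesocosm generator.

Emulates the dolphin-enclosure decay experiment at droplet-count level: three
biological-replicate carboys of seawater plus a deionized-water control held
in an environmental chamber, sampled at nine timepoints (0–188 h) with two
ddPCR technical replicates per sample and ~20,000 droplets per well. Six
marker-component combinations decay biphasically; 16S and D-loop are read in
a duplex assay whose double-positive excess encodes intact (Bridge) mtDNA;
every RNA well has a paired No-RT control showing occasional residual-DNA
positives; a serial-filtration screen at the first timepoint splits the Cytb
signal over 5 / 1 / 0.45 µm pore sizes.

Default truth values are the study's reported decay parameters; initial
concentrations are set so that the two molecular-clock ratios start at a
Bridge:Cytb proportion of 0.11 and an erRNA proportion of 0.5, the values
implied by the reported 0–24 h clock slopes given the phase-1 rates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .ddpcr import VolumeChain
from .duplex import category_probabilities
from .models import BiphasicParams, _biphasic

__all__ = [
    "ExperimentDesign",
    "TruthParams",
    "DEFAULT_TRUTH",
    "DEFAULT_DESIGN",
    "simulate_true_concentrations",
    "simulate_droplet_counts",
    "generate_fixture",
]

#: Monoplex marker-components and the duplex trio, keyed "<marker>_<component>".
MONOPLEX_COMPONENTS = ("Cytb_eDNA", "Cytb_emRNA", "16S_erRNA")
DUPLEX_COMPONENTS = ("16S_eDNA", "Dloop_eDNA", "Bridge_eDNA")
RNA_COMPONENTS = ("Cytb_emRNA", "16S_erRNA")


def split_key(key: str) -> tuple[str, str]:
    """'16S_eDNA' -> ('16S', 'eDNA')."""
    marker, component = key.rsplit("_", 1)
    return marker, component


@dataclass(frozen=True)
class ExperimentDesign:
    """Sampling design of the mesocosm experiment."""

    n_carboys: int = 3
    include_control_carboy: bool = True
    timepoints_h: tuple[float, ...] = (0.0, 4.0, 8.0, 12.0, 24.0, 48.0, 96.0, 140.0, 188.0)
    tech_reps: int = 2
    droplets_per_well: int = 20_000
    chain: VolumeChain = field(default_factory=VolumeChain)
    rna_dilution_d: float = 2.0
    baseline_offset_h: float = -3.0
    filtration_jitter_h: float = 0.25
    screening_pore_sizes_um: tuple[float, ...] = (5.0, 1.0, 0.45)

    def __post_init__(self) -> None:
        if list(self.timepoints_h) != sorted(set(self.timepoints_h)):
            raise ValueError("timepoints must be strictly increasing")
        if self.n_carboys < 1 or self.tech_reps < 1 or self.droplets_per_well < 1:
            raise ValueError("counts must be positive")

    @property
    def control_carboy(self) -> int | None:
        return self.n_carboys + 1 if self.include_control_carboy else None


@dataclass(frozen=True)
class TruthParams:
    """Generating truth for the synthetic experiment."""

    components: Mapping[str, BiphasicParams]
    carboy_sd: float = 0.2  # lognormal sd on C0, per carboy-component
    carboy_rate_sd: float = 0.0  # optional mis-specification: carboy-specific lambda1
    no_rt_rate: float = 0.5  # expected residual-DNA positives per RNA/No-RT well
    pore_allocation: Mapping[float, float] = field(
        default_factory=lambda: {5.0: 0.96, 1.0: 0.025, 0.45: 0.015}
    )


# Decay parameters per marker-component follow the reported posterior values
# (phase-1 and phase-2 rates in 1/h, transition time in h). Cytb emRNA truth is
# single-phase (lambda2 = lambda1): it is detected once and never again, so a
# second phase is unobservable. C0s (copies/L) encode the clock starting points
# derived in the module docstring; absolute scale gives ddPCR occupancies in
# the informative range (mu ~ 0.1-1 at t=0 for DNA markers).
DEFAULT_TRUTH = TruthParams(
    components={
        "Cytb_eDNA": BiphasicParams(c0=3.0e5, lambda1=0.114, lambda2=0.026, t_x=41.0),
        "Cytb_emRNA": BiphasicParams(c0=5.0e2, lambda1=1.615, lambda2=1.615, t_x=41.0),
        "16S_eDNA": BiphasicParams(c0=2.0e5, lambda1=0.165, lambda2=0.028, t_x=33.0),
        "16S_erRNA": BiphasicParams(c0=2.0e5, lambda1=0.236, lambda2=0.054, t_x=29.0),
        "Dloop_eDNA": BiphasicParams(c0=1.5e5, lambda1=0.166, lambda2=0.021, t_x=36.0),
        "Bridge_eDNA": BiphasicParams(c0=3.3e4, lambda1=0.190, lambda2=0.044, t_x=28.0),
    }
)

DEFAULT_DESIGN = ExperimentDesign()


def simulate_true_concentrations(
    truth: TruthParams, design: ExperimentDesign, seed: int | np.random.Generator = 0
) -> pd.DataFrame:
    """Noise-free (carboy-level) concentration truth per component, carboy, time.

    Carboy heterogeneity enters through a lognormal multiplier on C0 per
    (carboy, component); rates are shared across carboys unless
    ``carboy_rate_sd > 0`` (mis-specification mode). The control carboy is
    identically zero. Actual sampling times add a Uniform(0, jitter) filtration
    delay drawn once per carboy-timepoint; baseline rows sit at the (negative)
    transport offset with phase-1 back-extrapolated concentrations.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    carboys = list(range(1, design.n_carboys + 1))
    times = [design.baseline_offset_h] + list(design.timepoints_h)
    jitter = {
        (c, t): rng.uniform(0.0, design.filtration_jitter_h) for c in carboys for t in times
    }
    rows = []
    for key, params in truth.components.items():
        for c in carboys:
            mult = float(np.exp(rng.normal(0.0, truth.carboy_sd))) if truth.carboy_sd > 0 else 1.0
            lam1 = params.lambda1
            if truth.carboy_rate_sd > 0:
                lam1 = float(lam1 * np.exp(rng.normal(0.0, truth.carboy_rate_sd)))
            for t in times:
                t_act = t + jitter[(c, t)]
                if t_act >= 0:
                    conc = float(_biphasic(t_act, params.c0 * mult, lam1, params.lambda2, params.t_x))
                else:
                    # pre-transport baseline: back-extrapolate phase 1
                    conc = float(params.c0 * mult * np.exp(-lam1 * t_act))
                rows.append(
                    {
                        "component_key": key,
                        "carboy": c,
                        "time_nominal_h": t,
                        "time_actual_h": t_act,
                        "is_baseline": t < 0,
                        "concentration_true": conc,
                    }
                )
        if design.control_carboy is not None:
            for t in times:
                rows.append(
                    {
                        "component_key": key,
                        "carboy": design.control_carboy,
                        "time_nominal_h": t,
                        "time_actual_h": t,
                        "is_baseline": t < 0,
                        "concentration_true": 0.0,
                    }
                )
    return pd.DataFrame(rows)


def _mu_from_concentration(conc: float, chain: VolumeChain, dilution_d: float) -> float:
    c = chain.with_(dilution_d=dilution_d)
    return conc / c.copies_per_litre_per_droplet_copy


def simulate_droplet_counts(
    conc: pd.DataFrame,
    truth: TruthParams,
    design: ExperimentDesign,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw droplet-level counts for every well of the design.

    Monoplex wells draw ``W ~ Binomial(U, 1 - exp(-mu))``; each RNA well gets
    a paired No-RT control whose occasional positives follow a small Poisson
    residual-DNA rate. The duplex 16S/D-loop well draws
    the four droplet categories from the exact multinomial implied by the
    free-16S, free-D-loop and Bridge per-droplet loads. Serial-filtration
    screening wells split the earliest-timepoint Cytb signal across pore
    sizes; all other wells are the 5 µm fraction.

    Returns (monoplex table, duplex table) in the package's CSV dialect.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    U = design.droplets_per_well
    chain = design.chain
    alloc = dict(truth.pore_allocation)
    main_pore = max(alloc, key=alloc.get)
    lookup = {
        (r.component_key, r.carboy, r.time_nominal_h): r
        for r in conc.itertuples(index=False)
    }
    carboys = list(range(1, design.n_carboys + 1))
    if design.control_carboy is not None:
        carboys.append(design.control_carboy)
    times = [design.baseline_offset_h] + list(design.timepoints_h)
    first_t = design.timepoints_h[0]
    mono_comps = [k for k in MONOPLEX_COMPONENTS if k in truth.components]
    rna_comps = [k for k in RNA_COMPONENTS if k in truth.components]
    have_duplex = all(k in truth.components for k in DUPLEX_COMPONENTS)

    mono_rows, duplex_rows = [], []

    def sample_id(key: str, c: int, t: float, rep: int, pore: float) -> str:
        return f"{key}_c{c}_t{t:g}_r{rep}_p{pore:g}"

    for c in carboys:
        is_control = c == design.control_carboy
        for t in times:
            for rep in range(1, design.tech_reps + 1):
                # --- monoplex wells (5 um main fraction) ---
                for key in mono_comps:
                    row = lookup[(key, c, t)]
                    marker, component = split_key(key)
                    is_rna = key in RNA_COMPONENTS
                    d = design.rna_dilution_d if is_rna else 1.0
                    mu = _mu_from_concentration(
                        row.concentration_true * alloc[main_pore], chain, d
                    )
                    w = int(rng.binomial(U, -np.expm1(-mu))) if mu > 0 else 0
                    mono_rows.append(
                        {
                            "sample_id": sample_id(key, c, t, rep, main_pore),
                            "marker": marker,
                            "component": component,
                            "carboy": c,
                            "time_nominal_h": t,
                            "time_actual_h": row.time_actual_h,
                            "tech_rep": rep,
                            "pore_size_um": main_pore,
                            "droplets_total": U,
                            "droplets_positive": w,
                            "filt_vol_L": chain.filt_vol,
                            "dilution_d": d,
                        }
                    )
                # --- No-RT controls, one per RNA marker ---
                for key in rna_comps:
                    marker, _ = split_key(key)
                    row = lookup[(key, c, t)]
                    w = 0 if is_control else min(int(rng.poisson(truth.no_rt_rate)), U)
                    mono_rows.append(
                        {
                            "sample_id": sample_id(f"{marker}_NoRT", c, t, rep, main_pore),
                            "marker": marker,
                            "component": "NoRT",
                            "carboy": c,
                            "time_nominal_h": t,
                            "time_actual_h": row.time_actual_h,
                            "tech_rep": rep,
                            "pore_size_um": main_pore,
                            "droplets_total": U,
                            "droplets_positive": w,
                            "filt_vol_L": chain.filt_vol,
                            "dilution_d": design.rna_dilution_d,
                        }
                    )
                # --- duplex 16S/D-loop well ---
                if not have_duplex:
                    continue
                lam = {}
                for key in DUPLEX_COMPONENTS:
                    row = lookup[(key, c, t)]
                    lam[key] = _mu_from_concentration(
                        row.concentration_true * alloc[main_pore], chain, 1.0
                    )
                probs = category_probabilities(
                    lam["16S_eDNA"], lam["Dloop_eDNA"], lam["Bridge_eDNA"]
                )
                n_both, n_a, n_b, n_none = rng.multinomial(U, list(probs))
                duplex_rows.append(
                    {
                        "sample_id": sample_id("16S-Dloop_duplex", c, t, rep, main_pore),
                        "marker": "16S-Dloop",
                        "component": "eDNA",
                        "carboy": c,
                        "time_nominal_h": t,
                        "time_actual_h": lookup[("16S_eDNA", c, t)].time_actual_h,
                        "tech_rep": rep,
                        "pore_size_um": main_pore,
                        "droplets_total": U,
                        "n_both": int(n_both),
                        "n_a_only": int(n_a),
                        "n_b_only": int(n_b),
                        "n_neither": int(n_none),
                        "filt_vol_L": chain.filt_vol,
                        "dilution_d": 1.0,
                    }
                )
            # --- pore-size screening wells (first timepoint, Cytb eDNA) ---
            if t == first_t and "Cytb_eDNA" in truth.components:
                row = lookup[("Cytb_eDNA", c, t)]
                for pore in design.screening_pore_sizes_um:
                    if pore == main_pore:
                        continue  # the main wells above are the 5 um fraction
                    mu = _mu_from_concentration(
                        row.concentration_true * alloc.get(pore, 0.0), chain, 1.0
                    )
                    w = int(rng.binomial(U, -np.expm1(-mu))) if mu > 0 else 0
                    mono_rows.append(
                        {
                            "sample_id": sample_id("Cytb_eDNA", c, t, 1, pore),
                            "marker": "Cytb",
                            "component": "eDNA",
                            "carboy": c,
                            "time_nominal_h": t,
                            "time_actual_h": row.time_actual_h,
                            "tech_rep": 1,
                            "pore_size_um": pore,
                            "droplets_total": U,
                            "droplets_positive": w,
                            "filt_vol_L": chain.filt_vol,
                            "dilution_d": 1.0,
                        }
                    )
    return pd.DataFrame(mono_rows), pd.DataFrame(duplex_rows)


def generate_fixture(
    seed: int,
    outdir: str | Path | None = None,
    truth: TruthParams = DEFAULT_TRUTH,
    design: ExperimentDesign = DEFAULT_DESIGN,
) -> dict:
    """Generate a complete synthetic input bundle; deterministic per seed.

    Returns a dict with the monoplex/duplex tables, the truth, and (when
    ``outdir`` is given) the paths of the written ``wells.csv``,
    ``duplex.csv`` and ``truth.json``.
    """
    rng = np.random.default_rng(seed)
    conc = simulate_true_concentrations(truth, design, rng)
    mono, dup = simulate_droplet_counts(conc, truth, design, rng)
    bundle = {"monoplex": mono, "duplex": dup, "truth": truth, "design": design, "seed": seed}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        mono_path = outdir / "wells.csv"
        dup_path = outdir / "duplex.csv"
        truth_path = outdir / "truth.json"
        mono.to_csv(mono_path, index=False, float_format="%.10g")
        dup.to_csv(dup_path, index=False, float_format="%.10g")
        truth_json = {
            "seed": seed,
            "components": {k: asdict(v) for k, v in truth.components.items()},
            "carboy_sd": truth.carboy_sd,
            "no_rt_rate": truth.no_rt_rate,
            "pore_allocation": {str(k): v for k, v in truth.pore_allocation.items()},
        }
        truth_path.write_text(json.dumps(truth_json, indent=2, sort_keys=True) + "\n")
        bundle["paths"] = {"wells": mono_path, "duplex": dup_path, "truth": truth_path}
    return bundle
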