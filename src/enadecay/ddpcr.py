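"""Droplet-level ddPCR observation model.

Digital droplet PCR partitions a reaction into ~20,000 nanolitre-scale droplets.
Target molecules distribute over droplets approximately as a Poisson process, so
the fraction of positive droplets ``p`` relates to the mean per-droplet copy
number ``mu`` by ``p = 1 - exp(-mu)`` — equivalently ``cloglog(p) = ln(mu)``.
This module converts positive/total droplet counts into occupancy estimates,
per-droplet copy numbers, and absolute sample concentrations (copies per litre
of source water) through the laboratory volume chain, and implements the two
screening rules applied upstream of decay fitting: subtraction of residual-DNA
No-RT control counts from eRNA wells, and the pore-size fractionation screen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InvalidInputError

__all__ = [
    "Marker",
    "Component",
    "DropletRecord",
    "VolumeChain",
    "OccupancyEstimate",
    "SizeFractionProfile",
    "estimate_occupancy",
    "mean_copies_to_sample_concentration",
    "sample_concentration_to_mean_copies",
    "subtract_no_rt",
    "apply_no_rt_subtraction",
    "size_fraction_profile",
    "concentration_table",
]


class Marker(str, Enum):
    """Mitochondrial locus targeted by an assay."""

    CYTB = "Cytb"
    S16 = "16S"
    DLOOP = "Dloop"


class Component(str, Enum):
    """Nucleic-acid component quantified in a well.

    ``CARRYOVER`` is reserved for the residual-DNA fraction passing the first
    extraction column; it is accepted on input but not modelled here.
    """

    EDNA = "eDNA"
    EMRNA = "emRNA"
    ERRNA = "erRNA"
    NO_RT = "NoRT"
    CARRYOVER = "carryover"


@dataclass(frozen=True)
class VolumeChain:
    """Laboratory volumes linking droplet occupancy to source-water concentration.

    Parameters
    ----------
    rvol : float
        Total ddPCR reaction volume, µL (default 22).
    tvol : float
        Template volume added to the reaction, µL (default 2).
    evol : float
        Extraction elution volume, µL (default 50).
    dvol : float
        Single droplet volume, µL (default 8.5e-4, i.e. ~0.85 nL).
    filt_vol : float
        Water volume filtered for the sample, litres (nominal 2).
    dilution_d : float
        Sample-specific template dilution factor (>= 1), e.g. the volumetric
        dilution introduced by the reverse-transcription reaction for RNA
        extracts. A diluted template lowers the per-droplet copy number, so
        recovering the source concentration multiplies by this factor.
    """

    rvol: float = 22.0
    tvol: float = 2.0
    evol: float = 50.0
    dvol: float = 8.5e-4
    filt_vol: float = 2.0
    dilution_d: float = 1.0

    def __post_init__(self) -> None:
        for name in ("rvol", "tvol", "evol", "dvol", "filt_vol", "dilution_d"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise InvalidInputError(f"VolumeChain.{name} must be finite and > 0, got {v}")
        if self.dvol >= self.rvol:
            raise InvalidInputError("droplet volume must be small relative to the reaction volume")
        if self.dilution_d < 1.0:
            raise InvalidInputError("dilution_d must be >= 1")

    @property
    def copies_per_litre_per_droplet_copy(self) -> float:
        """Factor g such that concentration C = g * mu (copies/L per copies/droplet)."""
        return (self.rvol * self.evol * self.dilution_d) / (
            self.dvol * self.tvol * self.filt_vol
        )

    def with_(self, **kwargs) -> "VolumeChain":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class DropletRecord:
    """One monoplex ddPCR well."""

    sample_id: str
    marker: Marker
    component: Component
    carboy: int
    time_nominal_h: float
    time_actual_h: float
    tech_rep: int
    droplets_total: int
    droplets_positive: int
    pore_size_um: float = 5.0

    def __post_init__(self) -> None:
        if self.droplets_total <= 0:
            raise InvalidInputError(f"{self.sample_id}: droplets_total must be > 0")
        if not (0 <= self.droplets_positive <= self.droplets_total):
            raise InvalidInputError(
                f"{self.sample_id}: need 0 <= positive ({self.droplets_positive}) "
                f"<= total ({self.droplets_total})"
            )
        if not 1 <= int(self.carboy) <= 4:
            raise InvalidInputError(f"{self.sample_id}: carboy must be in 1..4")
        if self.tech_rep < 1:
            raise InvalidInputError(f"{self.sample_id}: tech_rep must be >= 1")


@dataclass(frozen=True)
class OccupancyEstimate:
    """Poisson occupancy of a single well: positive fraction and mean copies/droplet."""

    p_hat: float
    mu: float
    ci_low: float
    ci_high: float
    saturated: bool = False


def estimate_occupancy(W: int, U: int, ci_level: float = 0.95) -> OccupancyEstimate:
    """Estimate droplet occupancy from W positive droplets out of U total.

    The positive count is binomial, ``W ~ Binomial(U, p)``, and under Poisson
    loading ``p = 1 - exp(-mu)``, so ``mu = -ln(1 - W/U)``. The interval on p
    is the exact (Clopper–Pearson) binomial interval. A well with W = U has no
    negative droplets, so mu is unbounded; it is returned as ``inf`` with the
    ``saturated`` flag set.
    """
    W, U = int(W), int(U)
    if U <= 0:
        raise InvalidInputError(f"droplet total U must be > 0, got {U}")
    if not 0 <= W <= U:
        raise InvalidInputError(f"need 0 <= W <= U, got W={W}, U={U}")
    p_hat = W / U
    alpha = 1.0 - ci_level
    ci_low = 0.0 if W == 0 else float(stats.beta.ppf(alpha / 2, W, U - W + 1))
    ci_high = 1.0 if W == U else float(stats.beta.ppf(1 - alpha / 2, W + 1, U - W))
    if W == U:
        return OccupancyEstimate(p_hat, math.inf, ci_low, ci_high, saturated=True)
    mu = -math.log1p(-p_hat)
    return OccupancyEstimate(p_hat, mu, ci_low, ci_high, saturated=False)


def mean_copies_to_sample_concentration(mu: float, chain: VolumeChain) -> float:
    """Convert mean copies per droplet to copies per litre of source water.

    The chain runs: copies/droplet → copies/µL reaction (÷dvol) → copies in the
    reaction (×rvol) → copies/µL template (÷tvol) → undiluted template (×d) →
    copies in the extract (×evol) → copies/L filtered water (÷filt_vol).
    """
    if not (np.isfinite(mu) and mu >= 0):
        raise InvalidInputError(f"mu must be finite and >= 0, got {mu}")
    return mu * chain.copies_per_litre_per_droplet_copy


def sample_concentration_to_mean_copies(concentration: float, chain: VolumeChain) -> float:
    """Exact inverse of :func:`mean_copies_to_sample_concentration`."""
    if not (np.isfinite(concentration) and concentration >= 0):
        raise InvalidInputError(f"concentration must be finite and >= 0, got {concentration}")
    return concentration / chain.copies_per_litre_per_droplet_copy


def subtract_no_rt(W_eRNA: int, W_noRT: int) -> int:
    """Subtract the No-RT control droplet count from the paired eRNA count.

    The No-RT reaction (no reverse transcriptase) quantifies residual DNA
    carryover in the RNA extract; its positives are subtracted at the droplet
    count level, floored at zero.
    """
    if W_eRNA < 0 or W_noRT < 0:
        raise InvalidInputError("droplet counts must be non-negative")
    return max(int(W_eRNA) - int(W_noRT), 0)


def apply_no_rt_subtraction(wells: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply No-RT subtraction to every eRNA well of a long-format well table.

    Each eRNA/emRNA well is paired with the No-RT control of the same marker,
    carboy, nominal time, pore size and technical replicate. Returns the
    adjusted table (No-RT rows dropped) and a per-well adjustment log.

    Raises
    ------
    ConfigurationError
        If an eRNA well has no matching No-RT control, naming the sample.
    """
    df = wells.copy()
    keys = ["marker", "carboy", "time_nominal_h", "pore_size_um", "tech_rep"]
    nort = df[df["component"] == Component.NO_RT.value]
    rna_mask = df["component"].isin([Component.EMRNA.value, Component.ERRNA.value])
    lookup = {tuple(row[k] for k in keys): int(row["droplets_positive"]) for _, row in nort.iterrows()}
    log_rows = []
    adjusted = df["droplets_positive"].copy()
    for idx, row in df[rna_mask].iterrows():
        key = tuple(row[k] for k in keys)
        if key not in lookup:
            raise ConfigurationError(
                f"eRNA well {row.get('sample_id', idx)!r} has no paired No-RT control "
                f"(marker={row['marker']}, carboy={row['carboy']}, t={row['time_nominal_h']})"
            )
        w_ctrl = lookup[key]
        w_adj = subtract_no_rt(int(row["droplets_positive"]), w_ctrl)
        log_rows.append(
            {
                "sample_id": row.get("sample_id", idx),
                "W_raw": int(row["droplets_positive"]),
                "W_noRT": w_ctrl,
                "W_adjusted": w_adj,
            }
        )
        adjusted.loc[idx] = w_adj
    out = df.loc[df["component"] != Component.NO_RT.value].copy()
    out["droplets_positive"] = adjusted.loc[out.index]
    return out, pd.DataFrame(log_rows)


@dataclass(frozen=True)
class SizeFractionProfile:
    """Distribution of a marker's signal over filter pore sizes at one timepoint."""

    fractions: Mapping[float, float]
    dominant_pore_um: float | None
    dominant_fraction: float
    passes_screen: bool
    threshold: float
    undefined: bool = False
    verdict: str = ""


def size_fraction_profile(
    concentrations: Mapping[float, float], threshold: float = 0.95
) -> SizeFractionProfile:
    """Fraction of total signal captured on each pore size of a serial filtration.

    Parameters
    ----------
    concentrations : mapping pore size (µm) -> concentration (copies/L)
    threshold : float
        Screening rule: if the dominant pore size captures more than this
        fraction of the total signal, downstream analysis is restricted to it.
    """
    if not concentrations:
        raise InvalidInputError("no pore sizes supplied")
    if any(c < 0 for c in concentrations.values()):
        raise InvalidInputError("concentrations must be non-negative")
    total = float(sum(concentrations.values()))
    if total == 0.0:
        return SizeFractionProfile(
            fractions={k: float("nan") for k in concentrations},
            dominant_pore_um=None,
            dominant_fraction=float("nan"),
            passes_screen=False,
            threshold=threshold,
            undefined=True,
            verdict="all-zero concentrations; fractions undefined",
        )
    fractions = {k: v / total for k, v in concentrations.items()}
    dominant = max(fractions, key=fractions.get)
    dom_frac = fractions[dominant]
    passes = dom_frac > threshold
    verdict = (
        f"restrict analysis to the {dominant:g} um fraction"
        if passes
        else "no single pore size dominates; keep all fractions"
    )
    return SizeFractionProfile(fractions, dominant, dom_frac, passes, threshold, False, verdict)


def concentration_table(wells: pd.DataFrame, default_chain: VolumeChain | None = None) -> pd.DataFrame:
    """Per-well concentration estimates with exact binomial intervals.

    Expects a long-format monoplex well table (columns as written by the
    synthetic generator / reader). Per-row ``filt_vol_L`` and ``dilution_d``
    override the default volume chain. Saturated wells (W = U) get infinite
    point estimates and a flag; they remain in the table but should be excluded
    from point-estimate summaries.
    """
    chain = default_chain or VolumeChain()
    rows = []
    for _, row in wells.iterrows():
        c = chain.with_(
            filt_vol=float(row.get("filt_vol_L", chain.filt_vol)),
            dilution_d=float(row.get("dilution_d", chain.dilution_d)),
        )
        occ = estimate_occupancy(int(row["droplets_positive"]), int(row["droplets_total"]))
        g = c.copies_per_litre_per_droplet_copy
        conc = math.inf if occ.saturated else occ.mu * g
        mu_low = -math.log1p(-occ.ci_low)
        mu_high = math.inf if occ.ci_high >= 1.0 else -math.log1p(-occ.ci_high)
        rows.append(
            {
                "sample_id": row.get("sample_id", ""),
                "marker": row["marker"],
                "component": row["component"],
                "carboy": row["carboy"],
                "time_actual_h": row["time_actual_h"],
                "pore_size_um": row.get("pore_size_um", 5.0),
                "tech_rep": row["tech_rep"],
                "p_hat": occ.p_hat,
                "mu": occ.mu,
                "concentration_copies_per_L": conc,
                "conc_ci_low": mu_low * g,
                "conc_ci_high": mu_high * g if math.isfinite(mu_high) else math.inf,
                "saturated": occ.saturated,
            }
        )
    return pd.DataFrame(rows)
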