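"""Time-sensitive molecular ratios ("molecular clocks").

A ratio of a fast-decaying to a slow-decaying nucleic-acid component declines
predictably after release, so its value indexes the age of the genetic
signal. Two ratios are supported out of the box: the proportion of long
(Bridge) relative to short (Cytb) mitochondrial fragments, and the proportion
of ribosomal eRNA relative to total 16S nucleic acids. Ratios are computed
per posterior draw and then summarized (median and 2.5/97.5% quantiles) per
time point and carboy — never as a ratio of summaries — and the trend over
the 0–24 h window is condensed into an ordinary-least-squares slope on the
pooled per-carboy posterior-median trajectories. The slope p-value is a
heuristic descriptor (grid points are autocorrelated), reported as such.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InvalidInputError
from .fit import PosteriorDraws

__all__ = [
    "RatioSpec",
    "RatioTrajectory",
    "ClockSlope",
    "BRIDGE_TO_CYTB",
    "ERRNA_PROPORTION_16S",
    "ratio_trajectory",
    "clock_slope",
    "default_grid",
]


def default_grid(t_max: float = 24.0, step: float = 0.5) -> np.ndarray:
    return np.arange(0.0, t_max + step / 2, step)


@dataclass(frozen=True)
class RatioSpec:
    """A molecular ratio: numerator component over a summed denominator set.

    The numerator is part of the denominator only if listed there explicitly,
    so both ``Bridge/Cytb`` and ``Bridge/(Bridge+Cytb)`` conventions are
    expressible.
    """

    numerator: str
    denominator: tuple[str, ...]
    label: str

    def __post_init__(self) -> None:
        if not self.denominator:
            raise InvalidInputError("denominator set must be non-empty")

    @property
    def is_proportion(self) -> bool:
        return self.numerator in self.denominator


#: Long (Bridge) vs short (Cytb) mitochondrial fragments. The default reads
#: the proportion as Bridge over total Cytb fragments.
BRIDGE_TO_CYTB = RatioSpec("Bridge_eDNA", ("Cytb_eDNA",), "Bridge:Cytb")
#: Alternative convention with the Bridge included in the denominator.
BRIDGE_PROPORTION = RatioSpec(
    "Bridge_eDNA", ("Bridge_eDNA", "Cytb_eDNA"), "Bridge:(Bridge+Cytb)"
)
#: Ribosomal eRNA over total 16S nucleic acids (eDNA + erRNA).
ERRNA_PROPORTION_16S = RatioSpec(
    "16S_erRNA", ("16S_erRNA", "16S_eDNA"), "erRNA:(erRNA+eDNA) 16S"
)


@dataclass
class RatioTrajectory:
    """Posterior ratio trajectory per carboy over a time grid."""

    spec: RatioSpec
    grid: np.ndarray
    table: pd.DataFrame  # columns: time_h, carboy, median, q2.5, q97.5
    n_excluded_draws: int = 0


def ratio_trajectory(
    draws: PosteriorDraws,
    spec: RatioSpec,
    grid: np.ndarray | None = None,
) -> RatioTrajectory:
    """Posterior trajectory of a molecular ratio, summarized per carboy.

    For every posterior draw and carboy, concentrations of all components in
    the spec are predicted on the grid and combined into the ratio; medians
    and the central 95% interval are then taken across draws. Draws in which
    the denominator vanishes at any grid time are excluded (counted).
    """
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    if grid.size < 1:
        raise InvalidInputError("empty time grid")
    components = {spec.numerator, *spec.denominator}
    available = set(draws.components())
    missing = components - available
    if missing:
        raise ConfigurationError(f"fit lacks components required by the ratio: {sorted(missing)}")
    rows = []
    n_excluded = 0
    for carboy in draws.carboys:
        num = draws.predict_concentration(spec.numerator, carboy, grid)
        den = np.zeros_like(num)
        for comp in spec.denominator:
            den = den + draws.predict_concentration(comp, carboy, grid)
        ok = (den > 0).all(axis=1)
        n_excluded += int((~ok).sum())
        ratio = num[ok] / den[ok]
        med = np.median(ratio, axis=0)
        lo = np.quantile(ratio, 0.025, axis=0)
        hi = np.quantile(ratio, 0.975, axis=0)
        for j, t in enumerate(grid):
            rows.append(
                {
                    "time_h": float(t),
                    "carboy": carboy,
                    "median": float(med[j]),
                    "q2.5": float(lo[j]),
                    "q97.5": float(hi[j]),
                }
            )
    return RatioTrajectory(spec, grid, pd.DataFrame(rows), n_excluded)


@dataclass(frozen=True)
class ClockSlope:
    """OLS trend of a ratio trajectory: slope per hour with fit diagnostics."""

    slope_per_h: float
    intercept: float
    r_squared: float
    p_value_heuristic: float
    zero_variance: bool = False


def clock_slope(traj: RatioTrajectory) -> ClockSlope:
    """Linear trend of the pooled (across carboys) posterior-median trajectory.

    The regression is unweighted OLS of the per-carboy median ratios on time,
    with all carboys pooled into one regression. A constant trajectory gets
    slope 0 and a zero-variance flag; its p-value is undefined (NaN).
    """
    df = traj.table
    if df["time_h"].nunique() < 3:
        raise InvalidInputError("need at least 3 grid points for a slope")
    y = df["median"].to_numpy()
    t = df["time_h"].to_numpy()
    if np.allclose(y, y[0], rtol=0, atol=1e-15):
        return ClockSlope(0.0, float(y[0]), 0.0, float("nan"), zero_variance=True)
    res = stats.linregress(t, y)
    return ClockSlope(
        slope_per_h=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value_heuristic=float(res.pvalue),
        zero_variance=False,
    )
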