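"""Hierarchical Bayesian estimation of decay parameters from droplet counts.

The observation model works directly on droplet counts. For a monoplex well
with W positive droplets out of U,

    W ~ Binomial(U, p),   cloglog(p) = ln(mu),

where mu is the mean copies per droplet implied by the source-water
concentration C(t) through the laboratory volume chain, and C(t) follows a
decay curve (by default the biphasic exponential) with carboy-specific
initial concentrations and decay rates shared across the three biological
replicates. Duplex 16S/D-loop wells enter through the exact four-category
multinomial parameterized by the per-droplet loads of free-16S, free-D-loop
and linked (Bridge) molecules, each decaying under its own curve — so Bridge
decay rates carry droplet-level uncertainty rather than being plugged in from
per-well point estimates.

Sampling uses affine-invariant ensemble MCMC (emcee). A "chain" is one
independent ensemble, thinned and flattened, so multi-chain diagnostics
(rank-normalized split R-hat, bulk ESS via arviz) apply as usual. Components
with no detections after their first detected timepoint are unidentifiable
beyond a single rate and are automatically reduced to the single-exponential
model, with t_x and lambda2 reported NA.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special

import emcee

from .ddpcr import VolumeChain
from .errors import (
    ConfigurationError,
    InvalidComparisonError,
    InvalidInputError,
)
from .models import DecayModelSpec, ParamSpec, get_model
from .simulate import DUPLEX_COMPONENTS, split_key

__all__ = [
    "MCMCConfig",
    "PriorConfig",
    "ModelDataset",
    "PosteriorDraws",
    "build_dataset",
    "fit_decay_model",
    "convergence_diagnostics",
    "compare_models_loo",
    "summarize_decay",
    "prior_posterior_overlap",
]

# arviz emits a refactor FutureWarning on import; it is not actionable here.
with warnings.catch_warnings():
    warnings.simplefilter("ignore", FutureWarning)
    import arviz as az

DUPLEX_GROUP_ID = "duplex_16S_Dloop"


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings.

    ``warmup`` is the number of discarded ensemble steps and ``draws`` the
    number of retained posterior draws, per chain; each chain is an
    independent ensemble of ``n_walkers`` walkers whose post-warmup states are
    kept every ``thin`` steps. Test-scale defaults; ``production_scale()`` gives
    the 4 x (5000 warmup + 10,000 draw) configuration.
    """

    n_chains: int = 4
    warmup: int = 1000
    draws: int = 2000
    thin: int = 4
    n_walkers: int | None = None

    def walkers_for(self, ndim: int) -> int:
        if self.n_walkers is not None:
            return max(self.n_walkers, 2 * ndim + 2)
        return max(32, 2 * ndim + 2)

    @staticmethod
    def production_scale() -> "MCMCConfig":
        return MCMCConfig(n_chains=4, warmup=5000, draws=10_000, thin=4)


@dataclass(frozen=True)
class PriorConfig:
    """Priors for the decay fit; all proper, all overridable.

    ln C0 per carboy-component is Normal centred on a method-of-moments
    estimate from the earliest timepoint with sd ``ln_c0_sd``. Shape-parameter
    priors default to the model menu's declarations (rates half-Normal(0, 1)
    per hour, t_x Uniform over ``t_x_bounds``); ``overrides`` replaces the
    prior tuple for a named parameter. ``order_constraint`` optionally imposes
    lambda2 < lambda1 (off by default so the biphasic shape must come from
    the data).
    """

    ln_c0_sd: float = 3.0
    t_x_bounds: tuple[float, float] = (12.0, 96.0)
    overrides: Mapping[str, tuple] = field(default_factory=dict)
    order_constraint: bool = False


# ----------------------------------------------------------------- dataset


@dataclass
class MonoplexGroup:
    group_id: str
    component: str
    W: np.ndarray
    U: np.ndarray
    t: np.ndarray
    t_nominal: np.ndarray
    carboy_idx: np.ndarray
    factor: np.ndarray  # copies/droplet per copies/L, per well
    well_ids: tuple[str, ...]


@dataclass
class DuplexGroup:
    group_id: str
    components: tuple[str, str, str]  # (free A, free B, linked)
    counts: np.ndarray  # (n, 4): both, a_only, b_only, neither
    U: np.ndarray
    t: np.ndarray
    t_nominal: np.ndarray
    carboy_idx: np.ndarray
    factor: np.ndarray
    well_ids: tuple[str, ...]


@dataclass
class ModelDataset:
    """Well-level data grouped for fitting.

    Each monoplex marker-component is an independent fit group; the duplex
    assay forms one joint group over (free 16S, free D-loop, Bridge). The
    control carboy is excluded from fitting but checked for zero signal.
    """

    monoplex_groups: list[MonoplexGroup]
    duplex_group: DuplexGroup | None
    carboys: tuple[int, ...]
    validation_warnings: tuple[str, ...] = ()

    @property
    def components(self) -> list[str]:
        out = [g.component for g in self.monoplex_groups]
        if self.duplex_group is not None:
            out.extend(self.duplex_group.components)
        return out

    @property
    def well_ids(self) -> tuple[str, ...]:
        ids: list[str] = []
        for g in self.monoplex_groups:
            ids.extend(g.well_ids)
        if self.duplex_group is not None:
            ids.extend(self.duplex_group.well_ids)
        return tuple(ids)


def _factor(chain: VolumeChain, row) -> float:
    c = chain.with_(
        filt_vol=float(row.get("filt_vol_L", chain.filt_vol)),
        dilution_d=float(row.get("dilution_d", chain.dilution_d)),
    )
    return 1.0 / c.copies_per_litre_per_droplet_copy


def build_dataset(
    monoplex: pd.DataFrame,
    duplex: pd.DataFrame | None = None,
    chain: VolumeChain | None = None,
    control_carboy: int = 4,
    include_baseline: bool = False,
    pore_size_um: float = 5.0,
) -> ModelDataset:
    """Assemble fit groups from validated well tables.

    Expects No-RT subtraction already applied (No-RT rows are rejected).
    Control-carboy wells are excluded from fitting; any positive droplet in
    them raises a validation warning. Baseline (negative-time) wells and
    non-primary pore-size fractions are excluded by default.
    """
    chain = chain or VolumeChain()
    warnings_list: list[str] = []
    mono = monoplex.copy() if monoplex is not None else pd.DataFrame()
    if len(mono) == 0:
        mono = pd.DataFrame(
            columns=[
                "sample_id", "marker", "component", "carboy", "time_nominal_h",
                "time_actual_h", "tech_rep", "pore_size_um", "droplets_total",
                "droplets_positive", "filt_vol_L", "dilution_d",
            ]
        )
    if (mono["component"] == "NoRT").any():
        raise ConfigurationError(
            "No-RT control rows present; apply apply_no_rt_subtraction() before building the dataset"
        )
    ctrl = mono[mono["carboy"] == control_carboy]
    if len(ctrl) and (ctrl["droplets_positive"] > 0).any():
        bad = ctrl.loc[ctrl["droplets_positive"] > 0, "sample_id"].tolist()
        warnings_list.append(f"control carboy has positive droplets in wells: {bad}")
    if duplex is not None and len(duplex):
        dctrl = duplex[duplex["carboy"] == control_carboy]
        pos = dctrl["n_both"] + dctrl["n_a_only"] + dctrl["n_b_only"]
        if len(dctrl) and (pos > 0).any():
            warnings_list.append("control carboy has positive droplets in duplex wells")

    def keep(df: pd.DataFrame) -> pd.DataFrame:
        out = df[df["carboy"] != control_carboy]
        out = out[np.isclose(out["pore_size_um"], pore_size_um)]
        if not include_baseline:
            out = out[out["time_nominal_h"] >= 0]
        return out

    mono = keep(mono)
    carboy_set = set(mono["carboy"].unique())
    if duplex is not None and len(duplex):
        carboy_set |= set(keep(duplex)["carboy"].unique())
    carboys = tuple(sorted(carboy_set))
    cidx = {c: i for i, c in enumerate(carboys)}

    groups: list[MonoplexGroup] = []
    for (marker, component), sub in mono.groupby(["marker", "component"], sort=True):
        key = f"{marker}_{component}"
        groups.append(
            MonoplexGroup(
                group_id=key,
                component=key,
                W=sub["droplets_positive"].to_numpy(dtype=np.int64),
                U=sub["droplets_total"].to_numpy(dtype=np.int64),
                t=sub["time_actual_h"].to_numpy(dtype=float),
                t_nominal=sub["time_nominal_h"].to_numpy(dtype=float),
                carboy_idx=sub["carboy"].map(cidx).to_numpy(dtype=np.int64),
                factor=np.array([_factor(chain, r) for _, r in sub.iterrows()]),
                well_ids=tuple(sub["sample_id"]),
            )
        )

    dgroup = None
    if duplex is not None and len(duplex):
        dup = keep(duplex)
        if len(dup):
            counts = dup[["n_both", "n_a_only", "n_b_only", "n_neither"]].to_numpy(dtype=np.int64)
            if not np.array_equal(counts.sum(axis=1), dup["droplets_total"].to_numpy()):
                raise InvalidInputError("duplex category counts do not sum to droplets_total")
            dgroup = DuplexGroup(
                group_id=DUPLEX_GROUP_ID,
                components=DUPLEX_COMPONENTS,
                counts=counts,
                U=dup["droplets_total"].to_numpy(dtype=np.int64),
                t=dup["time_actual_h"].to_numpy(dtype=float),
                t_nominal=dup["time_nominal_h"].to_numpy(dtype=float),
                carboy_idx=dup["carboy"].map(cidx).to_numpy(dtype=np.int64),
                factor=np.array([_factor(chain, r) for _, r in dup.iterrows()]),
                well_ids=tuple(dup["sample_id"]),
            )
    return ModelDataset(groups, dgroup, carboys, tuple(warnings_list))


# ------------------------------------------------------- identifiability


def _detections_after_first(W: np.ndarray, t: np.ndarray) -> bool:
    """True if any detection occurs at a timepoint later than the first detection."""
    if not (W > 0).any():
        return False
    t0 = t[W > 0].min()
    return bool(((W > 0) & (t > t0 + 1e-9)).any())


def _duplex_component_counts(g: DuplexGroup) -> dict[str, np.ndarray]:
    """Per-well positive-droplet pseudo-counts for each duplex component.

    Free markers count their positive droplets; the Bridge counts the excess
    of double positives over the number expected from chance co-occupancy.
    """
    both, a_only, b_only, neither = g.counts.T
    U = g.U.astype(float)
    qA = (b_only + neither) / U
    qB = (a_only + neither) / U
    expected = U * (1 - qA) * (1 - qB)
    excess = np.maximum(both - expected, 0.0)
    return {
        g.components[0]: (a_only + both).astype(float),
        g.components[1]: (b_only + both).astype(float),
        g.components[2]: excess,
    }


def _duplex_detections(g: DuplexGroup) -> dict[str, np.ndarray]:
    """Per-well detection indicators; the Bridge requires the double-positive
    excess to clear its chance-co-occupancy noise (3 sigma, Poisson scale)."""
    both, a_only, b_only, neither = g.counts.T
    pseudo = _duplex_component_counts(g)
    U = g.U.astype(float)
    qA = (b_only + neither) / U
    qB = (a_only + neither) / U
    expected = U * (1 - qA) * (1 - qB)
    return {
        g.components[0]: (a_only + both) > 0,
        g.components[1]: (b_only + both) > 0,
        g.components[2]: pseudo[g.components[2]] > 3.0 * np.sqrt(expected + 1.0),
    }


# --------------------------------------------------------------- log-prob


def _prior_logpdf(x: np.ndarray, prior: tuple, lo: float, hi: float) -> np.ndarray:
    kind = prior[0]
    out = np.where((x >= lo) & (x <= hi), 0.0, -np.inf)
    with np.errstate(divide="ignore", invalid="ignore"):
        if kind == "halfnormal":
            out = out - 0.5 * (x / prior[1]) ** 2
        elif kind == "uniform":
            out = np.where((x >= prior[1]) & (x <= prior[2]), 0.0, -np.inf)
        elif kind == "lognormal":
            lx = np.log(np.where(x > 0, x, np.nan))
            out = out + np.where(
                x > 0, -lx - 0.5 * ((lx - prior[1]) / prior[2]) ** 2, -np.inf
            )
        elif kind == "beta":
            a, b = prior[1], prior[2]
            ok = (x > 0) & (x < 1)
            xs = np.where(ok, x, 0.5)
            out = out + np.where(ok, (a - 1) * np.log(xs) + (b - 1) * np.log1p(-xs), -np.inf)
        else:  # pragma: no cover - guarded by ParamSpec construction
            raise ConfigurationError(f"unknown prior family {kind!r}")
    return np.where(np.isnan(out), -np.inf, out)


@dataclass
class _CompBlock:
    """Parameter layout for one component inside a fit group."""

    component: str
    spec: DecayModelSpec
    lnc0_slice: slice
    shape_slice: slice
    shape_specs: tuple[ParamSpec, ...]
    lnc0_center: np.ndarray  # per carboy
    reduced: bool = False  # single-exponential reduction applied
    lambda_init: float = 0.1  # data-driven starting decay rate


def _resolve_spec(model_id: str, priors: PriorConfig, t_max: float) -> DecayModelSpec:
    spec = get_model(model_id)
    new_params = []
    for p in spec.params:
        prior = priors.overrides.get(p.name, p.prior)
        lo, hi = p.lo, p.hi
        if p.name == "t_x":
            lo, hi = priors.t_x_bounds
            hi = min(hi, t_max)
            prior = priors.overrides.get("t_x", ("uniform", lo, hi))
        new_params.append(ParamSpec(p.name, prior, lo, hi))
    return DecayModelSpec(spec.model_id, tuple(new_params), spec.evaluator)


_INIT_VALUES = {
    "lambda1": 0.12,
    "lambda2": 0.03,
    "t_x": 36.0,
    "resid_frac": 0.05,
    "scale": 15.0,
    "shape": 1.0,
    "t50": 15.0,
    "hill": 1.0,
    "lambda_fast": 0.2,
    "lambda_slow": 0.02,
    "w_fast": 0.7,
}


def _mom_lambda(W, U, t, factor) -> float:
    """Crude initial decay rate: OLS slope of ln(MoM concentration) on time."""
    W = np.asarray(W, dtype=float)
    det = (W > 0) & (W < U)
    if det.sum() < 3 or np.ptp(t[det]) <= 0:
        return 0.1
    mu = -np.log1p(-W[det] / U[det])
    lnc = np.log(mu / factor[det])
    slope = np.polyfit(t[det], lnc, 1)[0]
    return float(min(max(-slope, 0.01), 3.0))


def _mom_lnc0(W, U, t, carboy_idx, factor, n_carboys) -> np.ndarray:
    """Method-of-moments ln C0 per carboy from the earliest timepoint wells."""
    centers = np.empty(n_carboys)
    for c in range(n_carboys):
        m = carboy_idx == c
        if not m.any():
            centers[c] = 0.0
            continue
        tc = t[m]
        first = np.isclose(tc, tc.min())
        w = np.maximum(W[m][first].astype(float), 0.5)
        u = U[m][first].astype(float)
        mu = -np.log1p(-np.minimum(w / u, 1 - 1e-9))
        conc = mu / factor[m][first]
        centers[c] = float(np.log(conc.mean()))
    return centers


class _GroupModel:
    """Vectorized log-posterior over walkers for one fit group."""

    def __init__(
        self,
        group: MonoplexGroup | DuplexGroup,
        model_ids: Mapping[str, str],
        priors: PriorConfig,
        n_carboys: int,
    ):
        self.group = group
        self.priors = priors
        self.n_carboys = n_carboys
        self.is_duplex = isinstance(group, DuplexGroup)
        t_max = float(group.t.max()) if len(group.t) else priors.t_x_bounds[1]
        comps = group.components if self.is_duplex else (group.component,)
        self.blocks: list[_CompBlock] = []
        off = 0
        for comp in comps:
            spec = _resolve_spec(model_ids[comp], priors, t_max)
            k = n_carboys
            p = len(spec.params)
            if self.is_duplex:
                # pseudo positive counts per well for the MoM centre
                pos = np.asarray(_duplex_component_counts(group)[comp])
            else:
                pos = group.W
            centers = _mom_lnc0(pos, group.U, group.t, group.carboy_idx, group.factor, k)
            lam_init = _mom_lambda(pos, group.U, group.t, group.factor)
            self.blocks.append(
                _CompBlock(
                    component=comp,
                    spec=spec,
                    lnc0_slice=slice(off, off + k),
                    shape_slice=slice(off + k, off + k + p),
                    shape_specs=spec.params,
                    lnc0_center=centers,
                    reduced=model_ids[comp] == "single_exponential",
                    lambda_init=lam_init,
                )
            )
            off += k + p
        self.ndim = off
        self.param_names: list[str] = []
        for b in self.blocks:
            self.param_names += [f"{b.component}.ln_c0[c{c + 1}]" for c in range(n_carboys)]
            self.param_names += [f"{b.component}.{p.name}" for p in b.shape_specs]

    # -- concentrations per component, vectorized over walker batch
    def _concentrations(self, theta: np.ndarray, t: np.ndarray, carboy_idx: np.ndarray):
        out = {}
        with np.errstate(over="ignore", invalid="ignore"):
            for b in self.blocks:
                lnc0 = np.minimum(theta[:, b.lnc0_slice], 500.0)  # cap to avoid inf C0
                c0 = np.exp(lnc0[:, carboy_idx])  # (L, n)
                shape = [theta[:, b.shape_slice][:, j : j + 1] for j in range(len(b.shape_specs))]
                out[b.component] = b.spec.evaluator(t[None, :], c0, *shape)
        return out

    def log_prior(self, theta: np.ndarray) -> np.ndarray:
        lp = np.zeros(theta.shape[0])
        for b in self.blocks:
            lnc0 = theta[:, b.lnc0_slice]
            z = (lnc0 - b.lnc0_center[None, :]) / self.priors.ln_c0_sd
            lp = lp - 0.5 * np.sum(z**2, axis=1)
            sh = theta[:, b.shape_slice]
            names = [p.name for p in b.shape_specs]
            for j, p in enumerate(b.shape_specs):
                lp = lp + _prior_logpdf(sh[:, j], p.prior, p.lo, p.hi)
            if self.priors.order_constraint and "lambda1" in names and "lambda2" in names:
                lam1 = sh[:, names.index("lambda1")]
                lam2 = sh[:, names.index("lambda2")]
                lp = np.where(lam2 < lam1, lp, -np.inf)
        return lp

    def log_likelihood(self, theta: np.ndarray, pointwise: bool = False) -> np.ndarray:
        g = self.group
        conc = self._concentrations(theta, g.t, g.carboy_idx)
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            if not self.is_duplex:
                mu = conc[g.component] * g.factor[None, :]
                W, U = g.W[None, :], g.U[None, :]
                log_p = np.log(-np.expm1(-mu))
                ll = np.where(W > 0, W * log_p, 0.0) + (U - W) * (-mu)
                if pointwise:
                    ll = ll + (
                        special.gammaln(U + 1)
                        - special.gammaln(W + 1)
                        - special.gammaln(U - W + 1)
                    )
            else:
                mu_a = conc[g.components[0]] * g.factor[None, :]
                mu_b = conc[g.components[1]] * g.factor[None, :]
                mu_l = conc[g.components[2]] * g.factor[None, :]
                q00 = np.exp(-(mu_a + mu_b + mu_l))
                qa = np.exp(-(mu_b + mu_l)) - q00  # a_only
                qb = np.exp(-(mu_a + mu_l)) - q00  # b_only
                qboth = np.maximum(1.0 - q00 - qa - qb, 1e-300)
                qa = np.maximum(qa, 1e-300)
                qb = np.maximum(qb, 1e-300)
                n = g.counts  # (n, 4): both, a_only, b_only, neither
                ll = (
                    n[None, :, 0] * np.log(qboth)
                    + n[None, :, 1] * np.log(qa)
                    + n[None, :, 2] * np.log(qb)
                    + n[None, :, 3] * (-(mu_a + mu_b + mu_l))
                )
                # zero-count categories with zero probability contribute 0, not nan
                ll = np.where(np.isnan(ll), -np.inf, ll)
                if pointwise:
                    U = g.U[None, :]
                    ll = ll + special.gammaln(U + 1) - special.gammaln(n + 1).sum(axis=1)[None, :]
        ll = np.where(np.isnan(ll), -np.inf, ll)
        return ll if pointwise else ll.sum(axis=1)

    def __call__(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        lp = self.log_prior(theta)
        ok = np.isfinite(lp)
        out = np.full(theta.shape[0], -np.inf)
        if ok.any():
            out[ok] = lp[ok] + self.log_likelihood(theta[ok])
        return out

    def initial_point(self) -> np.ndarray:
        x = np.empty(self.ndim)
        for b in self.blocks:
            x[b.lnc0_slice] = b.lnc0_center
            vals = []
            for p in b.shape_specs:
                v = _INIT_VALUES.get(p.name, 1.0)
                if p.name in ("lambda1", "lambda_fast"):
                    v = b.lambda_init
                elif p.name == "lambda2":
                    v = max(b.lambda_init / 5.0, 0.005)
                elif p.name in ("scale", "t50"):
                    v = 1.0 / b.lambda_init
                lo = p.lo if p.prior[0] != "uniform" else p.prior[1]
                hi = p.hi if p.prior[0] != "uniform" else p.prior[2]
                vals.append(min(max(v, lo + 1e-3), hi - 1e-3 if np.isfinite(hi) else v))
            x[b.shape_slice] = vals
        return x

    def initial_walkers(self, n_walkers: int, rng: np.random.Generator) -> np.ndarray:
        """Over-dispersed starting ensemble around the method-of-moments point.

        Differential-evolution proposals scale with the current ensemble
        spread, so walkers start deliberately wide (half a log-unit on
        magnitudes, full prior range on bounded parameters) and contract onto
        the posterior during warmup.
        """
        x0 = self.initial_point()
        pts = np.empty((n_walkers, self.ndim))
        for i in range(n_walkers):
            for attempt in range(200):
                x = x0.copy()
                for b in self.blocks:
                    x[b.lnc0_slice] += rng.normal(0, 0.5, size=self.n_carboys)
                    for j, p in enumerate(b.shape_specs):
                        idx = b.shape_slice.start + j
                        if p.prior[0] in ("uniform", "beta"):
                            lo = p.prior[1] if p.prior[0] == "uniform" else 0.0
                            hi = p.prior[2] if p.prior[0] == "uniform" else 1.0
                            if p.name == "t_x":
                                # start inside the sampling gap where the
                                # transition lives; wide starts strand whole
                                # ensembles in a metastable late-transition mode
                                lo, hi = max(lo, 24.0), min(hi, 48.0)
                            x[idx] = rng.uniform(lo + 1e-6, hi - 1e-6)
                        else:
                            x[idx] = max(x0[idx], 1e-4) * np.exp(rng.normal(0, 0.5))
                if np.isfinite(self(x[None, :])[0]):
                    pts[i] = x
                    break
            else:  # pragma: no cover
                raise ConfigurationError("could not initialize walkers in the prior support")
        return pts


# ------------------------------------------------------------ posterior


@dataclass
class GroupDraws:
    group_id: str
    param_names: list[str]
    draws: np.ndarray  # (n_chains, n_draws, ndim)
    model: _GroupModel
    model_ids: dict[str, str]


class PosteriorDraws:
    """Labeled MCMC draws for all fit groups of one model fit."""

    def __init__(
        self,
        groups: dict[str, GroupDraws],
        carboys: tuple[int, ...],
        model_id: str,
        mcmc: MCMCConfig,
        seed: int,
        well_ids: tuple[str, ...],
        na_components: dict[str, str],
    ):
        self.groups = groups
        self.carboys = carboys
        self.model_id = model_id
        self.mcmc = mcmc
        self.seed = seed
        self.well_ids = well_ids
        self.na_components = na_components
        self._log_lik: np.ndarray | None = None

    @property
    def n_chains(self) -> int:
        return next(iter(self.groups.values())).draws.shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.groups.values())).draws.shape[1]

    def components(self) -> list[str]:
        out = []
        for g in self.groups.values():
            comps = (
                list(g.model.group.components)
                if g.model.is_duplex
                else [g.model.group.component]
            )
            out.extend(comps)
        return out

    def _block(self, component: str):
        for g in self.groups.values():
            for b in g.model.blocks:
                if b.component == component:
                    return g, b
        raise ConfigurationError(f"component {component!r} not in this fit")

    def parameter(self, name: str) -> np.ndarray:
        """Draws of a scalar parameter, shape (chains, draws)."""
        for g in self.groups.values():
            if name in g.param_names:
                return g.draws[:, :, g.param_names.index(name)]
        raise ConfigurationError(f"unknown parameter {name!r}")

    def shape_param(self, component: str, pname: str) -> np.ndarray:
        return self.parameter(f"{component}.{pname}")

    def predict_concentration(
        self, component: str, carboy: int, t_grid: np.ndarray
    ) -> np.ndarray:
        """Posterior concentration trajectories, shape (chains*draws, len(t_grid))."""
        g, b = self._block(component)
        flat = g.draws.reshape(-1, g.draws.shape[-1])
        cpos = list(self.carboys).index(carboy)
        c0 = np.exp(flat[:, b.lnc0_slice][:, cpos : cpos + 1])
        shape = [flat[:, b.shape_slice][:, j : j + 1] for j in range(len(b.shape_specs))]
        return b.spec.evaluator(np.asarray(t_grid, float)[None, :], c0, *shape)

    def pointwise_log_likelihood(self, batch: int = 512) -> np.ndarray:
        """Pointwise log-likelihood, shape (chains, draws, n_wells)."""
        if self._log_lik is not None:
            return self._log_lik
        chunks = []
        for g in self.groups.values():
            nc, nd, ndim = g.draws.shape
            flat = g.draws.reshape(-1, ndim)
            lls = [
                g.model.log_likelihood(flat[i : i + batch], pointwise=True)
                for i in range(0, flat.shape[0], batch)
            ]
            chunks.append(np.concatenate(lls, axis=0).reshape(nc, nd, -1))
        self._log_lik = np.concatenate(chunks, axis=2)
        return self._log_lik

    def to_inference_data(self, include_log_likelihood: bool = False) -> "az.InferenceData":
        posterior = {}
        for g in self.groups.values():
            for j, name in enumerate(g.param_names):
                posterior[name] = g.draws[:, :, j]
        kwargs = {"posterior": posterior}
        if include_log_likelihood:
            kwargs["log_likelihood"] = {"W": self.pointwise_log_likelihood()}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return az.from_dict(**kwargs)


# ------------------------------------------------------------------ fit


def fit_decay_model(
    dataset: ModelDataset,
    model_id: str = "biphasic",
    priors: PriorConfig | None = None,
    mcmc: MCMCConfig | None = None,
    seed: int = 0,
) -> PosteriorDraws:
    """Sample the joint posterior of decay parameters for every fit group.

    Groups (each monoplex marker-component; the duplex trio jointly) share no
    parameters and are sampled independently; chains are independent
    ensembles seeded from ``seed``. Components failing the detection rule
    (no detections after their first detected timepoint) are reduced to the
    single-exponential model and flagged NA for t_x / lambda2.
    """
    priors = priors or PriorConfig()
    mcmc = mcmc or MCMCConfig()
    if not dataset.monoplex_groups and dataset.duplex_group is None:
        raise ConfigurationError("dataset has no fit groups")

    na_components: dict[str, str] = {}
    group_draws: dict[str, GroupDraws] = {}
    ss = np.random.SeedSequence(seed)
    groups: list[MonoplexGroup | DuplexGroup] = list(dataset.monoplex_groups)
    if dataset.duplex_group is not None:
        groups.append(dataset.duplex_group)

    for group in groups:
        comps = group.components if isinstance(group, DuplexGroup) else (group.component,)
        model_ids = {}
        for comp in comps:
            mid = model_id
            if model_id == "biphasic":
                if isinstance(group, DuplexGroup):
                    pos = _duplex_detections(group)[comp].astype(int)
                else:
                    pos = group.W
                if not _detections_after_first(np.asarray(pos), group.t_nominal):
                    mid = "single_exponential"
                    na_components[comp] = "no detections after first detected timepoint"
            model_ids[comp] = mid
        gm = _GroupModel(group, model_ids, priors, len(dataset.carboys))
        n_walkers = mcmc.walkers_for(gm.ndim)
        steps_post = math.ceil(mcmc.draws / n_walkers) * mcmc.thin
        chains = []
        for child in ss.spawn(mcmc.n_chains):
            rng = np.random.default_rng(child)
            # Differential-evolution moves mix well on the correlated
            # (ln C0, lambda1, t_x) geometry; the stretch component contracts
            # distant walkers from the over-dispersed start geometrically.
            moves = [
                (emcee.moves.DEMove(), 0.6),
                (emcee.moves.DESnookerMove(), 0.2),
                (emcee.moves.StretchMove(), 0.2),
            ]
            sampler = emcee.EnsembleSampler(n_walkers, gm.ndim, gm, vectorize=True, moves=moves)
            # emcee draws proposals from a legacy RandomState; seed it from the
            # same chain-specific stream for reproducibility.
            sampler._random = np.random.RandomState(child.generate_state(1)[0] % (2**31))
            p0 = gm.initial_walkers(n_walkers, rng)
            state = sampler.run_mcmc(p0, mcmc.warmup + steps_post, progress=False, skip_initial_state_check=True)
            raw = sampler.get_chain(discard=mcmc.warmup, thin=mcmc.thin)  # (S, L, ndim)
            flat = raw.reshape(-1, gm.ndim)  # step-major
            if flat.shape[0] < mcmc.draws:  # pragma: no cover
                raise ConfigurationError("insufficient post-warmup draws; increase steps")
            chains.append(flat[: mcmc.draws])
        draws = np.stack(chains, axis=0)
        group_draws[group.group_id] = GroupDraws(
            group.group_id, gm.param_names, draws, gm, model_ids
        )
    return PosteriorDraws(
        group_draws,
        dataset.carboys,
        model_id,
        mcmc,
        seed,
        dataset.well_ids,
        na_components,
    )


# ---------------------------------------------------------- diagnostics


def convergence_diagnostics(
    draws: PosteriorDraws,
    rhat_threshold: float = 1.005,
    ess_threshold: float = 500.0,
) -> pd.DataFrame:
    """Rank-normalized split R-hat and bulk ESS per parameter, with pass flags."""
    if draws.n_chains < 2:
        raise InvalidInputError("R-hat requires at least 2 chains")
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for g in draws.groups.values():
            for j, name in enumerate(g.param_names):
                arr = g.draws[:, :, j]
                rhat = float(az.rhat(az.convert_to_dataset(arr))["x"].values.item())
                ess = float(az.ess(az.convert_to_dataset(arr))["x"].values.item())
                rows.append(
                    {
                        "parameter": name,
                        "rhat": rhat,
                        "ess_bulk": ess,
                        "rhat_ok": rhat < rhat_threshold,
                        "ess_ok": ess > ess_threshold,
                    }
                )
    df = pd.DataFrame(rows)
    df.attrs["all_ok"] = bool(df["rhat_ok"].all() and df["ess_ok"].all())
    return df


def _loo_pointwise(ll: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-well PSIS-LOO elpd from a (chain, draw, well) log-likelihood array.

    Wells whose log-likelihood is numerically constant across draws (e.g.
    all-zero wells far below the detection limit) have exact LOO equal to that
    constant; PSIS is applied to the remaining wells. Returns (loo_i,
    fraction of wells with Pareto k > 0.7).
    """
    n = ll.shape[2]
    spread = ll.max(axis=(0, 1)) - ll.min(axis=(0, 1))
    const = spread < 1e-10
    loo_i = np.empty(n)
    loo_i[const] = ll[0, 0, const]
    bad_frac = 0.0
    if (~const).any():
        idata = az.from_dict(
            posterior={"_z": np.zeros(ll.shape[:2])},
            log_likelihood={"W": ll[:, :, ~const]},
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = az.loo(idata, pointwise=True)
        loo_i[~const] = np.asarray(res.loo_i.values)
        k = np.asarray(res.pareto_k.values)
        bad_frac = float((k > 0.7).mean())
    return loo_i, bad_frac


def compare_models_loo(
    fits: Sequence[tuple[str, PosteriorDraws]],
) -> pd.DataFrame:
    """Rank candidate decay models by PSIS leave-one-out cross-validation.

    All fits must be on the identical well set. Per-well expected log
    predictive densities come from Pareto-smoothed importance sampling;
    the table reports each model's elpd_loo with its SE, the difference to
    the best model, and the SE of that difference (computed from the paired
    per-well elpd differences). Best model first.
    """
    if len(fits) < 2:
        raise InvalidComparisonError("need at least two fits to compare")
    ref = fits[0][1].well_ids
    for mid, f in fits[1:]:
        if f.well_ids != ref:
            raise InvalidComparisonError(f"fit {mid!r} was run on a different well set")
    n = len(ref)
    per_model: dict[str, tuple[np.ndarray, float]] = {}
    for mid, f in fits:
        per_model[mid] = _loo_pointwise(f.pointwise_log_likelihood())
    rows = []
    order = sorted(per_model, key=lambda m: -per_model[m][0].sum())
    best = order[0]
    for rank, mid in enumerate(order):
        loo_i, bad = per_model[mid]
        diff_i = per_model[best][0] - loo_i
        rows.append(
            {
                "model": mid,
                "rank": rank,
                "elpd_loo": float(loo_i.sum()),
                "se": float(np.sqrt(n * loo_i.var(ddof=1))),
                "elpd_diff": float(diff_i.sum()),
                "dse": float(np.sqrt(n * diff_i.var(ddof=1))) if rank > 0 else 0.0,
                "bad_pareto_k_frac": bad,
            }
        )
    return pd.DataFrame(rows).set_index("model")


_PHASE2_NAMES = ("lambda2", "t_x")


def summarize_decay(draws: PosteriorDraws) -> pd.DataFrame:
    """Posterior summary per marker-component, mirroring the decay-rate table.

    Columns: posterior mean and central 95% interval for lambda1, posterior
    median t_x, posterior mean lambda2. Components reduced to a single phase
    carry NA for t_x / lambda2 with the reason recorded.
    """
    rows = []
    for comp in draws.components():
        marker, component = split_key(comp)
        g, b = draws._block(comp)
        names = [p.name for p in b.shape_specs]
        flat = g.draws.reshape(-1, g.draws.shape[-1])[:, b.shape_slice]

        def col(pname):
            return flat[:, names.index(pname)] if pname in names else None

        lam1 = col("lambda1")
        row = {
            "marker": marker,
            "component": component,
            "model": g.model_ids[comp],
            "lambda1_mean": float(np.mean(lam1)) if lam1 is not None else np.nan,
            "lambda1_q2.5": float(np.quantile(lam1, 0.025)) if lam1 is not None else np.nan,
            "lambda1_q97.5": float(np.quantile(lam1, 0.975)) if lam1 is not None else np.nan,
            "t_x_median": np.nan,
            "lambda2_mean": np.nan,
            "na_reason": draws.na_components.get(comp, ""),
        }
        tx, lam2 = col("t_x"), col("lambda2")
        if comp not in draws.na_components:
            if tx is not None:
                row["t_x_median"] = float(np.median(tx))
            if lam2 is not None:
                row["lambda2_mean"] = float(np.mean(lam2))
        rows.append(row)
    return pd.DataFrame(rows)


def prior_posterior_overlap(
    draws: PosteriorDraws, component: str, pname: str = "t_x", bins: int = 40
) -> float:
    """Overlap between the posterior of a parameter and its prior.

    Computed as the integral of the pointwise minimum of the two densities
    (1.0 = posterior identical to prior). Useful as an identifiability
    diagnostic: when the data carry no information about t_x (e.g. lambda1 =
    lambda2), the posterior reproduces the prior and the overlap is near 1.
    Implemented for uniform-prior parameters.
    """
    g, b = draws._block(component)
    spec = {p.name: p for p in b.shape_specs}[pname]
    if spec.prior[0] != "uniform":
        raise ConfigurationError("overlap statistic implemented for uniform priors only")
    lo, hi = spec.prior[1], spec.prior[2]
    samples = draws.shape_param(component, pname).ravel()
    hist, edges = np.histogram(samples, bins=bins, range=(lo, hi), density=True)
    prior_dens = 1.0 / (hi - lo)
    widths = np.diff(edges)
    return float(np.sum(np.minimum(hist, prior_dens) * widths))
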