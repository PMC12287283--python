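"""Candidate decay-model family for environmental nucleic acids.

The central model is the biphasic exponential: a steep first-phase loss at
rate λ1 up to a transition time t_x, then a slow persistent tail at rate λ2,

    C(t) = C0 · exp(−λ1 t)                      for t < t_x,
    C(t) = C(t_x) · exp(−λ2 (t − t_x))          for t ≥ t_x,

with C(t_x) = C0 · exp(−λ1 t_x), so the curve is continuous at t_x. The menu
around it spans the standard empirical decay-curve families used for eDNA:
single exponential, exponential with a constant residual pool, Weibull
(stretched exponential), a Hill-type power-law tail, and a two-pool
exponential mixture. All evaluators are closed-form and non-increasing in
time for non-negative rate parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np

from .errors import ConfigurationError, InvalidInputError

__all__ = [
    "BiphasicParams",
    "DecayModelSpec",
    "MODEL_MENU",
    "biphasic_concentration",
    "evaluate_model",
    "get_model",
]


@dataclass(frozen=True)
class BiphasicParams:
    """Biphasic-decay parameters for one marker-component.

    c0 : initial concentration, copies/L
    lambda1, lambda2 : first- and second-phase decay rates, 1/h
    t_x : transition time between phases, h
    """

    c0: float
    lambda1: float
    lambda2: float
    t_x: float

    def __post_init__(self) -> None:
        if not self.c0 > 0:
            raise InvalidInputError(f"c0 must be > 0, got {self.c0}")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise InvalidInputError("decay rates must be >= 0")
        if not self.t_x > 0:
            raise InvalidInputError(f"t_x must be > 0, got {self.t_x}")


def biphasic_concentration(params: BiphasicParams, t) -> np.ndarray | float:
    """Evaluate the biphasic decay curve at time(s) t (hours, >= 0)."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise InvalidInputError("t must be >= 0")
    out = _biphasic(t_arr, params.c0, params.lambda1, params.lambda2, params.t_x)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def _biphasic(t, c0, lam1, lam2, t_x):
    # np.where evaluates both branches; both are finite for t >= 0.
    c_break = c0 * np.exp(-lam1 * t_x)
    return np.where(t < t_x, c0 * np.exp(-lam1 * t), c_break * np.exp(-lam2 * (t - t_x)))


def _single_exponential(t, c0, lam):
    return c0 * np.exp(-lam * t)


def _exponential_constant(t, c0, lam, resid_frac):
    # Decaying pool plus a non-decaying residual fraction of the initial signal.
    return c0 * ((1.0 - resid_frac) * np.exp(-lam * t) + resid_frac)


def _weibull(t, c0, scale, shape):
    return c0 * np.exp(-np.power(t / scale, shape))


def _power_law(t, c0, t50, hill):
    return c0 / (1.0 + np.power(t / t50, hill))


def _double_exponential(t, c0, lam_fast, lam_slow, w_fast):
    return c0 * (w_fast * np.exp(-lam_fast * t) + (1.0 - w_fast) * np.exp(-lam_slow * t))


@dataclass(frozen=True)
class ParamSpec:
    """One shape parameter: name, prior family and hyperparameters, support.

    Prior families understood by the fitter: ``halfnormal(scale)``,
    ``uniform(lo, hi)``, ``lognormal(mu, sd)``, ``beta(a, b)``.
    """

    name: str
    prior: tuple
    lo: float = 0.0
    hi: float = np.inf


@dataclass(frozen=True)
class DecayModelSpec:
    """A candidate decay model: identity, shape parameters, closed-form evaluator.

    The evaluator signature is ``f(t, c0, *shape_params)`` and must return a
    positive concentration for positive c0 and t >= 0. C0 handling (per-carboy,
    log-normal prior) is common to all models and owned by the fitter.
    """

    model_id: str
    params: tuple[ParamSpec, ...]
    evaluator: Callable

    @property
    def param_names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.params)

    def __call__(self, t, c0, *shape) -> np.ndarray:
        return self.evaluator(np.asarray(t, dtype=float), c0, *shape)


MODEL_MENU: Mapping[str, DecayModelSpec] = {
    "single_exponential": DecayModelSpec(
        "single_exponential",
        (ParamSpec("lambda1", ("halfnormal", 1.0)),),
        _single_exponential,
    ),
    "biphasic": DecayModelSpec(
        "biphasic",
        (
            ParamSpec("lambda1", ("halfnormal", 1.0)),
            ParamSpec("lambda2", ("halfnormal", 1.0)),
            ParamSpec("t_x", ("uniform", 12.0, 96.0), lo=12.0, hi=96.0),
        ),
        _biphasic,
    ),
    "exponential_constant": DecayModelSpec(
        "exponential_constant",
        (
            ParamSpec("lambda1", ("halfnormal", 1.0)),
            ParamSpec("resid_frac", ("beta", 1.0, 9.0), lo=0.0, hi=1.0),
        ),
        _exponential_constant,
    ),
    "weibull": DecayModelSpec(
        "weibull",
        (
            ParamSpec("scale", ("halfnormal", 50.0)),
            ParamSpec("shape", ("lognormal", 0.0, 0.5)),
        ),
        _weibull,
    ),
    "power_law": DecayModelSpec(
        "power_law",
        (
            ParamSpec("t50", ("halfnormal", 50.0)),
            ParamSpec("hill", ("lognormal", 0.0, 0.5)),
        ),
        _power_law,
    ),
    "double_exponential": DecayModelSpec(
        "double_exponential",
        (
            ParamSpec("lambda_fast", ("halfnormal", 1.0)),
            ParamSpec("lambda_slow", ("halfnormal", 0.1)),
            ParamSpec("w_fast", ("beta", 2.0, 2.0), lo=0.0, hi=1.0),
        ),
        _double_exponential,
    ),
}


def get_model(model_id: str) -> DecayModelSpec:
    try:
        return MODEL_MENU[model_id]
    except KeyError:
        raise ConfigurationError(
            f"unknown model_id {model_id!r}; choose from {sorted(MODEL_MENU)}"
        ) from None


def evaluate_model(model_id: str, params: Mapping[str, float], t) -> np.ndarray | float:
    """Evaluate a menu model at time(s) t from a named-parameter mapping.

    ``params`` must contain ``c0`` plus the model's shape parameters.
    """
    spec = get_model(model_id)
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise InvalidInputError("t must be >= 0")
    missing = {"c0", *spec.param_names} - set(params)
    if missing:
        raise ConfigurationError(f"model {model_id!r} missing parameters: {sorted(missing)}")
    out = spec(t_arr, params["c0"], *(params[n] for n in spec.param_names))
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out
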