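"""Thermal performance curve (TPC) model families.

A thermal performance curve describes the unimodal response of a biological
rate (here: exploratory movement speed, m/s) to body temperature (degrees C):
the rate rises roughly exponentially towards an optimum and collapses sharply
above it.  This module defines the five candidate families compared during
model selection:

``gaussian``
    r_max * exp(-0.5 * ((T - T_opt) / a)**2)
``modified_gaussian``
    r_max * exp(-0.5 * (|T - T_opt| / a)**b) — shape ``b`` relaxes the
    Gaussian kurtosis; ``b = 2`` recovers the plain Gaussian.
``quadratic``
    a + b*T + c*T**2
``weibull``
    four-parameter Weibull curve with amplitude ``a`` at the optimum,
    optimum ``T_opt``, scale ``b`` and shape ``c > 1``.
``pawar``
    a Sharpe–Schoolfield curve re-parameterised so that the optimum
    temperature ``T_opt`` is an explicit parameter and the curve's maximum
    falls exactly at ``T_opt``::

        r(T) = r_ref * exp(-E/k * (1/(T+273.15) - 1/(T_ref+273.15)))
               / (1 + (E/(E_h-E)) * exp((E_h/k) * (1/(T_opt+273.15) - 1/(T+273.15))))

    with activation energy ``E`` (eV), deactivation energy ``E_h > E`` (eV),
    Boltzmann constant ``k`` and reference temperature ``T_ref = 15`` degrees C.

All models take temperature in degrees C at the interface; the Kelvin
conversion (+273.15) happens internally.  Rates carry the units of the
fitted response (m/s for speed data).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "BOLTZMANN_EV",
    "T_REF_C",
    "KELVIN_OFFSET",
    "Constants",
    "CONSTANTS",
    "TPCModelSpec",
    "ParamTransform",
    "MODEL_NAMES",
    "model_spec",
    "eval_model",
    "sharpe_schoolfield_factor",
]

#: Boltzmann constant in eV/K.
BOLTZMANN_EV = 8.617e-5
#: Reference temperature for the Sharpe–Schoolfield normalisation, degrees C.
T_REF_C = 15.0
#: Celsius -> Kelvin offset.
KELVIN_OFFSET = 273.15


@dataclass(frozen=True)
class Constants:
    """Physical constants of the thermal models (immutable)."""

    k: float = BOLTZMANN_EV
    t_ref_c: float = T_REF_C
    kelvin_offset: float = KELVIN_OFFSET


CONSTANTS = Constants()


def _as_temp(T):
    T = np.asarray(T, dtype=float)
    return T


def _maybe_scalar(out, T):
    if np.ndim(T) == 0:
        return float(out)
    return out


def sharpe_schoolfield_factor(T, e: float, e_h: float, t_opt: float,
                              t_ref: float = T_REF_C):
    """Dimensionless Sharpe–Schoolfield thermal factor.

    Equals the ``pawar`` model with unit amplitude: a Boltzmann–Arrhenius
    rise below the optimum divided by a high-temperature deactivation term.
    The factor's maximum over temperature falls exactly at ``t_opt``.

    Parameters
    ----------
    T : array_like
        Temperature, degrees C.
    e, e_h : float
        Activation and deactivation energies in eV; requires ``e_h > e > 0``.
    t_opt : float
        Optimum temperature, degrees C.
    t_ref : float
        Reference temperature for the normalisation, degrees C.
    """
    if not (e > 0.0):
        raise ValueError(f"activation energy E must be > 0, got {e}")
    if not (e_h > e):
        raise ValueError(
            f"deactivation energy E_h must exceed E (got E_h={e_h}, E={e})")
    Ta = _as_temp(T)
    u = 1.0 / (Ta + KELVIN_OFFSET)
    u_ref = 1.0 / (t_ref + KELVIN_OFFSET)
    u_opt = 1.0 / (t_opt + KELVIN_OFFSET)
    num = np.exp(-e / BOLTZMANN_EV * (u - u_ref))
    den = 1.0 + (e / (e_h - e)) * np.exp(e_h / BOLTZMANN_EV * (u_opt - u))
    return _maybe_scalar(num / den, T)


# ---------------------------------------------------------------------------
# model functions: f(params, T) -> rate
# ---------------------------------------------------------------------------

def _gaussian(params, T):
    r_max, t_opt, a = params
    Ta = _as_temp(T)
    return _maybe_scalar(r_max * np.exp(-0.5 * ((Ta - t_opt) / a) ** 2), T)


def _modified_gaussian(params, T):
    r_max, t_opt, a, b = params
    Ta = _as_temp(T)
    return _maybe_scalar(
        r_max * np.exp(-0.5 * (np.abs(Ta - t_opt) / a) ** b), T)


def _quadratic(params, T):
    a, b, c = params
    Ta = _as_temp(T)
    return _maybe_scalar(a + b * Ta + c * Ta * Ta, T)


def _weibull(params, T):
    # 4-parameter Weibull TPC; amplitude a is the rate at T_opt, c > 1.
    a, t_opt, b, c = params
    if not c > 1.0:
        raise ValueError(f"weibull shape c must be > 1, got {c}")
    Ta = _as_temp(T)
    g = ((c - 1.0) / c)
    base = (Ta - t_opt) / b + g ** (1.0 / c)
    # below the curve's lower support the rate is zero, not NaN
    base = np.clip(base, 0.0, None)
    out = (a * g ** ((1.0 - c) / c) * base ** (c - 1.0)
           * np.exp(-(base ** c) + g))
    return _maybe_scalar(out, T)


def _pawar(params, T):
    r_ref, e, e_h, t_opt = params
    return r_ref * sharpe_schoolfield_factor(T, e, e_h, t_opt)


# ---------------------------------------------------------------------------
# parameter transforms (constrained optimisation support)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParamTransform:
    """Bijection between natural and internal optimiser coordinates.

    Used to turn an ordering constraint (``E_h > E``) into a box constraint:
    internally the gap is optimised as ``theta = log(E_h - E)``.
    """

    to_internal: Callable[[np.ndarray], np.ndarray]
    from_internal: Callable[[np.ndarray], np.ndarray]
    internal_bounds: tuple
    sanitize_start: Callable[[np.ndarray], np.ndarray]


def eh_log_gap_transform(e_idx: int, eh_idx: int,
                         natural_bounds: Sequence[tuple],
                         gap_bounds: tuple = (1e-3, 30.0)) -> ParamTransform:
    """Transform enforcing ``params[eh_idx] > params[e_idx]``.

    Internal coordinate ``eh_idx`` holds ``log(E_h - E)`` with the gap
    confined to ``gap_bounds``; all other coordinates pass through.
    """
    lo_gap, hi_gap = gap_bounds

    def to_internal(p):
        q = np.array(p, dtype=float)
        q[eh_idx] = np.log(p[eh_idx] - p[e_idx])
        return q

    def from_internal(q):
        p = np.array(q, dtype=float)
        p[eh_idx] = p[e_idx] + np.exp(q[eh_idx])
        return p

    lows = [b[0] for b in natural_bounds]
    highs = [b[1] for b in natural_bounds]
    lows[eh_idx] = np.log(lo_gap)
    highs[eh_idx] = np.log(hi_gap)

    def sanitize_start(p):
        p = np.array(p, dtype=float)
        if p[eh_idx] <= p[e_idx] + lo_gap:
            p[eh_idx] = p[e_idx] + max(0.1, 10 * lo_gap)
        return p

    return ParamTransform(to_internal, from_internal,
                          (np.array(lows), np.array(highs)), sanitize_start)


# ---------------------------------------------------------------------------
# model registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TPCModelSpec:
    """A named thermal-response function with fitting metadata.

    ``bounds`` are box constraints on the natural parameters, ``start_ranges``
    the per-parameter intervals from which multistart initial values are
    drawn uniformly.  ``transform`` (optional) maps to unconstrained-ordering
    internal coordinates for the optimiser.
    """

    name: str
    param_names: tuple
    bounds: tuple
    start_ranges: tuple
    func: Callable = field(repr=False)
    transform: ParamTransform | None = field(default=None, repr=False)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def __call__(self, params, T):
        params = np.asarray(params, dtype=float)
        if params.shape != (self.n_params,):
            raise ValueError(
                f"model '{self.name}' expects {self.n_params} parameters "
                f"{self.param_names}, got shape {params.shape}")
        return self.func(params, T)


_PAWAR_BOUNDS = ((1e-8, 1.0), (1e-4, 4.0), (1e-4, 34.0), (0.0, 60.0))

_REGISTRY: dict[str, TPCModelSpec] = {
    "gaussian": TPCModelSpec(
        name="gaussian",
        param_names=("r_max", "t_opt", "a"),
        bounds=((1e-8, 1.0), (0.0, 60.0), (0.5, 60.0)),
        start_ranges=((0.005, 0.2), (15.0, 35.0), (2.0, 15.0)),
        func=_gaussian,
    ),
    "modified_gaussian": TPCModelSpec(
        name="modified_gaussian",
        param_names=("r_max", "t_opt", "a", "b"),
        bounds=((1e-8, 1.0), (0.0, 60.0), (0.5, 60.0), (0.2, 10.0)),
        start_ranges=((0.005, 0.2), (15.0, 35.0), (2.0, 15.0), (1.0, 4.0)),
        func=_modified_gaussian,
    ),
    "quadratic": TPCModelSpec(
        name="quadratic",
        param_names=("a", "b", "c"),
        bounds=((-1.0, 1.0), (-0.5, 0.5), (-0.05, 0.05)),
        start_ranges=((-0.05, 0.05), (-0.01, 0.01), (-0.002, 0.002)),
        func=_quadratic,
    ),
    "weibull": TPCModelSpec(
        name="weibull",
        param_names=("a", "t_opt", "b", "c"),
        bounds=((1e-8, 1.0), (0.0, 60.0), (1.0, 150.0), (1.01, 20.0)),
        start_ranges=((0.005, 0.2), (15.0, 35.0), (5.0, 60.0), (1.2, 5.0)),
        func=_weibull,
    ),
    "pawar": TPCModelSpec(
        name="pawar",
        param_names=("r_ref", "e", "e_h", "t_opt"),
        bounds=_PAWAR_BOUNDS,
        start_ranges=((0.005, 0.2), (0.1, 1.5), (0.6, 8.0), (15.0, 35.0)),
        func=_pawar,
        transform=eh_log_gap_transform(1, 2, _PAWAR_BOUNDS),
    ),
}

MODEL_NAMES = tuple(_REGISTRY)


def model_spec(name: str) -> TPCModelSpec:
    """Look up a model family by name; raises with the valid names."""
    try:
        return _REGISTRY[name]
    except KeyError:
        raise ValueError(
            f"unknown TPC model '{name}'; valid names: "
            f"{', '.join(MODEL_NAMES)}") from None


def eval_model(name: str, params, T):
    """Evaluate a named TPC model at temperatures ``T`` (degrees C).

    Vectorised over ``T``; returns a float for scalar input.
    """
    return model_spec(name)(params, T)
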