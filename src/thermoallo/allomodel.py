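"""Combined allometric and thermal model of exploratory speed.

The headline model predicts exploratory movement speed ``v`` (m/s) from body
mass ``M`` (mg) and ambient temperature ``T`` (degrees C) by multiplying a
power-law mass scaling with the Sharpe–Schoolfield thermal factor::

    v = a0 * M**b * exp(-E/k * (1/(T+273.15) - 1/(T_ref+273.15)))
        / (1 + (E/(E_h-E)) * exp((E_h/k) * (1/(T_opt+273.15) - 1/(T+273.15))))

``a0`` is the speed of a 1 mg animal at the reference temperature
``T_ref = 15`` degrees C, ``b`` the allometric exponent, ``E`` and ``E_h``
the activation and deactivation energies (eV), and ``T_opt`` the optimum
temperature at which speed peaks.  The fit is unweighted least squares on
the natural speed scale.

``CARABID_PARAMS`` holds the parameter values estimated for Central European
ground beetles (Carabidae, masses 10–303 mg, temperatures 8–32 degrees C);
they double as the default ground truth of the synthetic-data generator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import fitting
from .tpc_models import sharpe_schoolfield_factor, eh_log_gap_transform

__all__ = [
    "AlloTPCParams",
    "CARABID_PARAMS",
    "PredictionGrid",
    "eval_allo_tpc",
    "fit_allo_tpc",
    "params_from_fit",
    "predict_grid",
    "residuals",
    "bootstrap_allo_ci",
]

ALLO_PARAM_NAMES = ("a0", "b", "e", "e_h", "t_opt")
_ALLO_BOUNDS = ((1e-8, 1.0), (-2.0, 2.0), (1e-4, 4.0), (1e-4, 34.0),
                (0.0, 60.0))
_ALLO_START_RANGES = ((1e-4, 0.5), (-0.5, 1.0), (0.05, 2.0), (0.6, 8.0),
                      (10.0, 40.0))
_ALLO_TRANSFORM = eh_log_gap_transform(2, 3, _ALLO_BOUNDS)

#: study-range envelopes beyond which predictions are extrapolations
MASS_RANGE_MG = (10.0, 303.0)
TEMP_RANGE_C = (8.0, 32.0)


@dataclass(frozen=True)
class AlloTPCParams:
    """Parameter vector of the allometric–thermal speed model.

    Attributes
    ----------
    a0 : float
        Speed (m/s) of a 1 mg animal at the reference temperature (15 C).
    b : float
        Dimensionless allometric exponent of body mass (mg).
    e : float
        Activation energy, eV (> 0): steepness of the rise below the optimum.
    e_h : float
        Deactivation energy, eV (> e): steepness of the collapse above it.
    t_opt : float
        Optimum temperature, degrees C, at which speed is maximal.
    """

    a0: float
    b: float
    e: float
    e_h: float
    t_opt: float

    def __post_init__(self):
        if not self.a0 > 0:
            raise ValueError(f"a0 must be > 0, got {self.a0}")
        if not (self.e_h > self.e > 0):
            raise ValueError(
                f"need E_h > E > 0, got E={self.e}, E_h={self.e_h}")
        if not np.isfinite(self.t_opt):
            raise ValueError("t_opt must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.a0, self.b, self.e, self.e_h, self.t_opt])


#: estimates for Central European carabid beetles (see module docstring)
CARABID_PARAMS = AlloTPCParams(a0=0.03, b=0.12, e=0.37, e_h=3.11,
                               t_opt=26.33)


def eval_allo_tpc(p: AlloTPCParams, M, T):
    """Predicted exploratory speed (m/s) at body mass ``M`` (mg), temp ``T`` (C).

    Vectorised over ``M`` and ``T`` (broadcast together).
    """
    M_arr = np.asarray(M, dtype=float)
    if np.any(M_arr <= 0):
        raise ValueError("body mass must be > 0 mg")
    out = p.a0 * M_arr ** p.b * np.asarray(
        sharpe_schoolfield_factor(T, p.e, p.e_h, p.t_opt))
    if np.ndim(M) == 0 and np.ndim(T) == 0:
        return float(out)
    return out


def _predict(params, X):
    a0, b, e, e_h, t_opt = params
    M, T = X
    return a0 * np.asarray(M, float) ** b * np.asarray(
        sharpe_schoolfield_factor(T, e, e_h, t_opt))


def _records_arrays(records: pd.DataFrame):
    needed = {"mass_mg", "temperature_C", "speed_m_s"}
    missing = needed - set(records.columns)
    if missing:
        raise ValueError(f"records table missing columns: {sorted(missing)}")
    ok = records["speed_m_s"].notna()
    sub = records.loc[ok]
    return (sub["mass_mg"].to_numpy(float),
            sub["temperature_C"].to_numpy(float),
            sub["speed_m_s"].to_numpy(float))


def fit_allo_tpc(records: pd.DataFrame, n_starts: int = 250, seed: int = 0,
                 fix_b: float | None = None) -> fitting.FitResult:
    """Fit the allometric–thermal model to an individual-records table.

    ``records`` needs columns ``mass_mg``, ``temperature_C``, ``speed_m_s``;
    rows with missing speed are dropped.  Requires variation in both mass
    (unless ``fix_b`` is given) and temperature — the model is otherwise
    unidentifiable.

    ``fix_b`` pins the allometric exponent (``fix_b=0`` reduces the model to
    a pure Sharpe–Schoolfield TPC in ``(a0, E, E_h, T_opt)``).
    """
    M, T, v = _records_arrays(records)
    n = v.size
    if n < 7:
        raise ValueError(f"need at least 7 records, got {n}")
    if fix_b is None and np.unique(M).size < 2:
        raise ValueError(
            "all body masses identical: allometric exponent b is "
            "unidentifiable (pass fix_b to pin it)")
    if np.unique(T).size < 2:
        raise ValueError(
            "all temperatures identical: thermal parameters are "
            "unidentifiable")

    if fix_b is not None:
        names = ("a0", "e", "e_h", "t_opt")
        bounds = tuple(_ALLO_BOUNDS[i] for i in (0, 2, 3, 4))
        starts = tuple(_ALLO_START_RANGES[i] for i in (0, 2, 3, 4))
        transform = eh_log_gap_transform(1, 2, bounds)

        def predict(params, X):
            a0, e, e_h, t_opt = params
            return _predict((a0, fix_b, e, e_h, t_opt), X)

        return fitting.multistart_least_squares(
            predict, (M, T), v, model_name="allo_sharpe_schoolfield",
            param_names=names, bounds=bounds, start_ranges=starts,
            n_starts=n_starts, seed=seed, transform=transform)

    return fitting.multistart_least_squares(
        _predict, (M, T), v, model_name="allo_sharpe_schoolfield",
        param_names=ALLO_PARAM_NAMES, bounds=_ALLO_BOUNDS,
        start_ranges=_ALLO_START_RANGES, n_starts=n_starts, seed=seed,
        transform=_ALLO_TRANSFORM)


def params_from_fit(fit: fitting.FitResult) -> AlloTPCParams:
    """Convert a full five-parameter fit back to an ``AlloTPCParams``."""
    if tuple(fit.param_names) != ALLO_PARAM_NAMES:
        raise ValueError(
            f"fit does not carry the allometric parameter set "
            f"{ALLO_PARAM_NAMES}: got {fit.param_names}")
    return AlloTPCParams(*map(float, fit.estimates))


@dataclass
class PredictionGrid:
    """Speed predictions on a mass x temperature grid.

    ``speeds[i, j]`` is the prediction at ``masses[i]``, ``temperatures[j]``.
    """

    masses: np.ndarray
    temperatures: np.ndarray
    speeds: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns mass_mg, temperature_C, speed_m_s."""
        mm, tt = np.meshgrid(self.masses, self.temperatures, indexing="ij")
        return pd.DataFrame({
            "mass_mg": mm.ravel(),
            "temperature_C": tt.ravel(),
            "speed_m_s": self.speeds.ravel(),
        })


def predict_grid(p: AlloTPCParams, masses, temperatures) -> PredictionGrid:
    """Evaluate the model on the outer product of masses and temperatures.

    Warns (without refusing) when the grid extends beyond the mass or
    temperature ranges the parameters were estimated for.
    """
    masses = np.atleast_1d(np.asarray(masses, dtype=float))
    temperatures = np.atleast_1d(np.asarray(temperatures, dtype=float))
    if np.any(masses <= 0):
        raise ValueError("body masses must be > 0 mg")
    if masses.min() < MASS_RANGE_MG[0] or masses.max() > MASS_RANGE_MG[1]:
        warnings.warn(
            f"predicting outside the studied mass range "
            f"{MASS_RANGE_MG} mg", UserWarning, stacklevel=2)
    if (temperatures.min() < TEMP_RANGE_C[0]
            or temperatures.max() > TEMP_RANGE_C[1]):
        warnings.warn(
            f"predicting outside the studied temperature range "
            f"{TEMP_RANGE_C} C", UserWarning, stacklevel=2)
    speeds = eval_allo_tpc(p, masses[:, None], temperatures[None, :])
    return PredictionGrid(masses=masses, temperatures=temperatures,
                          speeds=np.asarray(speeds))


def residuals(fit: fitting.FitResult, records: pd.DataFrame) -> pd.DataFrame:
    """Observed minus predicted speed, one row per fitted record.

    Grouping columns (individual id, species, habitat) are carried through
    so the table feeds directly into the residual sensitivity analysis.
    """
    M, T, v = _records_arrays(records)
    if fit.n_params == 5:
        pred = _predict(fit.estimates, (M, T))
    else:
        raise ValueError("residuals requires a full five-parameter fit")
    out = records.loc[records["speed_m_s"].notna()].copy().reset_index(
        drop=True)
    out["predicted_m_s"] = pred
    out["residual"] = v - pred
    return out


def bootstrap_allo_ci(records: pd.DataFrame, fit: fitting.FitResult,
                      B: int = 500, seed: int = 0,
                      level: float = 0.95) -> pd.DataFrame:
    """Case-resampling bootstrap percentile CIs for the allometric fit."""
    if B < 100:
        raise ValueError("bootstrap needs B >= 100 replicates")
    M, T, v = _records_arrays(records)
    return fitting._bootstrap_core(
        _predict, (M, T), v, fit, B=B, seed=seed, level=level,
        transform=_ALLO_TRANSFORM, bounds=_ALLO_BOUNDS,
        start_ranges=_ALLO_START_RANGES)
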