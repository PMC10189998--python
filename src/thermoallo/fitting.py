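"""Multistart bounded nonlinear least squares for thermal response data.

TPC model fits are notoriously sensitive to starting values: the optimiser is
therefore restarted from many random start vectors drawn uniformly from each
model's documented start ranges, and the converged solution with the lowest
residual sum of squares is kept.  Candidate models are ranked by a
Gaussian-likelihood AIC computed with the same convention R uses for ``nls``
objects, so that delta-AIC values are directly comparable with analyses done
in that ecosystem::

    AIC = n*log(2*pi) + n*log(rss/n) + n + 2*(n_params + 1)

(the ``+1`` counts the estimated error variance as a parameter).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from .tpc_models import TPCModelSpec, MODEL_NAMES, model_spec

__all__ = [
    "FitResult",
    "ModelComparison",
    "FitConvergenceError",
    "fit_multistart",
    "multistart_least_squares",
    "aic",
    "gaussian_aic",
    "compare_models",
    "wald_ci",
    "bootstrap_ci",
    "summary_table",
]

#: convergence tolerances for the trust-region optimiser
_FTOL = 1e-10
_XTOL = 1e-10
_GTOL = 1e-10


class FitConvergenceError(RuntimeError):
    """No multistart replicate converged."""


@dataclass(eq=False)
class FitResult:
    """Outcome of one model fit on one dataset.

    ``estimates``/``std_errors`` are on the natural parameter scale in the
    order of ``param_names``.  Standard errors come from the Gauss–Newton
    covariance ``sigma2 * (J'J)^-1`` with ``sigma2 = rss / (n_obs - n_params)``.
    """

    model_name: str
    param_names: tuple
    estimates: np.ndarray
    std_errors: np.ndarray
    rss: float
    n_obs: int
    n_params: int
    aic: float
    converged: bool
    n_starts_converged: int
    seed: int

    def params_dict(self) -> dict:
        return dict(zip(self.param_names, map(float, self.estimates)))


@dataclass
class ModelComparison:
    """AIC ranking of several TPC model fits on the same data.

    ``table`` has one row per requested model, sorted ascending by AIC
    (ties broken by fewer parameters, then name); ``delta_aic`` is relative
    to the best converged model.  Models that failed to fit keep a row with
    NaN AIC and the error message.
    """

    table: pd.DataFrame
    fits: dict = field(repr=False, default_factory=dict)

    @property
    def best_name(self) -> str:
        return str(self.table.iloc[0]["model"])


def gaussian_aic(rss: float, n_obs: int, n_params: int) -> float:
    """Gaussian-likelihood AIC (R ``nls`` convention, see module docstring)."""
    if rss <= 0.0:
        raise ValueError(
            "AIC undefined for a perfect fit (rss must be > 0)")
    n = n_obs
    return n * np.log(2.0 * np.pi) + n * np.log(rss / n) + n \
        + 2.0 * (n_params + 1)


def aic(fit: FitResult) -> float:
    """Recompute the AIC of a fit; raises on a degenerate perfect fit."""
    return gaussian_aic(fit.rss, fit.n_obs, fit.n_params)


def _take(X, idx):
    if isinstance(X, tuple):
        return tuple(np.asarray(a)[idx] for a in X)
    return np.asarray(X)[idx]


def _numeric_jacobian(predict, params: np.ndarray, X) -> np.ndarray:
    """Central-difference Jacobian of ``predict`` w.r.t. natural parameters."""
    params = np.asarray(params, dtype=float)
    y0 = np.asarray(predict(params, X), dtype=float)
    n, p = y0.size, params.size
    J = np.empty((n, p))
    rel = np.finfo(float).eps ** (1.0 / 3.0)
    for j in range(p):
        h = rel * max(abs(params[j]), 1.0)
        up = params.copy()
        dn = params.copy()
        up[j] += h
        dn[j] -= h
        try:
            J[:, j] = (np.asarray(predict(up, X)) -
                       np.asarray(predict(dn, X))) / (2.0 * h)
        except ValueError:
            # constraint violated by the perturbation: fall back one-sided
            J[:, j] = (y0 - np.asarray(predict(dn, X))) / h
    return J


def multistart_least_squares(predict: Callable, X, y, *,
                             model_name: str,
                             param_names: Sequence[str],
                             bounds: Sequence[tuple],
                             start_ranges: Sequence[tuple],
                             n_starts: int = 250,
                             seed: int = 0,
                             transform=None,
                             x0: np.ndarray | None = None) -> FitResult:
    """Core multistart engine shared by the TPC and allometric fits.

    Parameters
    ----------
    predict : callable
        ``predict(params, X) -> yhat`` on the natural parameter scale.
    X : array or tuple of arrays
        Covariates (temperature, or ``(mass, temperature)``).
    y : array
        Response (speed, m/s).
    x0 : array, optional
        If given, fit from this single start instead of sampling
        (used by the bootstrap).
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    p = len(param_names)
    if n < p + 2:
        raise ValueError(
            f"need at least {p + 2} observations to fit '{model_name}' "
            f"({p} parameters), got {n}")

    if transform is None:
        lows = np.array([b[0] for b in bounds], dtype=float)
        highs = np.array([b[1] for b in bounds], dtype=float)
        to_internal = from_internal = lambda q: np.asarray(q, dtype=float)
        sanitize = lambda q: q
        internal_bounds = (lows, highs)
    else:
        to_internal = transform.to_internal
        from_internal = transform.from_internal
        sanitize = transform.sanitize_start
        internal_bounds = transform.internal_bounds

    def residuals(q):
        return np.asarray(predict(from_internal(q), X), dtype=float) - y

    if x0 is not None:
        starts = np.asarray(x0, dtype=float)[None, :]
    else:
        rng = np.random.default_rng(seed)
        lo = [r[0] for r in start_ranges]
        hi = [r[1] for r in start_ranges]
        starts = rng.uniform(lo, hi, size=(n_starts, p))

    ilo, ihi = internal_bounds
    eps = 1e-12
    best = None
    n_conv = 0
    for s in starts:
        q0 = to_internal(sanitize(np.asarray(s, dtype=float)))
        q0 = np.clip(q0, ilo + eps, ihi - eps)
        try:
            res = least_squares(residuals, q0, bounds=internal_bounds,
                                method="trf", ftol=_FTOL, xtol=_XTOL,
                                gtol=_GTOL)
        except (ValueError, FloatingPointError):
            continue
        if res.status <= 0 or not np.all(np.isfinite(res.x)):
            continue
        n_conv += 1
        if best is None or res.cost < best.cost:
            best = res

    if best is None:
        raise FitConvergenceError(
            f"no start converged for model '{model_name}'; widen bounds or "
            f"increase n_starts (tried {len(starts)})")

    estimates = from_internal(best.x)
    resid = np.asarray(predict(estimates, X), dtype=float) - y
    rss = float(resid @ resid)

    dof = n - p
    sigma2 = rss / dof
    J = _numeric_jacobian(predict, estimates, X)
    cov = sigma2 * np.linalg.pinv(J.T @ J)
    std_errors = np.sqrt(np.clip(np.diag(cov), 0.0, None))

    aic_value = gaussian_aic(rss, n, p) if rss > 0.0 else float("nan")
    return FitResult(
        model_name=model_name,
        param_names=tuple(param_names),
        estimates=np.asarray(estimates, dtype=float),
        std_errors=std_errors,
        rss=rss,
        n_obs=n,
        n_params=p,
        aic=aic_value,
        converged=True,
        n_starts_converged=n_conv,
        seed=int(seed),
    )


def fit_multistart(spec: TPCModelSpec | str, T, v, n_starts: int = 250,
                   seed: int = 0) -> FitResult:
    """Fit one TPC model to (temperature, speed) data by multistart NLS."""
    if isinstance(spec, str):
        spec = model_spec(spec)
    T = np.asarray(T, dtype=float)
    v = np.asarray(v, dtype=float)
    if T.shape != v.shape:
        raise ValueError("T and v must have the same length")
    return multistart_least_squares(
        lambda params, X: spec.func(params, X), T, v,
        model_name=spec.name,
        param_names=spec.param_names,
        bounds=spec.bounds,
        start_ranges=spec.start_ranges,
        n_starts=n_starts,
        seed=seed,
        transform=spec.transform,
    )


def compare_models(T, v, names: Sequence[str] = MODEL_NAMES,
                   n_starts: int = 250, seed: int = 0) -> ModelComparison:
    """Fit several TPC families to the same data and rank them by AIC.

    Each model is fitted independently (same seed, its own start ranges);
    failures are recorded per row rather than aborting the comparison.
    """
    rows = []
    fits: dict[str, FitResult] = {}
    for name in names:
        spec = model_spec(name)
        try:
            fit = fit_multistart(spec, T, v, n_starts=n_starts, seed=seed)
        except (FitConvergenceError, ValueError) as exc:
            rows.append(dict(model=name, aic=np.nan,
                             n_params=spec.n_params, converged=False,
                             error=str(exc)))
            continue
        fits[name] = fit
        rows.append(dict(model=name, aic=fit.aic, n_params=fit.n_params,
                         converged=True, error=""))
    table = pd.DataFrame(rows)
    ok = table["converged"]
    # ties broken by parsimony, then name
    table = pd.concat([
        table[ok].sort_values(["aic", "n_params", "model"]),
        table[~ok],
    ], ignore_index=True)
    if ok.any():
        best = table["aic"].iloc[0]
        table["delta_aic"] = table["aic"] - best
    else:
        table["delta_aic"] = np.nan
    table = table[["model", "aic", "delta_aic", "n_params",
                   "converged", "error"]]
    return ModelComparison(table=table, fits=fits)


def wald_ci(fit: FitResult, level: float = 0.95) -> pd.DataFrame:
    """Normal-approximation confidence intervals: estimate +- z * SE."""
    if not 0.0 <= level < 1.0:
        raise ValueError("level must be in [0, 1)")
    z = stats.norm.ppf(0.5 + level / 2.0)
    est = fit.estimates
    se = fit.std_errors
    lo = np.where(np.isfinite(se), est - z * se, np.nan)
    hi = np.where(np.isfinite(se), est + z * se, np.nan)
    return pd.DataFrame({
        "parameter": list(fit.param_names),
        "estimate": est,
        "ci_low": lo,
        "ci_high": hi,
    })


def summary_table(fit: FitResult, level: float = 0.95) -> pd.DataFrame:
    """Per-parameter report: estimate, SE, Wald CI and two-sided t p-value.

    The t statistics use ``n_obs - n_params`` degrees of freedom.
    """
    df = fit.n_obs - fit.n_params
    with np.errstate(divide="ignore", invalid="ignore"):
        t = fit.estimates / fit.std_errors
    p = 2.0 * stats.t.sf(np.abs(t), df)
    out = wald_ci(fit, level=level)
    out["std_error"] = fit.std_errors
    out["t_stat"] = t
    out["p_value"] = p
    return out[["parameter", "estimate", "std_error", "ci_low", "ci_high",
                "t_stat", "p_value"]]


def bootstrap_ci(spec: TPCModelSpec | str, T, v, fit: FitResult,
                 B: int = 500, seed: int = 0,
                 level: float = 0.95) -> pd.DataFrame:
    """Case-resampling bootstrap percentile intervals for a TPC fit.

    Each replicate resamples (T, v) pairs with replacement and refits the
    model from the original estimates as the single start.  If more than 20%
    of replicates fail to converge a warning is attached; the intervals are
    then computed from the converged replicates only.
    """
    if isinstance(spec, str):
        spec = model_spec(spec)
    if B < 100:
        raise ValueError("bootstrap needs B >= 100 replicates")
    return _bootstrap_core(
        lambda params, X: spec.func(params, X), np.asarray(T, float),
        np.asarray(v, float), fit, B=B, seed=seed, level=level,
        transform=spec.transform, bounds=spec.bounds,
        start_ranges=spec.start_ranges)


def _bootstrap_core(predict, X, y, fit: FitResult, *, B, seed, level,
                    transform, bounds, start_ranges) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    n = np.asarray(y).size
    draws = np.full((B, fit.n_params), np.nan)
    n_fail = 0
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            rep = multistart_least_squares(
                predict, _take(X, idx), np.asarray(y)[idx],
                model_name=fit.model_name, param_names=fit.param_names,
                bounds=bounds, start_ranges=start_ranges,
                transform=transform, x0=fit.estimates)
        except (FitConvergenceError, ValueError):
            n_fail += 1
            continue
        draws[b] = rep.estimates
    if n_fail > 0.2 * B:
        warnings.warn(
            f"bootstrap: {n_fail}/{B} replicates failed to converge; "
            "intervals use converged replicates only", RuntimeWarning)
    alpha = (1.0 - level) / 2.0
    lo = np.nanpercentile(draws, 100 * alpha, axis=0)
    hi = np.nanpercentile(draws, 100 * (1 - alpha), axis=0)
    out = pd.DataFrame({
        "parameter": list(fit.param_names),
        "estimate": fit.estimates,
        "ci_low": lo,
        "ci_high": hi,
    })
    out.attrs["n_failed"] = n_fail
    out.attrs["B"] = B
    return out
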