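"""Sensitivity analysis of the allometric–thermal model residuals.

After fitting the mass-and-temperature model, any structure left in the
residuals by species identity or habitat preference would indicate
group-specific responses the general model misses.  The test fits a
zero-intercept linear model ``residual ~ 0 + group`` so that each
coefficient is literally a group's mean residual, tested against zero with
a pooled-variance two-sided t-test.  No multiplicity adjustment is applied
to the reported p-values; a Bonferroni column is included for transparency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["ResidualGroupTest", "group_residual_test", "any_significant"]


@dataclass(frozen=True)
class ResidualGroupTest:
    """One group's deviation of mean residual from zero."""

    grouping: str
    group: str
    n: int
    mean_residual: float
    std_error: float
    t_stat: float
    p_value: float


def group_residual_test(residual_table: pd.DataFrame,
                        grouping_column: str = "species",
                        treatment_coding: bool = False) -> pd.DataFrame:
    """Test whether group-wise mean residuals deviate from zero.

    Parameters
    ----------
    residual_table : DataFrame
        Must contain a ``residual`` column and ``grouping_column``.
    grouping_column : str
        Typically ``"species"`` or ``"habitat_group"``.
    treatment_coding : bool
        If True, fit an intercept plus treatment contrasts instead; the
        coefficients are then differences from the (alphabetically first)
        reference group, not group means.

    Returns
    -------
    DataFrame
        Columns ``grouping, group, n, mean_residual, std_error, t_stat,
        p_value, p_bonferroni``, one row per group.  Groups with a single
        observation get NaN SE/t/p and trigger a warning.
    """
    if len(residual_table) == 0:
        raise ValueError("empty residual table")
    if "residual" not in residual_table.columns:
        raise ValueError("residual table must contain a 'residual' column")
    if grouping_column not in residual_table.columns:
        raise ValueError(f"no such grouping column: '{grouping_column}'")

    tab = residual_table[[grouping_column, "residual"]].dropna()
    y = tab["residual"].to_numpy(float)
    groups = tab[grouping_column].astype(str)
    counts = groups.value_counts()
    n_groups = counts.size
    if len(tab) - n_groups < 1:
        raise ValueError(
            "not enough observations to estimate the residual variance "
            "(need more rows than groups)")

    dummies = pd.get_dummies(groups, dtype=float)
    dummies = dummies[sorted(dummies.columns)]
    if treatment_coding:
        X = sm.add_constant(dummies.iloc[:, 1:])
    else:
        X = dummies
    res = sm.OLS(y, X).fit()

    rows = []
    singletons = []
    for name in X.columns:
        if treatment_coding and name == "const":
            label = dummies.columns[0]
        else:
            label = name
        n_g = int(counts.get(label, 0)) if not treatment_coding else \
            int(counts.get(label, 0))
        se, t, p = res.bse[name], res.tvalues[name], res.pvalues[name]
        if not treatment_coding and n_g == 1:
            singletons.append(label)
            se = t = p = np.nan
        rows.append(dict(grouping=grouping_column, group=str(name),
                         n=n_g, mean_residual=float(res.params[name]),
                         std_error=float(se) if np.isfinite(se) else np.nan,
                         t_stat=float(t) if np.isfinite(t) else np.nan,
                         p_value=float(p) if np.isfinite(p) else np.nan))
    if singletons:
        warnings.warn(
            f"groups with a single observation reported without SE/p: "
            f"{singletons}", RuntimeWarning)
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = np.minimum(out["p_value"] * len(out), 1.0)
    return out


def any_significant(test_table: pd.DataFrame, alpha: float = 0.05) -> bool:
    """True if any group's unadjusted p-value falls below ``alpha``."""
    p = test_table["p_value"].to_numpy(float)
    return bool(np.any(p[np.isfinite(p)] < alpha))
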