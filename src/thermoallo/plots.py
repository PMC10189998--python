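"""Quick-look figures for fitted thermal responses and prediction surfaces."""

from __future__ import annotations

import numpy as np

from . import fitting
from .allomodel import AlloTPCParams, predict_grid
from .tpc_models import model_spec

__all__ = ["plot_tpc_comparison", "plot_prediction_curves"]


def plot_tpc_comparison(T, v, comparison: fitting.ModelComparison, ax=None):
    """Scatter the data and overlay every fitted TPC family.

    The best-ranked model is drawn emphasised; the others in light gray.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    T = np.asarray(T, float)
    grid = np.linspace(T.min(), T.max(), 300)
    ax.scatter(T, v, s=12, color="0.4", alpha=0.6, label="data")
    best = comparison.best_name
    for name, fit in comparison.fits.items():
        curve = model_spec(name)(fit.estimates, grid)
        if name == best:
            ax.plot(grid, curve, color="tab:blue", lw=2.0,
                    label=f"{name} (best)")
        else:
            ax.plot(grid, curve, color="0.7", lw=1.0, label=name)
    ax.set_xlabel("temperature [°C]")
    ax.set_ylabel("exploratory speed [m/s]")
    ax.legend(fontsize="small")
    return ax


def plot_prediction_curves(p: AlloTPCParams, masses=(10.0, 105.0, 303.0),
                           temperatures=None, ax=None):
    """Predicted speed against temperature, one curve per body mass."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    if temperatures is None:
        temperatures = np.linspace(8.0, 32.0, 200)
    grid = predict_grid(p, masses, temperatures)
    for i, m in enumerate(grid.masses):
        ax.plot(grid.temperatures, grid.speeds[i], label=f"{m:g} mg")
    ax.set_xlabel("temperature [°C]")
    ax.set_ylabel("predicted speed [m/s]")
    ax.legend(title="body mass")
    return ax
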