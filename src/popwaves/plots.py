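"""Figures: SPD with breakpoint, R_t series with waves, phase portraits."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .changepoint import BreakpointFit
from .growth import GrowthSeries, Wave
from .spd import SPDSeries

__all__ = ["plot_spd_with_breakpoint", "plot_growth_waves", "plot_phase_portrait"]


def plot_spd_with_breakpoint(spd: SPDSeries, fit: BreakpointFit = None, ax=None):
    """Annual SPD against cal BP (time flowing left), breakpoint dashed."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    ax.plot(spd.cal_bp, spd.value, lw=0.8, color="0.2")
    if fit is not None:
        ax.axvline(fit.break_cal_bp, color="crimson", ls=":", label=f"break {fit.break_cal_bp:.0f} cal BP")
        ax.legend(frameon=False)
    ax.set_xlabel("cal BP")
    ax.set_ylabel("summed density")
    ax.invert_xaxis()
    return ax


def plot_growth_waves(growth: GrowthSeries, waves: list[Wave], ax=None):
    """Generational R_t with shaded maximal growth runs."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    t = growth.t[:-1]
    ax.axhline(0.0, color="0.7", lw=0.8)
    ax.plot(t, growth.R, marker="o", ms=2.5, lw=0.8, color="0.2")
    for w in waves:
        lo, hi = w.span()
        ax.axvspan(lo, hi, color="orange", alpha=0.3)
    ax.set_xlabel("cal BP")
    ax.set_ylabel(r"$R_t$")
    ax.invert_xaxis()
    return ax


def plot_phase_portrait(points: np.ndarray, fit=None, ax=None):
    """(X, R) path in temporal order, optionally with a fitted R(X) curve."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ax.plot(points[:, 0], points[:, 1], marker="o", ms=3, lw=0.8, color="0.2")
    if fit is not None:
        xs = np.linspace(points[:, 0].min() - 0.2, points[:, 0].max() + 0.2, 200)
        p = fit.params
        ax.plot(xs, p.rm - p.c * np.exp(xs) - p.w * np.exp(-xs), color="crimson", lw=1.2)
    ax.axhline(0.0, color="0.7", lw=0.8)
    ax.set_xlabel(r"$X_t = \ln$ SPD")
    ax.set_ylabel(r"$R_t$")
    return ax
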