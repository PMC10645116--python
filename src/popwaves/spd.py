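"""Summed probability distributions (SPDs) and generational aggregation.

The SPD — the pointwise sum of many dates' calibrated densities — is the
standard relative population proxy in paleodemography.  The workflow here
mirrors the common practice for demographic reconstruction: sum
unnormalized per-date densities on an annual grid, smooth with a rolling
mean (default 200 years) to suppress calibration-curve artifacts, trim
the near-empty edges, then aggregate to generational (30-year) bins whose
sums feed the growth-rate analysis.

All annual series are stored ascending in cal BP; "forward in time" means
decreasing cal BP.  Generational series are stored forward in time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .radiocarbon import (
    CalibrationCurve,
    RadiocarbonDate,
    calibrate_date,
    gaussian_ordinates,
)

__all__ = [
    "SPDSeries",
    "GenerationalSeries",
    "build_spd",
    "rolling_smooth",
    "trim_edges",
    "to_generations",
]


@dataclass(frozen=True)
class SPDSeries:
    """Annual summed density on a contiguous integer cal BP grid (ascending)."""

    cal_bp: np.ndarray
    value: np.ndarray
    n_dates: int
    smoothing_window: int = 0  # 0 = raw
    normalized: bool = False
    trim_bounds: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "cal_bp", np.asarray(self.cal_bp, dtype=int))
        object.__setattr__(self, "value", np.asarray(self.value, dtype=float))
        if self.cal_bp.size != self.value.size:
            raise ValueError("grid/value length mismatch")
        if self.cal_bp.size and np.any(np.diff(self.cal_bp) != 1):
            raise ValueError("cal_bp grid must be consecutive integer years ascending")
        if np.any(self.value < 0):
            raise ValueError("SPD values must be non-negative")

    def __len__(self) -> int:
        return self.value.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cal_bp": self.cal_bp, "value": self.value})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class GenerationalSeries:
    """Generational sums of annual SPD values, ordered forward in time.

    ``bin_start_cal_bp[i]`` is the first (oldest) year of bin *i*; the bin
    covers ``bin_start_cal_bp[i]`` down to ``bin_start_cal_bp[i] -
    bin_width + 1``.  Only full-width bins are kept.
    """

    bin_start_cal_bp: np.ndarray
    value: np.ndarray
    bin_width: int = 30

    def __post_init__(self) -> None:
        object.__setattr__(self, "bin_start_cal_bp", np.asarray(self.bin_start_cal_bp, dtype=int))
        object.__setattr__(self, "value", np.asarray(self.value, dtype=float))
        if self.bin_start_cal_bp.size != self.value.size:
            raise ValueError("grid/value length mismatch")
        if self.bin_start_cal_bp.size > 1 and np.any(np.diff(self.bin_start_cal_bp) != -self.bin_width):
            raise ValueError("bins must be consecutive and ordered forward in time (decreasing cal BP)")
        if np.any(self.value < 0):
            raise ValueError("generational values must be non-negative")

    def __len__(self) -> int:
        return self.value.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_start_cal_bp": self.bin_start_cal_bp, "value": self.value})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


CurveRegistry = Union[CalibrationCurve, Mapping[str, CalibrationCurve]]


def _resolve_curve(curves: CurveRegistry, curve_id: str) -> CalibrationCurve:
    if isinstance(curves, CalibrationCurve):
        return curves
    try:
        return curves[curve_id]
    except KeyError:
        raise KeyError(f"no calibration curve registered under id {curve_id!r}") from None


def build_spd(
    dates: Sequence[RadiocarbonDate],
    curves: CurveRegistry,
    window: tuple[float, float] = (0, 15000),
    normalize: bool = False,
) -> SPDSeries:
    """Sum calibrated densities of all dates over an annual window.

    ``normalize`` selects whether each per-date density is rescaled to
    unit mass before summation (False = the unnormalized dialect).
    Implementation sums Gaussian ordinates curve-by-curve with the same
    kernel :func:`calibrate_date` uses, so the result is identical to
    looping ``calibrate_date`` and adding densities.
    """
    if len(dates) == 0:
        raise ValueError("build_spd requires at least one date")
    lo, hi = int(min(window)), int(max(window))
    grid = np.arange(lo, hi + 1)
    total = np.zeros(grid.size)

    by_curve: dict[str, list[RadiocarbonDate]] = {}
    for d in dates:
        by_curve.setdefault(d.curve_id, []).append(d)

    for curve_id, group in by_curve.items():
        curve = _resolve_curve(curves, curve_id)
        c_lo, c_hi = curve.cal_support
        if lo < c_lo or hi > c_hi:
            raise ValueError(
                f"window ({lo}, {hi}) outside curve {curve.name!r} support ({c_lo}, {c_hi})"
            )
        mu = curve.c14_at(grid)
        sig = curve.sigma_at(grid)
        a_lo, a_hi = curve.c14_support
        for d in group:
            if not (a_lo <= d.c14_age <= a_hi):
                raise ValueError(
                    f"date {d.lab_id!r}: ¹⁴C age outside curve {curve.name!r} range"
                )
            dens = gaussian_ordinates(d.c14_age, d.c14_error, mu, sig)
            if normalize:
                s = dens.sum()
                if s > 0:
                    dens = dens / s
            total += dens

    return SPDSeries(grid, total, n_dates=len(dates), normalized=normalize)


def rolling_smooth(spd: SPDSeries, window: int = 200) -> SPDSeries:
    """Centered rolling mean; edge years without a full window are dropped.

    For an even window the mean is centered with the extra half-step
    toward the past (the assigned year is ``window // 2`` grid steps from
    the young edge of each full window).
    """
    n = len(spd)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > n:
        raise ValueError(f"smoothing window {window} exceeds series length {n}")
    if window == 1:
        return spd
    kernel = np.full(window, 1.0 / window)
    sm = np.convolve(spd.value, kernel, mode="valid")
    sm = np.maximum(sm, 0.0)  # guard tiny negative round-off
    offset = window // 2
    grid = spd.cal_bp[offset : offset + sm.size]
    return SPDSeries(
        grid,
        sm,
        n_dates=spd.n_dates,
        smoothing_window=window,
        normalized=spd.normalized,
        trim_bounds=spd.trim_bounds,
    )


def trim_edges(spd: SPDSeries, policy="auto", eps: float = 1e-6) -> SPDSeries:
    """Drop leading/trailing low-density edge years.

    ``policy`` is either an explicit ``(young, old)`` cal BP pair, or
    ``"auto"``: drop leading and trailing years whose value is below
    ``eps`` times the series maximum (misleading near-zeros where there
    are no data).
    """
    if isinstance(policy, str):
        if policy != "auto":
            raise ValueError(f"unknown trim policy {policy!r}")
        floor = eps * spd.value.max() if spd.value.size else 0.0
        keep = np.nonzero(spd.value > floor)[0]
        if keep.size == 0:
            raise ValueError("auto trim removed the entire series")
        i0, i1 = int(keep[0]), int(keep[-1])
    else:
        lo, hi = int(min(policy)), int(max(policy))
        i0 = int(np.searchsorted(spd.cal_bp, lo, side="left"))
        i1 = int(np.searchsorted(spd.cal_bp, hi, side="right")) - 1
        if i0 > i1 or i0 >= len(spd):
            raise ValueError("explicit trim bounds leave an empty series")
    sub = spd.value[i0 : i1 + 1]
    grid = spd.cal_bp[i0 : i1 + 1]
    return SPDSeries(
        grid,
        sub,
        n_dates=spd.n_dates,
        smoothing_window=spd.smoothing_window,
        normalized=spd.normalized,
        trim_bounds=(int(grid[0]), int(grid[-1])),
    )


def to_generations(
    spd: SPDSeries, width: int = 30, anchor: Optional[int] = None
) -> GenerationalSeries:
    """Sum annual values into consecutive ``width``-year generational bins.

    Bins start at ``anchor`` (default: the oldest year of the series) and
    proceed toward the present; a trailing partial bin is dropped rather
    than zero-padded (padding would fabricate a population crash).
    """
    if width < 1:
        raise ValueError("bin width must be >= 1")
    if anchor is None:
        anchor = int(spd.cal_bp[-1])
    if not (spd.cal_bp[0] <= anchor <= spd.cal_bp[-1]):
        raise ValueError(f"anchor {anchor} outside series span")
    ia = int(anchor - spd.cal_bp[0])
    forward = spd.value[: ia + 1][::-1]  # from anchor toward the present
    n_bins = forward.size // width
    if n_bins < 2:
        raise ValueError("fewer than 2 full generational bins — growth rates need >= 2")
    sums = forward[: n_bins * width].reshape(n_bins, width).sum(axis=1)
    starts = anchor - width * np.arange(n_bins)
    return GenerationalSeries(starts, sums, bin_width=width)
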