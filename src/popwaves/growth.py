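"""Generational log reproductive rates, growth waves and phase portraits.

With X_t = log_e of the generational abundance proxy, the reproductive
rate per generation is R_t = X_{t+1} − X_t.  A "wave" is a maximal run of
consecutive generations with uninterrupted positive growth (R above a
tolerance, 0 by default); the phase portrait is the time-ordered (X_t,
R_t) path, the standard diagnostic for density dependence: a humped
portrait signals cooperation (Allee-type positive feedback) at low
abundance and competition at high abundance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .spd import GenerationalSeries

__all__ = [
    "GrowthSeries",
    "Wave",
    "WaveDurationStats",
    "reproductive_rates",
    "segment_waves",
    "wave_duration_stats",
    "phase_portrait",
]


@dataclass(frozen=True)
class GrowthSeries:
    """Log abundance X_t and first differences R_t, forward in time."""

    t: np.ndarray  # cal BP of each generational bin start
    X: np.ndarray
    R: np.ndarray
    floored: np.ndarray  # bins whose value fell below the log floor
    bin_width: int = 30

    def __post_init__(self) -> None:
        object.__setattr__(self, "t", np.asarray(self.t))
        object.__setattr__(self, "X", np.asarray(self.X, dtype=float))
        object.__setattr__(self, "R", np.asarray(self.R, dtype=float))
        object.__setattr__(self, "floored", np.asarray(self.floored, dtype=bool))
        if self.R.size != self.X.size - 1:
            raise ValueError("len(R) must equal len(X) - 1")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X must be finite everywhere (apply a floor upstream)")

    def __len__(self) -> int:
        return self.X.size


@dataclass(frozen=True)
class Wave:
    """A maximal run of uninterrupted growth.

    Indices refer to R-steps: the run covers R[start_index .. end_index]
    inclusive; ``points`` are the (X_t, R_t) pairs of those steps;
    duration = number of steps × generation width in years.
    """

    start_index: int
    end_index: int
    duration: float
    points: np.ndarray  # shape (n_steps, 2): columns X, R
    t_start: float  # cal BP of the oldest generation in the run
    t_end: float  # cal BP of the bin closing the run (youngest)
    fittable: bool
    contains_floored: bool = False

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def span(self) -> tuple[float, float]:
        """(young, old) cal BP interval covered by the run."""
        lo, hi = sorted((float(self.t_end), float(self.t_start)))
        return lo, hi


def reproductive_rates(series: GenerationalSeries, floor: float = 1e-12) -> GrowthSeries:
    """X = ln(max(value, floor)); R by forward first difference.

    Bins below ``floor`` are flagged; an all-floored series is an error
    (the log of a truly empty series carries no demographic signal).
    """
    if len(series) < 2:
        raise ValueError("need >= 2 generational bins")
    v = series.value
    floored = v < floor
    if floored.all():
        raise ValueError("all generational bins below the log floor")
    X = np.log(np.maximum(v, floor))
    R = np.diff(X)
    return GrowthSeries(series.bin_start_cal_bp, X, R, floored, bin_width=series.bin_width)


def segment_waves(
    growth: GrowthSeries, min_points: int = 4, tolerance: float = 0.0
) -> list[Wave]:
    """Maximal runs of R > tolerance, in temporal order.

    Runs with fewer than ``min_points`` (X, R) pairs are returned but
    flagged unfittable (the 3-parameter growth model needs >= 4 points);
    runs touching a floored bin are likewise flagged, since their log
    values are artifacts of the floor.
    """
    if len(growth) == 0:
        raise ValueError("empty growth series")
    pos = growth.R > tolerance
    waves: list[Wave] = []
    i = 0
    n = growth.R.size
    while i < n:
        if not pos[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and pos[j + 1]:
            j += 1
        n_steps = j - i + 1
        touches_floor = bool(growth.floored[i : j + 2].any())
        points = np.column_stack((growth.X[i : j + 1], growth.R[i : j + 1]))
        waves.append(
            Wave(
                start_index=i,
                end_index=j,
                duration=float(n_steps * growth.bin_width),
                points=points,
                t_start=float(growth.t[i]),
                t_end=float(growth.t[j + 1]),
                fittable=(n_steps >= min_points) and not touches_floor,
                contains_floored=touches_floor,
            )
        )
        i = j + 1
    return waves


@dataclass(frozen=True)
class WaveDurationStats:
    mean_years: float
    count: int
    hist_counts: np.ndarray
    hist_edges: np.ndarray


def wave_duration_stats(waves: Sequence[Wave], bin_width: float = 100.0) -> WaveDurationStats:
    """Arithmetic mean of wave durations plus a fixed-width histogram."""
    if len(waves) == 0:
        raise ValueError("no waves to summarize")
    durations = np.array([w.duration for w in waves], dtype=float)
    top = bin_width * np.ceil(durations.max() / bin_width + 1e-12)
    edges = np.arange(0.0, max(top, bin_width) + bin_width / 2, bin_width)
    counts, edges = np.histogram(durations, bins=edges)
    return WaveDurationStats(
        mean_years=float(durations.mean()),
        count=len(waves),
        hist_counts=counts,
        hist_edges=edges,
    )


def phase_portrait(growth: GrowthSeries) -> np.ndarray:
    """Time-ordered (X_t, R_t) pairs, one per generational step."""
    if len(growth) == 0:
        raise ValueError("empty growth series")
    return np.column_stack((growth.X[:-1].copy(), growth.R.copy()))
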