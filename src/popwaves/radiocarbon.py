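"""Radiocarbon calibration: curves, dates, and calendar-age densities.

A conventional radiocarbon determination (a ¹⁴C age BP with a 1σ lab
error) is mapped onto the calendar axis through a calibration curve — an
empirical table of expected ¹⁴C age (with its own 1σ uncertainty) per
calendar year BP (0 cal BP = AD 1950, values increase into the past).
The calibrated density at calendar year θ is the Gaussian ordinate of the
measured age at mean μ(θ) = curve ¹⁴C age and variance σ_lab² + σ_curve(θ)²,
evaluated on a 1-year grid.

Densities may be left as raw ordinates ("unnormalized" mode, the dialect
used for summed probability distributions that avoids spikes where the
curve is steep) or rescaled to unit mass per date.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "CalibrationError",
    "CurveParseError",
    "RadiocarbonDate",
    "CalibrationCurve",
    "CalibratedDensity",
    "read_calcurve",
    "read_dates",
    "write_dates",
    "calibrate_date",
]

_SQRT2PI = np.sqrt(2.0 * np.pi)


class CalibrationError(ValueError):
    """A date or window is incompatible with its calibration curve."""


class CurveParseError(ValueError):
    """A calibration-curve file could not be parsed."""


@dataclass(frozen=True)
class RadiocarbonDate:
    """One laboratory measurement: conventional ¹⁴C age BP ± 1σ."""

    lab_id: str
    c14_age: float
    c14_error: float
    curve_id: str
    region: Optional[str] = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.c14_age):
            raise ValueError(f"{self.lab_id}: c14_age must be finite")
        if not (self.c14_error > 0):
            raise ValueError(f"{self.lab_id}: c14_error must be > 0")


@dataclass(frozen=True)
class CalibrationCurve:
    """Calendar ↔ ¹⁴C mapping with per-knot 1σ uncertainty.

    ``cal_bp`` is strictly increasing; between knots the curve is defined
    by linear interpolation (of both the ¹⁴C age and its 1σ error).
    """

    cal_bp: np.ndarray
    c14_age: np.ndarray
    sigma: np.ndarray
    name: str = "curve"

    def __post_init__(self) -> None:
        for attr in ("cal_bp", "c14_age", "sigma"):
            object.__setattr__(self, attr, np.asarray(getattr(self, attr), dtype=float))
        n = self.cal_bp.size
        if n < 2 or self.c14_age.size != n or self.sigma.size != n:
            raise ValueError("curve grids must have equal length >= 2")
        if np.any(np.diff(self.cal_bp) <= 0):
            raise ValueError(f"curve {self.name!r}: cal_bp grid not strictly increasing")
        if not np.all(self.sigma > 0):
            raise ValueError(f"curve {self.name!r}: curve sigma must be > 0 everywhere")

    # -- interpolation contract: linear between knots ---------------------
    def c14_at(self, cal_bp) -> np.ndarray:
        return np.interp(cal_bp, self.cal_bp, self.c14_age)

    def sigma_at(self, cal_bp) -> np.ndarray:
        return np.interp(cal_bp, self.cal_bp, self.sigma)

    @property
    def cal_support(self) -> tuple[float, float]:
        return float(self.cal_bp[0]), float(self.cal_bp[-1])

    @property
    def c14_support(self) -> tuple[float, float]:
        return float(self.c14_age.min()), float(self.c14_age.max())


@dataclass(frozen=True)
class CalibratedDensity:
    """Calendar-year probability density of one date at 1-yr resolution."""

    cal_bp: np.ndarray
    density: np.ndarray
    normalized: bool

    def __post_init__(self) -> None:
        object.__setattr__(self, "cal_bp", np.asarray(self.cal_bp))
        object.__setattr__(self, "density", np.asarray(self.density, dtype=float))
        if self.cal_bp.size != self.density.size:
            raise ValueError("grid and density length mismatch")
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")


def read_calcurve(path, name: Optional[str] = None) -> CalibrationCurve:
    """Read an IntCal-style delimited curve file.

    Dialect: tab- or comma-delimited text, >= 3 numeric columns per data
    row (cal BP, ¹⁴C age BP, 1σ error); lines starting with '#' or whose
    first token is non-numeric are headers and skipped; extra columns are
    ignored. Rows are sorted ascending by cal BP; duplicate calendar knots
    are a validation error.
    """
    path = Path(path)
    if name is None:
        name = path.stem
    rows: list[tuple[float, float, float]] = []
    with open(path, "r", newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p for p in line.replace(",", " ").split() if p]
            try:
                first = float(parts[0])
            except ValueError:
                continue  # non-numeric leading token: header line
            if len(parts) < 3:
                raise CurveParseError(f"{path}:{lineno}: expected >= 3 columns, got {len(parts)}")
            try:
                cal, age, sig = float(parts[0]), float(parts[1]), float(parts[2])
            except ValueError as exc:
                raise CurveParseError(f"{path}:{lineno}: malformed numeric row: {line!r}") from exc
            rows.append((cal, age, sig))
    if len(rows) < 2:
        raise CurveParseError(f"{path}: fewer than 2 data rows")
    arr = np.array(rows, dtype=float)
    order = np.argsort(arr[:, 0], kind="stable")
    arr = arr[order]
    if np.any(np.diff(arr[:, 0]) <= 0):
        raise ValueError(f"{path}: duplicate calendar knots — grid not strictly monotone")
    return CalibrationCurve(arr[:, 0], arr[:, 1], arr[:, 2], name=name)


def read_dates(path) -> list[RadiocarbonDate]:
    """Read a dates CSV with columns lab_id, c14_age, c14_error, curve_id[, region]."""
    dates: list[RadiocarbonDate] = []
    with open(path, "r", newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"lab_id", "c14_age", "c14_error", "curve_id"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"{path}: dates CSV must have columns {sorted(required)}")
        for row in reader:
            dates.append(
                RadiocarbonDate(
                    lab_id=row["lab_id"],
                    c14_age=float(row["c14_age"]),
                    c14_error=float(row["c14_error"]),
                    curve_id=row["curve_id"],
                    region=row.get("region") or None,
                )
            )
    return dates


def write_dates(dates: Sequence[RadiocarbonDate], path) -> None:
    """Write dates to the CSV dialect that :func:`read_dates` reads."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["lab_id", "c14_age", "c14_error", "curve_id", "region"])
        for d in dates:
            writer.writerow([d.lab_id, repr(d.c14_age), repr(d.c14_error), d.curve_id, d.region or ""])


def gaussian_ordinates(c14_age: float, c14_error: float, mu: np.ndarray, curve_sigma: np.ndarray) -> np.ndarray:
    """Gaussian ordinate of the measured age at each calendar year.

    Shared kernel for single-date calibration and SPD accumulation, so
    the two paths are numerically identical.
    """
    var = c14_error**2 + curve_sigma**2
    sd = np.sqrt(var)
    z = (c14_age - mu) / sd
    return np.exp(-0.5 * z * z) / (sd * _SQRT2PI)


def calibrate_date(
    date: RadiocarbonDate,
    curve: CalibrationCurve,
    window: tuple[float, float] = (0, 15000),
    normalize: bool = True,
) -> CalibratedDensity:
    """Calibrate one date over an integer calendar-year window.

    Parameters
    ----------
    window:
        (young, old) bounds in cal BP, inclusive; must lie within the
        curve's calendar support. The density grid is every integer year
        in the window, ascending cal BP.
    normalize:
        If True, densities are rescaled to sum to 1 over the window; if
        False the raw Gaussian ordinates are returned (the "unnormalized"
        dialect used to build SPDs). Mass outside the window is simply
        truncated, never reflected or renormalized in unnormalized mode.
    """
    lo, hi = float(min(window)), float(max(window))
    c_lo, c_hi = curve.cal_support
    if lo < c_lo or hi > c_hi:
        raise CalibrationError(
            f"window ({lo}, {hi}) outside curve {curve.name!r} calendar support ({c_lo}, {c_hi})"
        )
    a_lo, a_hi = curve.c14_support
    if not (a_lo <= date.c14_age <= a_hi):
        raise CalibrationError(
            f"date {date.lab_id!r}: ¹⁴C age {date.c14_age} outside curve "
            f"{curve.name!r} range ({a_lo}, {a_hi})"
        )
    grid = np.arange(int(np.ceil(lo)), int(np.floor(hi)) + 1)
    mu = curve.c14_at(grid)
    sig = curve.sigma_at(grid)
    dens = gaussian_ordinates(date.c14_age, date.c14_error, mu, sig)
    total = dens.sum()
    if total == 0.0:
        warnings.warn(
            f"date {date.lab_id!r}: zero calibrated density over window ({lo}, {hi})",
            RuntimeWarning,
            stacklevel=2,
        )
        return CalibratedDensity(grid, dens, normalized=False)
    if normalize:
        dens = dens / total
    return CalibratedDensity(grid, dens, normalized=normalize)
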