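"""End-to-end orchestration: dates → SPD → breakpoint → waves → fits.

``run_region`` executes the full analysis for one pooled regional date
list under a :class:`RunConfig`, with one log line per stage and a fully
deterministic result for a given config + seed.  Reports serialize to
JSON (byte-stable) and flat CSV tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import ccmodel, changepoint, growth as growth_mod, spd as spd_mod
from .radiocarbon import RadiocarbonDate
from .spd import SPDSeries

logger = logging.getLogger("popwaves")

__all__ = ["RunConfig", "RegionReport", "PipelineError", "run_region"]


class PipelineError(RuntimeError):
    """A stage failure, annotated with region and stage name."""


@dataclass(frozen=True)
class RunConfig:
    """All pipeline settings; defaults are the standard analysis choices:
    unnormalized SPD over the past 15 000 years, 200-yr rolling mean,
    30-yr generations, mean-shift breakpoint with 0.15 trimming,
    strictly-positive growth waves of >= 4 points."""

    window: tuple[int, int] = (0, 15000)
    normalize: bool = False
    smoothing_window: int = 200
    generation_width: int = 30
    trim_policy: str = "auto"  # "auto" or "lo,hi" cal BP bounds
    trim_eps: float = 1e-6
    smooth_before_trim: bool = True
    breakpoint_model: str = "mean_shift"
    breakpoint_trim_frac: float = 0.15
    breakpoint_on: str = "annual"  # "annual" (smoothed SPD) or "generational"
    significance_method: str = "permutation"
    n_perm: int = 199
    wave_tolerance: float = 0.0
    min_points: int = 4
    fit_method: str = "nls"
    constrain_nonneg: bool = True
    log_floor: float = 1e-12
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["window"] = list(self.window)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "window" in d:
            d["window"] = tuple(int(v) for v in d["window"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def _trim_spec(self):
        if self.trim_policy == "auto":
            return "auto"
        lo, hi = (float(v) for v in str(self.trim_policy).split(","))
        return (lo, hi)


@dataclass(frozen=True)
class RegionReport:
    """Everything one regional run produced, ready to serialize."""

    region: str
    n_dates: int
    config: RunConfig
    spd_meta: dict
    breakpoint: changepoint.BreakpointFit
    p_value: float
    waves: list
    fits: list  # Optional[CCFit] aligned with waves (None = unfittable)
    duration_stats: Optional[growth_mod.WaveDurationStats]
    growth: growth_mod.GrowthSeries = field(repr=False, compare=False, default=None)
    annual: SPDSeries = field(repr=False, compare=False, default=None)
    generational: spd_mod.GenerationalSeries = field(repr=False, compare=False, default=None)

    def to_dict(self) -> dict:
        bp = self.breakpoint
        waves = []
        for w, f in zip(self.waves, self.fits):
            entry = {
                "start_index": w.start_index,
                "end_index": w.end_index,
                "t_start_cal_bp": w.t_start,
                "t_end_cal_bp": w.t_end,
                "duration_years": w.duration,
                "n_points": w.n_points,
                "fittable": w.fittable,
            }
            if f is not None:
                entry["fit"] = {
                    "rm": f.params.rm,
                    "c": f.params.c,
                    "w": f.params.w,
                    "se": list(f.se),
                    "rss": f.rss,
                    "r_squared": f.r_squared,
                    "aic": f.aic,
                    "delta_aic": f.delta_aic,
                    "shape": f.shape,
                    "degenerate": f.degenerate,
                }
            waves.append(entry)
        return {
            "region": self.region,
            "n_dates": self.n_dates,
            "config": self.config.to_dict(),
            "spd": self.spd_meta,
            "breakpoint": {
                "break_cal_bp": bp.break_cal_bp,
                "break_index": bp.break_index,
                "model": bp.model,
                "seg1_coef": list(bp.seg1_coef),
                "seg2_coef": list(bp.seg2_coef),
                "rss_split": bp.rss_split,
                "rss_null": bp.rss_null,
                "sup_f": bp.sup_f if np.isfinite(bp.sup_f) else None,
                "trim_frac": bp.trim_frac,
                "no_structural_change": bp.no_structural_change,
                "p_value": self.p_value,
            },
            "waves": waves,
            "duration_stats": None
            if self.duration_stats is None
            else {
                "mean_years": self.duration_stats.mean_years,
                "count": self.duration_stats.count,
                "hist_counts": self.duration_stats.hist_counts.tolist(),
                "hist_edges": self.duration_stats.hist_edges.tolist(),
            },
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def fits_frame(self) -> pd.DataFrame:
        rows = []
        for w, f in zip(self.waves, self.fits):
            row = {
                "region": self.region,
                "t_start_cal_bp": w.t_start,
                "t_end_cal_bp": w.t_end,
                "duration_years": w.duration,
                "n_points": w.n_points,
                "fittable": w.fittable,
            }
            if f is not None:
                row.update(
                    rm=f.params.rm, c=f.params.c, w=f.params.w,
                    se_rm=f.se[0], se_c=f.se[1], se_w=f.se[2],
                    rss=f.rss, r_squared=f.r_squared, aic=f.aic,
                    delta_aic=f.delta_aic, shape=f.shape,
                )
            rows.append(row)
        return pd.DataFrame(rows)


def _stage(region: str, name: str):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is not None:
                logger.error("[%s:%s] failed after %.2fs: %s", region, name, dt, exc)
                raise PipelineError(f"[{region}:{name}] {exc}") from exc
            logger.info("[%s:%s] done in %.2fs", region, name, dt)

    return _Ctx()


def run_region(
    dates: Sequence[RadiocarbonDate],
    curves,
    config: RunConfig = RunConfig(),
    region: str = "region",
) -> RegionReport:
    """Run the full pipeline for one pooled regional date list."""
    if len(dates) == 0:
        raise PipelineError(f"[{region}:input] no dates supplied")

    with _stage(region, "spd"):
        raw = spd_mod.build_spd(dates, curves, window=config.window, normalize=config.normalize)
        logger.info("[%s:spd] %d dates on %d annual steps", region, raw.n_dates, len(raw))

    with _stage(region, "smooth+trim"):
        series = raw
        steps = (
            ["smooth", "trim"] if config.smooth_before_trim else ["trim", "smooth"]
        )
        for step in steps:
            if step == "smooth" and config.smoothing_window > 1:
                series = spd_mod.rolling_smooth(series, config.smoothing_window)
            elif step == "trim":
                series = spd_mod.trim_edges(series, config._trim_spec(), eps=config.trim_eps)
        annual = series

    with _stage(region, "generations"):
        gens = spd_mod.to_generations(annual, width=config.generation_width)

    with _stage(region, "breakpoint"):
        bp_series = annual if config.breakpoint_on == "annual" else gens
        bp = changepoint.fit_single_breakpoint(
            bp_series, model=config.breakpoint_model, trim_frac=config.breakpoint_trim_frac
        )
        p = changepoint.significance(
            bp, method=config.significance_method, n_perm=config.n_perm, seed=config.seed
        )
        logger.info("[%s:breakpoint] break at %.0f cal BP (p=%.4g)", region, bp.break_cal_bp, p)

    with _stage(region, "growth"):
        gr = growth_mod.reproductive_rates(gens, floor=config.log_floor)
        n_floored = int(gr.floored.sum())
        if n_floored:
            logger.warning("[%s:growth] %d generational bins below the log floor", region, n_floored)

    with _stage(region, "waves"):
        waves = growth_mod.segment_waves(
            gr, min_points=config.min_points, tolerance=config.wave_tolerance
        )
        unfittable = sum(1 for w in waves if not w.fittable)
        if unfittable:
            logger.warning("[%s:waves] %d of %d waves unfittable", region, unfittable, len(waves))

    with _stage(region, "fits"):
        fits = []
        for w in waves:
            if not w.fittable:
                fits.append(None)
                continue
            try:
                fits.append(
                    ccmodel.fit_wave(
                        w, method=config.fit_method, constrain_nonneg=config.constrain_nonneg
                    )
                )
            except ValueError as exc:
                logger.warning("[%s:fits] wave at %.0f cal BP skipped: %s", region, w.t_start, exc)
                fits.append(None)

    stats = growth_mod.wave_duration_stats(waves) if waves else None

    spd_meta = {
        "window": list(config.window),
        "normalized": raw.normalized,
        "smoothing_window": annual.smoothing_window,
        "trim_bounds": list(annual.trim_bounds) if annual.trim_bounds else None,
        "n_annual_steps": len(annual),
        "n_generations": len(gens),
    }
    return RegionReport(
        region=region,
        n_dates=len(dates),
        config=config,
        spd_meta=spd_meta,
        breakpoint=bp,
        p_value=p,
        waves=waves,
        fits=fits,
        duration_stats=stats,
        growth=gr,
        annual=annual,
        generational=gens,
    )
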