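"""Single structural breakpoint in a population-proxy series.

The major demographic transition in an SPD series is located by classical
least-squares structural-change search: every admissible split point is
tried, the chosen regression (segment mean, or intercept + slope on time)
is fitted independently on each side, and the split minimizing combined
residual sum of squares is returned together with a sup-F statistic.
Significance is assessed by permutation of null-model residuals by
default; an asymptotic mode provides a conservative Bonferroni bound on
the pointwise F tail as a documented approximation to sup-F asymptotics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy import stats

from .spd import GenerationalSeries, SPDSeries

__all__ = ["BreakpointFit", "fit_single_breakpoint", "significance"]

_MODELS = ("mean_shift", "trend_shift")


@dataclass(frozen=True)
class BreakpointFit:
    """Result of the exhaustive single-split least-squares search.

    ``break_index`` is the first observation of the post-shift regime in
    forward-in-time ordering; ``break_cal_bp`` is its calendar year.
    """

    break_cal_bp: float
    break_index: int
    seg1_coef: tuple[float, ...]
    seg2_coef: tuple[float, ...]
    rss_split: float
    rss_null: float
    sup_f: float
    trim_frac: float
    model: str
    no_structural_change: bool = False
    # retained so significance() can re-run the search under permutation
    y: np.ndarray = field(default=None, repr=False, compare=False)

    @property
    def n(self) -> int:
        return 0 if self.y is None else int(self.y.size)


def _extract_forward(series) -> tuple[np.ndarray, np.ndarray]:
    """Return (time_labels, values) ordered forward in time (old → young)."""
    if isinstance(series, SPDSeries):
        return series.cal_bp[::-1].astype(float), series.value[::-1].copy()
    if isinstance(series, GenerationalSeries):
        return series.bin_start_cal_bp.astype(float), series.value.copy()
    y = np.asarray(series, dtype=float)
    return np.arange(y.size, dtype=float), y.copy()


def _prefix_rss_mean(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """RSS of a mean-only fit on every prefix y[:k] and suffix y[k:]."""
    n = y.size
    c1 = np.cumsum(y)
    c2 = np.cumsum(y * y)
    k = np.arange(1, n + 1, dtype=float)
    pre = c2 - c1 * c1 / k
    tot1, tot2 = c1[-1], c2[-1]
    m = n - k  # suffix sizes for split after position k
    s1 = tot1 - c1
    s2 = tot2 - c2
    with np.errstate(invalid="ignore", divide="ignore"):
        suf = s2 - np.where(m > 0, s1 * s1 / np.maximum(m, 1), 0.0)
    return np.maximum(pre, 0.0), np.maximum(suf, 0.0)


def _prefix_rss_linear(t: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """RSS of an intercept+slope fit on every prefix/suffix, via cumulants."""
    n = y.size
    k = np.arange(1, n + 1, dtype=float)
    cx, cy = np.cumsum(t), np.cumsum(y)
    cxx, cyy, cxy = np.cumsum(t * t), np.cumsum(y * y), np.cumsum(t * y)

    def seg_rss(nn, sx, sy, sxx, syy, sxy):
        with np.errstate(invalid="ignore", divide="ignore"):
            sxx_c = sxx - sx * sx / nn
            syy_c = syy - sy * sy / nn
            sxy_c = sxy - sx * sy / nn
            rss = np.where(sxx_c > 0, syy_c - sxy_c * sxy_c / np.maximum(sxx_c, 1e-300), syy_c)
        return np.maximum(rss, 0.0)

    pre = seg_rss(k, cx, cy, cxx, cyy, cxy)
    m = np.maximum(n - k, 1.0)
    suf = seg_rss(m, cx[-1] - cx, cy[-1] - cy, cxx[-1] - cxx, cyy[-1] - cyy, cxy[-1] - cxy)
    suf[n - k == 0] = 0.0
    return pre, suf


def _search(t: np.ndarray, y: np.ndarray, model: str, trim_frac: float):
    """Exhaustive split search; returns (k*, rss_split, rss_null, sup_f)."""
    n = y.size
    p_seg = 1 if model == "mean_shift" else 2
    k_min = max(p_seg, int(np.ceil(trim_frac * n)))
    k_max = n - k_min
    if k_max < k_min:
        raise ValueError(f"series length {n} admits no split at trim_frac={trim_frac}")
    if model == "mean_shift":
        pre, suf = _prefix_rss_mean(y)
        rss_null = float(pre[-1])
    else:
        pre, suf = _prefix_rss_linear(t, y)
        rss_null = float(pre[-1])
    ks = np.arange(k_min, k_max + 1)
    combined = pre[ks - 1] + suf[ks - 1]  # split before index k: y[:k] | y[k:]
    i_best = int(np.argmin(combined))
    k_star = int(ks[i_best])
    rss_split = float(combined[i_best])

    p2 = 2 * p_seg
    q = p_seg  # extra parameters of the two-segment model
    dof = n - p2
    with np.errstate(invalid="ignore", divide="ignore"):
        f = ((rss_null - combined) / q) / np.where(combined > 0, combined / max(dof, 1), np.inf)
    f = np.where(combined > 0, f, np.inf)
    if rss_null <= 1e-300:  # constant (or perfectly fit) series: no signal
        sup_f = 0.0
    else:
        sup_f = float(np.max(f))
        if not np.isfinite(sup_f):
            sup_f = np.inf
    return k_star, rss_split, rss_null, sup_f


def _segment_coefs(t, y, k, model):
    if model == "mean_shift":
        return (float(np.mean(y[:k])),), (float(np.mean(y[k:])),)
    c1 = np.polyfit(t[:k], y[:k], 1)
    c2 = np.polyfit(t[k:], y[k:], 1)
    return (float(c1[1]), float(c1[0])), (float(c2[1]), float(c2[0]))


def fit_single_breakpoint(
    series, model: str = "mean_shift", trim_frac: float = 0.15
) -> BreakpointFit:
    """Locate the single least-squares breakpoint of a series.

    Parameters
    ----------
    series:
        :class:`~popwaves.spd.SPDSeries`, :class:`~popwaves.spd.GenerationalSeries`
        or a plain value array; analysed forward in time.
    model:
        ``"mean_shift"`` — a segment-wise constant mean (the default, a
        shift-in-mean reading of the transition); ``"trend_shift"`` — a
        segment-wise intercept + slope on time.
    trim_frac:
        Minimum fraction of observations required on each side of the
        split (0.15, the usual structural-change convention).

    A zero-variance series is not an error: it returns ``sup_f = 0`` with
    ``no_structural_change`` set.
    """
    if model not in _MODELS:
        raise ValueError(f"model must be one of {_MODELS}")
    t, y = _extract_forward(series)
    if y.size < 4:
        raise ValueError("series too short for breakpoint search")
    k, rss_split, rss_null, sup_f = _search(t, y, model, trim_frac)
    seg1, seg2 = _segment_coefs(t, y, k, model)
    return BreakpointFit(
        break_cal_bp=float(t[k]),
        break_index=k,
        seg1_coef=seg1,
        seg2_coef=seg2,
        rss_split=rss_split,
        rss_null=rss_null,
        sup_f=sup_f,
        trim_frac=trim_frac,
        model=model,
        no_structural_change=(sup_f == 0.0),
        y=y,
    )


def _null_prediction(t, y, model):
    if model == "mean_shift":
        return np.full_like(y, np.mean(y))
    b, a = np.polyfit(t, y, 1)[::-1]  # intercept, slope
    return b + a * t


def significance(
    fit: BreakpointFit,
    method: str = "permutation",
    n_perm: int = 199,
    seed: Optional[int] = None,
) -> float:
    """p-value for the null hypothesis of no structural change.

    ``permutation`` (default, distribution-free): residuals from the
    single-regime null fit are randomly reordered, the sup-F statistic is
    recomputed for each reordering, and
    p = (1 + #{permuted sup_f >= observed}) / (1 + n_perm).

    ``asymptotic``: a Bonferroni bound over the admissible split points
    applied to the pointwise F tail — a documented, conservative
    approximation to the sup-F asymptotic distribution.
    """
    if fit.y is None:
        raise ValueError("fit carries no data; refit with fit_single_breakpoint")
    y = fit.y
    t = np.arange(y.size, dtype=float)
    if fit.sup_f == 0.0:
        return 1.0
    if method == "permutation":
        if n_perm < 99:
            raise ValueError("n_perm must be >= 99")
        rng = np.random.default_rng(seed)
        pred = _null_prediction(t, y, fit.model)
        resid = y - pred
        count = 0
        for _ in range(n_perm):
            y_perm = pred + rng.permutation(resid)
            _, _, _, f_perm = _search(t, y_perm, fit.model, fit.trim_frac)
            if f_perm >= fit.sup_f:
                count += 1
        return (1 + count) / (1 + n_perm)
    if method == "asymptotic":
        n = y.size
        p_seg = 1 if fit.model == "mean_shift" else 2
        k_min = max(p_seg, int(np.ceil(fit.trim_frac * n)))
        n_candidates = n - 2 * k_min + 1
        q, dof = p_seg, n - 2 * p_seg
        if not np.isfinite(fit.sup_f):
            return 0.0
        p_point = stats.f.sf(fit.sup_f, q, dof)
        return float(min(1.0, n_candidates * p_point))
    raise ValueError(f"unknown method {method!r}")
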