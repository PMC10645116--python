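"""Cooperation/competition population growth model.

The model is a Ricker map augmented with a hyperbolic Allee (cooperation)
term.  On the abundance scale the per-generation net rate is

    r_t = r_m · exp(−c·x_t − w / x_t),        x_{t+1} = x_t · r_t

and on the log scale, with X = ln x and R = ln r (so R_m = ln r_m),

    R(X) = R_m − c·e^X − w·e^(−X).

R_m is the log maximum reproductive rate per generation, c >= 0 the
intensity of intra-population competition (per abundance unit) and
w >= 0 the intensity of cooperation (abundance units).  When c, w > 0 the
R–X curve is humped with interior maximum at X* = ½·ln(w/c), R* = R_m −
2√(cw), and the map has up to two positive equilibria — the roots of
c·x² − R_m·x + w = 0 — an unstable Allee threshold below and a stable
(or oscillatory) carrying level above.

Because R(X) is linear in (R_m, c, w) given the predictors e^X and
e^(−X), the least-squares fit has a closed form; the nonlinear
least-squares route starts there and must agree on unconstrained
problems.  Model comparison against the nested pure-Ricker fit (w = 0)
uses small-sample-corrected AIC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Union

import numpy as np
from scipy.optimize import least_squares, lsq_linear

from .growth import Wave

__all__ = [
    "CCParams",
    "CCFit",
    "EquilibriumSet",
    "SimulatedTrajectory",
    "predict_R",
    "simulate",
    "equilibria",
    "rx_peak",
    "fit_wave",
]

_ZERO_TOL = 1e-12


@dataclass(frozen=True)
class CCParams:
    """(R_m, c, w): log max reproductive rate, competition, cooperation.

    The ecological interpretation requires c >= 0 and w >= 0, and the
    simulation entry points enforce that; negative values are tolerated
    in the container itself only so unconstrained diagnostic fits can be
    represented.
    """

    rm: float
    c: float
    w: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.rm) and np.isfinite(self.c) and np.isfinite(self.w)):
            raise ValueError("CCParams must be finite")


def predict_R(params: CCParams, X) -> Union[float, np.ndarray]:
    """R(X) = R_m − c·e^X − w·e^(−X)."""
    X = np.asarray(X, dtype=float)
    out = params.rm - params.c * np.exp(X) - params.w * np.exp(-X)
    return float(out) if out.ndim == 0 else out


class SimulatedTrajectory(NamedTuple):
    sizes: np.ndarray  # x_0 .. x_n (truncated early on underflow)
    extinct: bool


def simulate(
    params: CCParams,
    x0: float,
    n_gen: int,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    floor: float = 1e-9,
) -> SimulatedTrajectory:
    """Iterate the map for ``n_gen`` generations from ``x0 > 0``.

    With ``noise_sd > 0`` each step is multiplied by a lognormal factor
    exp(ε), ε ~ N(0, noise_sd²) (environmental/process noise on the
    reproductive rate).  If the size underflows ``floor`` the trajectory
    is truncated there and flagged extinct.
    """
    if x0 <= 0:
        raise ValueError("x0 must be > 0")
    if n_gen < 0:
        raise ValueError("n_gen must be >= 0")
    if params.c < 0 or params.w < 0:
        raise ValueError("simulation requires c >= 0 and w >= 0")
    rng = np.random.default_rng(seed)
    sizes = np.empty(n_gen + 1)
    sizes[0] = x0
    x = float(x0)
    for i in range(1, n_gen + 1):
        R = params.rm - params.c * x - params.w / x
        if noise_sd > 0:
            R = R + rng.normal(0.0, noise_sd)
        x = x * np.exp(R)
        if not np.isfinite(x) or x < floor:
            return SimulatedTrajectory(sizes[:i].copy(), True)
        sizes[i] = x
    return SimulatedTrajectory(sizes, False)


@dataclass(frozen=True)
class EquilibriumSet:
    """Positive fixed points of the map (roots of c·x² − R_m·x + w = 0).

    ``exists`` flags the generic two-root case (c > 0, w > 0, R_m² >= 4cw).
    In the degenerate limits one root may still be populated: pure Ricker
    (w = 0) has the carrying level x_upper = R_m/c; pure cooperation
    (c = 0) has only the Allee threshold x_lower = w/R_m.  Stability is
    from the map derivative |1 − c·x* + w/x*| < 1.
    """

    x_lower: Optional[float]
    x_upper: Optional[float]
    exists: bool
    stable_lower: Optional[bool] = None
    stable_upper: Optional[bool] = None


def _stable(params: CCParams, x: float) -> bool:
    return bool(abs(1.0 - params.c * x + params.w / x) < 1.0)


def equilibria(params: CCParams) -> EquilibriumSet:
    """Solve for the fixed points with the numerically stable quadratic form."""
    rm, c, w = params.rm, params.c, params.w
    if c < 0 or w < 0:
        return EquilibriumSet(None, None, False)
    if c > 0 and w > 0:
        disc = rm * rm - 4.0 * c * w
        if rm <= 0 or disc < 0:
            return EquilibriumSet(None, None, False)
        q = 0.5 * (rm + np.sqrt(disc))
        x_upper = q / c
        x_lower = w / q
        return EquilibriumSet(
            float(x_lower),
            float(x_upper),
            True,
            stable_lower=_stable(params, x_lower),
            stable_upper=_stable(params, x_upper),
        )
    if c > 0 and w == 0:
        if rm <= 0:
            return EquilibriumSet(None, None, False)
        x = rm / c
        return EquilibriumSet(None, float(x), False, stable_upper=_stable(params, x))
    if c == 0 and w > 0:
        if rm <= 0:
            return EquilibriumSet(None, None, False)
        x = w / rm
        return EquilibriumSet(float(x), None, False, stable_lower=_stable(params, x))
    return EquilibriumSet(None, None, False)  # density-independent limit


def rx_peak(params: CCParams) -> tuple[float, float]:
    """Interior maximum of the R–X curve: (½·ln(w/c), R_m − 2√(cw))."""
    if params.c <= 0 or params.w <= 0:
        raise ValueError("rx_peak requires c > 0 and w > 0 (no interior maximum otherwise)")
    x_peak = 0.5 * np.log(params.w / params.c)
    r_peak = params.rm - 2.0 * np.sqrt(params.c * params.w)
    return float(x_peak), float(r_peak)


@dataclass(frozen=True)
class RickerFit:
    """Nested pure-Ricker (w = 0) diagnostics for model comparison."""

    rm: float
    c: float
    rss: float
    aic: float


@dataclass(frozen=True)
class CCFit:
    """Least-squares fit of R(X) to one growth wave, with diagnostics."""

    params: CCParams
    se: tuple[float, float, float]
    rss: float
    r_squared: float
    aic: float
    n: int
    ricker: RickerFit
    delta_aic: float  # aic(ricker) − aic(full); positive favours the full model
    shape: str  # "humped" iff fitted c > 0 and w > 0, else "monotone"
    method: str
    degenerate: bool = False  # constrained fit pinned both c and w at 0


def _aicc(rss: float, n: int, k: int) -> float:
    """Gaussian AIC with small-sample correction; k counts sigma too."""
    rss = max(rss, 1e-300)
    aic = n * np.log(rss / n) + 2 * k
    if n - k - 1 > 0:
        aic += 2.0 * k * (k + 1) / (n - k - 1)
    return float(aic)


def _linear_solve(A: np.ndarray, R: np.ndarray, constrain: bool) -> np.ndarray:
    if constrain:
        res = lsq_linear(A, R, bounds=([-np.inf, 0.0, 0.0][: A.shape[1]], np.inf))
        return res.x
    beta, *_ = np.linalg.lstsq(A, R, rcond=None)
    return beta


def fit_wave(
    wave: Union[Wave, tuple],
    method: str = "nls",
    constrain_nonneg: bool = True,
) -> CCFit:
    """Fit R(X) = R_m − c·e^X − w·e^(−X) to one wave's (X, R) points.

    ``method="linear"`` solves the problem in closed form (the model is
    linear in its parameters given predictors e^X and e^(−X)), optionally
    with non-negativity constraints on c and w; ``method="nls"`` runs
    iterative nonlinear least squares initialized at the linear solution.
    The two agree to high precision on unconstrained problems.  The
    nested pure-Ricker fit (w = 0) is always computed alongside for the
    delta-AICc comparison and the humped/monotone shape call.
    """
    if isinstance(wave, Wave):
        X = wave.points[:, 0]
        R = wave.points[:, 1]
    else:
        X, R = (np.asarray(a, dtype=float) for a in wave)
    n = X.size
    if n < 4:
        raise ValueError("wave must have >= 4 (X, R) points for a 3-parameter fit")
    if np.unique(X).size < 3:
        raise ValueError("need >= 3 distinct X values (rank-deficient predictors)")
    if method not in ("linear", "nls"):
        raise ValueError("method must be 'linear' or 'nls'")

    eX, emX = np.exp(X), np.exp(-X)
    A = np.column_stack((np.ones(n), -eX, -emX))

    beta = _linear_solve(A, R, constrain_nonneg)
    if method == "nls":
        lo = np.array([-np.inf, 0.0, 0.0]) if constrain_nonneg else -np.inf
        x0 = np.clip(beta, lo if constrain_nonneg else -np.inf, np.inf)
        sol = least_squares(
            lambda b: A @ b - R,
            x0=x0,
            jac=lambda b: A,
            bounds=(lo, np.inf) if constrain_nonneg else (-np.inf, np.inf),
            ftol=1e-12,
            xtol=1e-12,
            gtol=1e-12,
            max_nfev=200,
        )
        beta = sol.x
    rm_hat, c_hat, w_hat = (float(b) for b in beta)
    if constrain_nonneg:
        c_hat, w_hat = max(c_hat, 0.0), max(w_hat, 0.0)

    resid = A @ np.array([rm_hat, c_hat, w_hat]) - R
    rss = float(resid @ resid)
    tss = float(np.sum((R - R.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else np.nan
    aic_full = _aicc(rss, n, k=4)

    # standard errors from the unconstrained normal equations
    dof = max(n - 3, 1)
    try:
        cov = np.linalg.inv(A.T @ A) * (rss / dof)
        se = tuple(float(s) for s in np.sqrt(np.maximum(np.diag(cov), 0.0)))
    except np.linalg.LinAlgError:
        se = (np.nan, np.nan, np.nan)

    # nested Ricker: w forced to 0
    A2 = A[:, :2]
    if constrain_nonneg:
        b2 = lsq_linear(A2, R, bounds=([-np.inf, 0.0], np.inf)).x
    else:
        b2, *_ = np.linalg.lstsq(A2, R, rcond=None)
    resid2 = A2 @ b2 - R
    rss2 = float(resid2 @ resid2)
    ricker = RickerFit(rm=float(b2[0]), c=float(b2[1]), rss=rss2, aic=_aicc(rss2, n, k=3))

    shape = "humped" if (c_hat > _ZERO_TOL and w_hat > _ZERO_TOL) else "monotone"
    degenerate = bool(constrain_nonneg and c_hat <= _ZERO_TOL and w_hat <= _ZERO_TOL)
    return CCFit(
        params=CCParams(rm_hat, c_hat, w_hat),
        se=se,
        rss=rss,
        r_squared=r2,
        aic=aic_full,
        n=n,
        ricker=ricker,
        delta_aic=float(ricker.aic - aic_full),
        shape=shape,
        method=method,
        degenerate=degenerate,
    )
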