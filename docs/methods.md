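# Methods

## Calibration and SPD construction

A radiocarbon determination is a conventional ¹⁴C age `y ± σ_lab` (¹⁴C yr
BP). A calibration curve supplies, per calendar year θ (cal BP; 0 = AD
1950, values increase into the past), the expected ¹⁴C age μ(θ) with a
1σ curve error σ_c(θ); between tabulated knots both are linearly
interpolated. The calibrated density of a date at θ is the Gaussian
ordinate

    f(θ) = N(y; μ(θ), σ_lab² + σ_c(θ)²)

evaluated on a 1-calendar-year grid. Two dialects exist:

- **normalized** — f rescaled to unit mass over the window (used when a
  single date's calendar probability is wanted);
- **unnormalized** — raw ordinates, no per-date rescaling. This is the
  dialect used for SPDs throughout, because per-date renormalization
  inflates density wherever the calibration curve is steep, producing
  spurious spikes in the sum. Mass falling outside the analysis window
  is truncated, never reflected or renormalized.

The SPD is the pointwise sum of per-date densities over the window
(default 0–15 000 cal BP). Post-processing, in order:

1. **200-yr centered rolling mean.** Calibration noise and sampling
   noise at annual resolution are far larger than any demographic
   signal; the window is the standard smoothing span for these series.
   Edge years without a full window carry no value and are dropped (for
   an even window, the assigned year sits half a step toward the past).
   Smoothing runs *before* edge trimming (order configurable): the
   near-zero tails must still be present for the mean to be honest
   about them, and the trim then removes every smeared edge artifact in
   one pass.
2. **Edge trim.** Leading/trailing years below 1e−6 × series maximum
   (configurable, or explicit bounds) are dropped — raw SPDs decay to
   machine-zero tails where no data exist, and a log-scale growth
   analysis must not see them.
3. **Generational binning.** Annual values are summed into consecutive
   30-yr bins (one human generation) anchored at the oldest trimmed
   year and proceeding toward the present. A trailing partial bin is
   dropped, never zero-padded — padding would fabricate a crash.
   Binning conserves mass exactly over the binned span.

All annual series are stored ascending in cal BP; generational series
are stored forward in time (decreasing cal BP), the order in which
growth rates are defined.

## Breakpoint search

The transition date is the split k minimizing

    RSS(k) = RSS(model | y_1..y_k) + RSS(model | y_{k+1}..y_n)

over all admissible k, with at least `trim_frac = 0.15` of the series on
each side (the usual structural-change convention). The default
segment model is a constant mean (`mean_shift`) — the reading in which
pre- and post-shift mean SPD levels are estimated jointly with the
change point; `trend_shift` (intercept + slope on time) is provided for
the alternative reading in which the regression on time shifts. The
search is exact (every admissible split, via prefix cumulants, O(n))
and runs by default on the smoothed annual SPD rather than the 30-yr
bins, where the split is resolved to the year.

The sup-F statistic is max over k of the F ratio between the null
(single-regime) and two-segment fits. Significance:

- **permutation** (default, 199 permutations): residuals from the null
  fit are reordered uniformly at random and sup-F recomputed;
  p = (1 + #{perm ≥ obs}) / (1 + n_perm). Distribution-free, and exact
  up to Monte-Carlo error under exchangeability.
- **asymptotic**: a Bonferroni bound over candidate splits applied to
  the pointwise F tail — deliberately conservative, and labelled an
  approximation; the exact sup-F asymptotics are not implemented.

A zero-variance series returns sup-F = 0 with a "no structural change"
flag rather than an error. A perfectly fitting split (RSS = 0) yields
an infinite sup-F, which permutation handles naturally (p attains its
minimum).

Estimator caveat, by construction: the population responds *after* the
regime switch, and a mean-shift split of a monotone ramp lands where
the series crosses the midpoint of the two segment means. The
breakpoint therefore lags the true switch by roughly the time the
population takes to cover half its level jump — about 1–2 generations
in the reference scenario. This is a property of the estimand, not an
implementation artifact.

## Growth rates, waves, phase portraits

With generational values v_t (forward in time), X_t = ln max(v_t, floor)
with floor = 1e−12; bins at the floor are flagged, and any wave touching
one is excluded from fitting (its log value is an artifact of the
floor). R_t = X_{t+1} − X_t. Both X and R are invariant to positive
rescaling of the proxy up to an additive constant in X, so the
(unknown) proportionality between SPD amplitude and true population
size does not affect wave segmentation — but it does set the *scale* of
the fitted c and w (per SPD unit and SPD units respectively), which are
reported on the data scale.

A **wave** is a maximal run of consecutive steps with R_t > tolerance
(default 0; exposed because near-zero dips within an expansion are a
plausible alternative reading). Waves shorter than `min_points = 4`
steps are reported but flagged unfittable — four points is the minimum
leaving one residual degree of freedom for a 3-parameter fit. Wave
duration = steps × 30 yr.

## The cooperation/competition model

Abundance scale: x_{t+1} = x_t · r_m · exp(−c·x_t − w/x_t). Log scale:
R(X) = R_m − c·e^X − w·e^(−X), R_m = ln r_m. Equilibria are the roots
of c·x² − R_m·x + w = 0, computed with the numerically stable quadratic
form (no cancellation for small c); local stability from the map
derivative |1 − c·x* + w/x*| < 1. Degenerate limits are handled
analytically: pure Ricker (w = 0) has the single carrying level R_m/c;
pure cooperation (c = 0) has only the Allee threshold w/R_m. The R–X
curve is strictly concave whenever c, w > 0, with interior peak
X* = ½·ln(w/c), R* = R_m − 2√(cw).

**Fitting.** Given predictors e^X and e^(−X) the model is linear in
(R_m, c, w), so the least-squares problem has a closed form; this is
`method="linear"`, with optional non-negativity bounds on c and w via
bounded linear least squares. `method="nls"` (default) runs iterative
least squares initialized at the linear solution (tolerances 1e−12,
≤200 evaluations); the two agree to well below 1e−6 on unconstrained
problems, and the iterative route exists for the bounded case and as a
cross-check. Non-negativity is enforced by default (the parameters are
intensities); the unconstrained mode is retained for diagnostics, which
is also why the parameter container tolerates negative values even
though the simulation entry points reject them.

**Model comparison.** Each wave fit carries the nested pure-Ricker fit
(w = 0) and delta-AICc = AICc(Ricker) − AICc(full), using the
small-sample correction because waves typically have 5–15 points
(parameter count includes the error variance). The classification
`shape = "humped"` means both fitted c > 0 and w > 0 — the operational
criterion for "cooperation and competition both acting". A constrained
fit pinning both at zero is flagged degenerate. Standard errors come
from the unconstrained normal equations and are indicative only near an
active bound.

## Synthetic scenario generator

The generator emulates exactly the assumptions the analysis makes:

- latent population from the cooperation/competition map at 30-yr
  steps, with lognormal process noise (default sd 0.02/generation) and
  an ordered list of parameter regimes ("epochs") concatenated in time
  — the regime switch is what the breakpoint search should find;
- calendar years of dated events drawn ∝ population size (the
  SPD-as-proxy assumption), independently (regional pooling without
  site structure);
- measured ages = curve mean at the true year + Gaussian noise with
  variance σ_lab² + σ_c², i.e. the same error model calibration
  inverts;
- a synthetic calibration curve, linear with slope 1 plus a sinusoidal
  wiggle (default amplitude 15 ¹⁴C yr, period 500 yr, σ_c = 8 ¹⁴C yr)
  — monotone, so no calibration multimodality by default.

Reference scenario (`default_scenario`): 250 generations at parameters
(R_m, c, w) = (0.5, 0.02, 2.0) — carrying level 20 — then 250
generations at (1.2, 0.0118, 2.0) — carrying level ≈ 100, a five-fold
jump at 7500 cal BP — sampled into 5000 dates with 25 ¹⁴C-yr lab error.
The post-switch regime is deliberately abrupt (the transition completes
in ~3 generations): the breakpoint estimator's response-time lag
(above) must stay within the ±2-generation precision at which recovery
is asserted, and an abrupt transition is also what "demographic
transition" means in this analysis. Both regimes have c, w > 0, so the
generating dynamics are humped and wave classification has a defined
truth.

What the generator does **not** emulate: taphonomic loss (an optional
thinning hook exists but is off, matching an analysis that applies no
correction), spatial/site clustering of dates, research-intensity bias
across periods, reservoir offsets, curve plateaus and reversals beyond
the mild wiggle. Passing the round-trip tests therefore shows the
pipeline recovers what it assumes, under its own error model — not that
real regional series are free of those additional complications.

## Numerical and design notes

- Calibration, SPD accumulation and the synthetic forward model share
  one Gaussian-ordinate kernel, so sums equal loop-and-add calibration
  to rounding error.
- Rolling-mean output is clipped at 0 to absorb convolution round-off.
- Breakpoint prefix/suffix RSS uses cumulants with clipping at 0;
  the returned split is the global argmin (ties broken toward the
  earliest admissible split by the argmin convention).
- AICc uses rss floored at 1e−300 so noiseless interpolating fits
  remain finite-ordered.
- Wave fitting requires ≥ 3 distinct X values; identical-X input is a
  rank error, not a silent pseudo-inverse solve.
- Parameter-recovery experiments report the median of the estimates
  against the truth (a central-tendency measure); per-replicate scatter
  at the reference noise level is substantially wider than the ~2–3%
  median deviation and is visible in the standard errors instead.
- Problem sizes in the bundled experiments (5000 dates, 500 replicate
  fits, 500 oracle series, 199 permutations) were chosen so the whole
  analysis re-runs from scratch in well under a minute on one core
  while keeping Monte-Carlo error far below the asserted margins.

## Known limitations

- Single breakpoint only; multi-break segmentation is out of scope.
- The asymptotic significance mode is a conservative bound, not the
  exact sup-F distribution.
- c and w are scale-dependent (per SPD unit); comparisons across
  regions require a common proxy scale.
- The wave criterion (strict positivity at tolerance 0 on 30-yr bins)
  is one consistent reading of "uninterrupted growth"; small tolerance
  changes can merge or split waves near R ≈ 0.
- The visual "start of expansion" (as opposed to the least-squares
  break) is not formalized.
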