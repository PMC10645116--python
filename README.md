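# popwaves

Demographic transitions in deep-time population proxies built from
radiocarbon dates: summed probability distributions (SPDs), structural
breakpoints, waves of uninterrupted growth, and fits of a
cooperation/competition growth model to each wave.

## The problem

Archaeological radiocarbon dates, pooled over a region and calibrated to
the calendar axis, give a relative population-size proxy: the SPD. Across
the Holocene these series show abrupt expansions — a population sitting
near a low, roughly constant level for millennia and then shifting to a
much higher level within a few centuries. Two questions follow:

1. **When** did the shift happen? Answered here by least-squares
   structural-change search: the split point that minimizes the combined
   two-segment residual sum of squares of the SPD series, with a sup-F
   statistic and a permutation p-value.
2. **How** did the population grow through the shift? Answered by the
   phase portrait: with `X_t = ln SPD_t` per 30-yr generation and the log
   reproductive rate `R_t = X_{t+1} − X_t`, each maximal run of
   uninterrupted growth (`R_t > 0`, a "wave") is fitted with

   ```
   R_t = R_m − c·e^{X_t} − w·e^{−X_t}
   ```

   a Ricker map (competition, intensity `c`) augmented with a hyperbolic
   Allee term (cooperation, intensity `w`); `R_m` is the log maximum
   reproductive rate per generation. With `c, w > 0` the R–X curve is
   humped — growth *accelerating* with size at low density (positive
   feedback through cooperation) and declining at high density — with
   interior peak at `X* = ½·ln(w/c)`, `R* = R_m − 2√(cw)`, and up to two
   equilibria, the roots of `c·x² − R_m·x + w = 0` (an unstable Allee
   threshold and a carrying level). A humped fitted wave is the dynamic
   signature of cooperation-driven demographic transitions.

Because real regional date databases need a large download and
under-specified screening choices, the package ships a first-class
synthetic generator (`popwaves.synthetic`) producing radiocarbon
datasets with known ground truth — a latent trajectory of the same
growth model with a parameter-regime switch, dates sampled in proportion
to population size and forward-modelled through a calibration curve —
so breakpoint, wave and parameter recovery are all testable offline.

## Worked example

The numbered scripts under `analysis/` run the whole study on the
reference synthetic scenario (a five-fold equilibrium jump at 7500 cal
BP sampled into 5000 dates):

```sh
python analysis/01_simulate_dataset.py   # latent population + dates
python analysis/02_build_spd.py          # calibrate, sum, smooth, bin
python analysis/03_detect_transition.py  # breakpoint + permutation test
python analysis/04_fit_growth_waves.py   # waves + model fits
python analysis/05_make_figures.py       # SVG figures
```

Output (seed 1):

```
regime switch at 7500 cal BP; carrying level 20.1 -> 99.8
SPD from 5000 dates: 15001 annual steps
  after 200-yr smoothing and edge trim: 14802 steps
breakpoint at 7471 cal BP (permutation p = 0.005)
  true switch 7500 cal BP -> error -29 yr (1.0 generations)
45 growth waves (30 fittable), mean duration 165 yr
transition wave [7641, 7251] cal BP: shape=humped, R_m=0.637, c=0.02717, w=1.266, R²=0.78
```

Reading: the structural-change search dates the transition one
generation late (the population needs ~1–2 generations to respond to the
regime switch); the permutation test rejects "no structural change" at
its smallest attainable p (199 permutations); and the wave carrying the
transition has both `c > 0` and `w > 0` — a humped reproductive curve,
correctly classifying the generating dynamics, which had cooperation and
competition acting in both regimes.

The same pipeline runs from the shell on any dates CSV + calibration
curve (IntCal-format) via the console script:

```sh
popwaves simulate --out data/ --n-dates 5000 --seed 1
popwaves analyze data/dates.csv --curve data/curve.tsv --out report.json
```

## Layout

- `src/popwaves/` — the library: `radiocarbon` (curves + calibration),
  `spd` (summation, smoothing, binning), `changepoint` (breakpoint
  search + significance), `growth` (rates, waves, portraits), `ccmodel`
  (the growth model: prediction, simulation, equilibria, fitting),
  `synthetic` (scenario generator), `pipeline` (+ `cli`).
- `analysis/` — the numbered study drivers above.
- `docs/methods.md` — models, assumptions, parameter choices, numerics.
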