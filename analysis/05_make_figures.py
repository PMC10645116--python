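#!/usr/bin/env python
"""Figures: SPD with breakpoint, R_t series with waves, transition phase portrait.

Reads the outputs of steps 02-04 and writes three SVG figures under
results/figures/.
"""

import json
from pathlib import Path

import matplotlib.pyplot as plt
import pandas as pd

from popwaves import ccmodel, growth, plots
from popwaves.changepoint import fit_single_breakpoint
from popwaves.spd import GenerationalSeries, SPDSeries

ROOT = Path(__file__).resolve().parents[1] / "results"
FIGS = ROOT / "figures"


def main() -> None:
    FIGS.mkdir(parents=True, exist_ok=True)
    df = pd.read_csv(ROOT / "spd_annual.csv")
    annual = SPDSeries(df["cal_bp"].to_numpy(), df["value"].to_numpy(), n_dates=0,
                       smoothing_window=200)
    gdf = pd.read_csv(ROOT / "spd_generational.csv")
    gens = GenerationalSeries(gdf["bin_start_cal_bp"].to_numpy(), gdf["value"].to_numpy())

    bp = fit_single_breakpoint(annual)
    ax = plots.plot_spd_with_breakpoint(annual, bp)
    ax.figure.savefig(FIGS / "spd_breakpoint.svg", bbox_inches="tight")
    plt.close(ax.figure)

    gr = growth.reproductive_rates(gens)
    waves = growth.segment_waves(gr)
    ax = plots.plot_growth_waves(gr, waves)
    ax.figure.savefig(FIGS / "growth_waves.svg", bbox_inches="tight")
    plt.close(ax.figure)

    onset = json.loads((ROOT / "breakpoint.json").read_text())["break_cal_bp"]
    carrier = [w for w in waves if w.fittable and w.span()[0] <= onset <= w.span()[1]]
    if carrier:
        w = carrier[0]
        fit = ccmodel.fit_wave(w)
        ax = plots.plot_phase_portrait(w.points, fit)
        ax.set_title(f"transition wave ({w.t_start:.0f}-{w.t_end:.0f} cal BP), {fit.shape}")
        ax.figure.savefig(FIGS / "transition_phase_portrait.svg", bbox_inches="tight")
        plt.close(ax.figure)

    print(f"wrote figures to {FIGS}")


if __name__ == "__main__":
    main()
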