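"""Simulated voltage clamp of the four funny-current formulations.

Hold -40 mV, hyperpolarizing steps to -50..-100 mV (10 mV increments) for
5 s, then back to -40 mV for 5 s, in the blank Paci2018 host (fixed ionic
concentrations, host g_f for every formulation).  Writes a tidy CSV and a
four-panel figure of the current traces.
"""

from __future__ import annotations

import pathlib

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from hipsc_ap.ifcurrent import FORMULATIONS, clamp_to_frame, run_voltage_clamp

OUT = pathlib.Path("results")


def main() -> None:
    OUT.mkdir(exist_ok=True)
    frames = []
    fig, axes = plt.subplots(2, 2, figsize=(9, 6), sharex=True)
    order = ["paci", "severi2012", "fabbri2017", "koivumaki2018"]
    for ax, name in zip(axes.ravel(), order):
        steps = run_voltage_clamp(name)
        frames.append(clamp_to_frame(name, steps))
        for s in steps:
            ax.plot(s.t, s.current, lw=0.8,
                    label=f"{s.step_potential * 1e3:.0f} mV")
        ax.set_title(name)
        ax.set_ylabel("I_f (A/F)")
        end = steps[-1].current[5000]
        print(f"{name:>14}: I_f at -100 mV after 5 s = {end:7.3f} A/F")
    for ax in axes[1]:
        ax.set_xlabel("time (s)")
    axes[0, 0].legend(fontsize=6, ncol=2)
    fig.tight_layout()
    fig.savefig(OUT / "voltage_clamp.svg")
    pd.concat(frames, ignore_index=True).to_csv(OUT / "voltage_clamp.csv",
                                                index=False)
    print(f"wrote {OUT / 'voltage_clamp.csv'} and {OUT / 'voltage_clamp.svg'}")
    assert set(f for f in FORMULATIONS) == set(order)


if __name__ == "__main__":
    main()
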