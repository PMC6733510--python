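"""Acute vs limit-cycle response to funny-current scaling.

The acute protocol applies the g_f change exactly at the diastolic minimum
between two beats and reads the first/second post-perturbation action
potentials; comparison against the limit-cycle response exposes slow
adaptation (the two can disagree in sign).  Covers the native hosts and the
three I_f-substituted Paci2018 hosts.  Writes results/acute_effects.csv.
"""

from __future__ import annotations

import argparse
import pathlib

import pandas as pd

from hipsc_ap.ifcurrent import substitute_if
from hipsc_ap.parameters import load_parameters
from hipsc_ap.protocols import (
    FULL_PROTOCOL,
    ProtocolConfig,
    SCALED_DOWN_PROTOCOL,
    run_acute,
    run_limit_cycle,
    run_perturbed,
)

OUT = pathlib.Path("results")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--full", action="store_true")
    parser.add_argument("--quick", action="store_true",
                        help="120 s / 60 s smoke-test durations")
    parser.add_argument("--factors", type=float, nargs="+", default=[0.5, 2.0])
    args = parser.parse_args()
    if args.quick:
        config = ProtocolConfig(pre_duration=120.0, post_duration=120.0,
                                analysis_window=60.0, scaled_down=True)
    elif args.full:
        config = FULL_PROTOCOL
    else:
        config = SCALED_DOWN_PROTOCOL

    models = {v: load_parameters(v) for v in ("paci2017", "paci2018")}
    p18, y18 = models["paci2018"]
    for name in ("severi2012", "fabbri2017", "koivumaki2018"):
        models[f"paci2018+{name}"] = (substitute_if(p18, name), y18)

    rows = []
    for label, (params, y0) in models.items():
        lc = run_limit_cycle(params, y0, config)
        if lc.status != "beating":
            print(f"{label}: baseline not beating, skipped")
            continue
        for f in args.factors:
            acute = run_acute(lc.state, params, {"gf": f}, config,
                              label=f"gf_x{f:g}")
            chronic = run_perturbed(lc.state, params, {"gf": f}, config,
                                    label=f"gf_x{f:g}")
            rows.append({
                "model": label, "gf_factor": f,
                "baseline_rr_s": lc.series.mean_rr,
                "acute_rr_s": acute.mean_rr,
                "limit_cycle_rr_s": chronic.mean_rr,
                "acute_apd90_s": acute.mean_apd90,
                "limit_cycle_apd90_s": chronic.mean_apd90,
                "acute_status": acute.status,
                "limit_cycle_status": chronic.status,
            })
            r = rows[-1]
            print(f"{label:>24} gf x{f:<4g} rr: base {r['baseline_rr_s']:.3f}"
                  f"  acute {r['acute_rr_s']:.3f}"
                  f"  limit-cycle {r['limit_cycle_rr_s']:.3f}")
    OUT.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(OUT / "acute_effects.csv", index=False)
    print(f"wrote {OUT / 'acute_effects.csv'}")


if __name__ == "__main__":
    main()
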