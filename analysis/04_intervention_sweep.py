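"""The full intervention sweep: g_f scaling plus the three compound grids.

One row per (model variant, intervention): 10 g_f factors and 4 set points
per compound profile, 22 rows per model, under limit-cycle conditions.
Writes results/interventions.csv.  With --substituted the three I_f-modified
hosts are swept as well.  The scaled-down protocol is the default; the full
5000 s protocol takes hours on one CPU.
"""

from __future__ import annotations

import argparse
import pathlib

from hipsc_ap.ifcurrent import substitute_if
from hipsc_ap.parameters import load_parameters
from hipsc_ap.protocols import (
    FULL_PROTOCOL,
    ProtocolConfig,
    SCALED_DOWN_PROTOCOL,
    run_intervention_set,
    standard_interventions,
)

OUT = pathlib.Path("results")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--full", action="store_true")
    parser.add_argument("--quick", action="store_true",
                        help="120 s / 60 s smoke-test durations")
    parser.add_argument("--substituted", action="store_true",
                        help="also sweep the I_f-substituted Paci2018 hosts")
    parser.add_argument("--family", default=None,
                        help="restrict to one intervention family, e.g. gf_sweep")
    args = parser.parse_args()
    if args.quick:
        config = ProtocolConfig(pre_duration=120.0, post_duration=120.0,
                                analysis_window=60.0, scaled_down=True)
    elif args.full:
        config = FULL_PROTOCOL
    else:
        config = SCALED_DOWN_PROTOCOL

    variants = {v: load_parameters(v) for v in ("paci2017", "paci2018")}
    if args.substituted:
        p18, y18 = variants["paci2018"]
        for name in ("severi2012", "fabbri2017", "koivumaki2018"):
            variants[f"paci2018+{name}"] = (substitute_if(p18, name), y18)

    interventions = standard_interventions()
    if args.family:
        interventions = [i for i in interventions if i["family"] == args.family]

    table, _ = run_intervention_set(variants, interventions, config)
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "interventions.csv", index=False)
    cols = ["model", "intervention", "concentration_uM", "rr_s", "apd90_s", "status"]
    print(table[cols].round(4).to_string(index=False))
    print(f"wrote {OUT / 'interventions.csv'}")


if __name__ == "__main__":
    main()
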