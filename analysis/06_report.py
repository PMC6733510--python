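"""Direction-of-effect verdicts and rr-vs-APD90 figures from a sweep table.

Reads results/interventions.csv (from 04_intervention_sweep.py), classifies
each intervention's rr/APD90 direction against the transcribed experimental
expectations, and exports the verdict summary plus one scatter per model with
the surrogate reference bands.
"""

from __future__ import annotations

import argparse
import pathlib

import pandas as pd

from hipsc_ap.reporting import classify_directions, export_results
from hipsc_ap.synthetic import surrogate_reference

OUT = pathlib.Path("results")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--table", type=pathlib.Path,
                        default=OUT / "interventions.csv")
    args = parser.parse_args()
    table = pd.read_csv(args.table)

    baseline = {}
    for model in table["model"].unique():
        near = table[(table["model"] == model)
                     & (table["intervention"].isin(("gf_x0.99", "gf_x1.01")))]
        if not len(near):
            raise SystemExit(f"no near-identity rows to anchor {model} baseline; "
                             "run the sweep with the gf_sweep family included")
        baseline[model] = (near["rr_s"].mean(), near["apd90_s"].mean())

    verdicts = classify_directions(table, baseline)
    ref = surrogate_reference("rate_modulation")
    paths = export_results(table, verdicts, ref, outdir=OUT, stem="report")
    matched = sum(1 for v in verdicts if v.matches_experiment)
    judged = sum(1 for v in verdicts if v.matches_experiment is not None)
    print(f"{judged} interventions judged against experimental directions; "
          f"{matched} match, {judged - matched} disagree")
    for key, path in paths.items():
        print(f"  {key}: {path}")


if __name__ == "__main__":
    main()
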