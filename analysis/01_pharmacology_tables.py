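"""Rebuild the compound scale-factor tables from IC50 / Hill-slope data.

For Diltiazem and the first Moxifloxacin profile the primary-target fractions
are the set points and the concentrations are derived; the alternative
Moxifloxacin profile is evaluated at the shared concentration series.  Writes
results/pharmacology_tables.csv and prints the tables.
"""

from __future__ import annotations

import pathlib

import pandas as pd

from hipsc_ap.pharmacology import (
    build_scaling,
    build_scaling_at_concentration,
    profile_grid,
)

OUT = pathlib.Path("results")


def main() -> None:
    rows = []
    for key in ("diltiazem_I", "moxifloxacin_II", "moxifloxacin_III"):
        profile, grid = profile_grid(key)
        for mode, value in grid:
            if mode == "fraction":
                scaling, conc = build_scaling(profile, value)
            else:
                scaling, conc = build_scaling_at_concentration(profile, value), value
            row = {"profile": key, "compound": profile.compound,
                   "concentration_uM": conc}
            row.update({f"scale_{k}": v for k, v in scaling.items()})
            rows.append(row)
    table = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "pharmacology_tables.csv", index=False)
    with pd.option_context("display.width", 120):
        print(table.round(4).to_string(index=False))
    print(f"\nwrote {OUT / 'pharmacology_tables.csv'}")


if __name__ == "__main__":
    main()
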