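"""Side-by-side comparison of the two bilayers.

Runs the full pipeline on each system and tabulates the headline numbers
with DPPC/POPE ratios: diffusion coefficients, moduli balance,
interaction counts, thickness and penetration depth.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, SPECS, config_for  # noqa: E402

from memdyn.pipeline import ANALYSES, compare_runs, run  # noqa: E402


def main():
    reports = {}
    for lipid in SPECS:
        out = RESULTS / "07_compare" / lipid
        reports[lipid] = run(config_for(lipid, out, ANALYSES))
        if reports[lipid].errors:
            print(f"warning — {lipid} stage errors: {reports[lipid].errors}")
    table = compare_runs(reports["dppc"], reports["pope"])
    table = table.rename(columns={"a": "dppc", "b": "pope",
                                  "ratio_a_over_b": "dppc_over_pope"})
    table.to_csv(RESULTS / "07_compare" / "headline_comparison.csv",
                 index=False)
    with open(RESULTS / "07_compare" / "headline_comparison.txt", "w") as fh:
        fh.write(table.to_string(index=False) + "\n")
    print(table.to_string(index=False))
    d_ratio = table.loc[table["key"] == "D_alpha_A2ns_contact",
                        "dppc_over_pope"]
    if len(d_ratio):
        print(f"\nContact-leaflet D_alpha is {float(d_ratio.iloc[0]):.1f}x "
              "larger for the DPPC-like bilayer — the planted 2x contrast "
              "recovered up to fluctuation-offset bias.")


if __name__ == "__main__":
    main()
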