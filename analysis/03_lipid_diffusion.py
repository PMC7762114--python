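"""Per-leaflet lipid MSD and anomalous-diffusion fits for both bilayers.

Levels jump artefacts, computes the fixed-origin MSD of lipid geometric
centers separately for the protein-facing (contact) and opposite
(noncontact) leaflets, fits MSD = 6 D_alpha t^alpha, and tabulates
(alpha, D_alpha) per bilayer and leaflet next to the generator's planted
values.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, SPECS, config_for  # noqa: E402

import pandas as pd  # noqa: E402

from memdyn.pipeline import run  # noqa: E402


def main():
    rows = []
    for lipid, make in SPECS.items():
        out = RESULTS / "03_diffusion" / lipid
        report = run(config_for(lipid, out, ["msd"]))
        if report.errors:
            raise SystemExit(f"{lipid}: stage errors {report.errors}")
        fits = json.loads((out / "msd_fits.json").read_text())
        spec = make()
        for leaflet, fit in fits.items():
            rows.append({
                "bilayer": lipid.upper(), "leaflet": leaflet,
                "alpha_fit": round(fit["alpha"], 3),
                "alpha_true": spec.leaflet_alpha[leaflet],
                "D_fit_A2ns": round(fit["D_alpha_A2ns"], 3),
                "D_true_A2ns": spec.leaflet_D[leaflet],
                "D_fit_cm2s": f"{fit['D_alpha_cm2s']:.3e}",
            })
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "03_diffusion" / "fit_summary.csv", index=False)
    print(table.to_string(index=False))
    print("\nNote: fitted alpha sits below the planted exponent because the "
          "geometric centers carry intramolecular fluctuation noise on top "
          "of the planted fractional Brownian motion — a constant MSD "
          "offset that flattens the log-log slope, exactly as for centers "
          "computed from real trajectories.")


if __name__ == "__main__":
    main()
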