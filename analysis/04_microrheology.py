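"""Viscoelastic moduli of both bilayers from the fitted MSD power laws.

Applies the generalized Stokes–Einstein relation with the mean lipid
radius of gyration as probe radius, writes per-leaflet G'(omega) and
G''(omega) tables, and renders the conventional log-log figure (storage
modulus as dots, loss modulus as crosses).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, SPECS, config_for  # noqa: E402

import matplotlib  # noqa: E402

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

from memdyn.pipeline import run  # noqa: E402


def main():
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    for ax, lipid in zip(axes, SPECS):
        out = RESULTS / "04_rheology" / lipid
        report = run(config_for(lipid, out, ["msd", "rheology"]))
        if report.errors:
            raise SystemExit(f"{lipid}: stage errors {report.errors}")
        rg = report.headline["lipid_Rg_A"]
        print(f"{lipid.upper()}: probe radius Rg = {rg:.2f} A")
        for leaflet, style in (("contact", "tab:blue"),
                               ("noncontact", "tab:orange")):
            df = pd.read_csv(out / f"moduli_{leaflet}.csv")
            ax.loglog(df["omega_per_ns"], df["Gprime_kPa"], ".",
                      color=style, label=f"G' {leaflet}")
            ax.loglog(df["omega_per_ns"], df["Gdoubleprime_kPa"], "x",
                      color=style, label=f"G'' {leaflet}")
            ratio = (df["Gprime_kPa"] / df["Gdoubleprime_kPa"]).iloc[0]
            print(f"  {leaflet}: G'/G'' = {ratio:.2f} "
                  f"(elastic response {'dominates' if ratio > 1 else 'is dominated'})")
        ax.set_title(f"{lipid.upper()}-like bilayer")
        ax.set_xlabel("omega (1/ns)")
    axes[0].set_ylabel("modulus (kPa)")
    axes[0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(RESULTS / "04_rheology" / "moduli.png", dpi=120)
    print(f"figure: {RESULTS / '04_rheology' / 'moduli.png'}")


if __name__ == "__main__":
    main()
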