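"""Build the two synthetic bilayer+protein systems and record ground truth.

Writes each system's composition and planted dynamical parameters to JSON
and a small multi-model PDB sample (reduced copy of the DPPC-like system)
demonstrating the on-disk exchange format.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, SPECS  # noqa: E402

import dataclasses  # noqa: E402

from memdyn.pdbio import write_multimodel_pdb  # noqa: E402
from memdyn.synthetic import (generate_topology, generate_trajectory,  # noqa: E402
                              ground_truth_dict)


def main():
    out = RESULTS / "01_systems"
    out.mkdir(parents=True, exist_ok=True)
    for lipid, make in SPECS.items():
        spec = make()
        top = generate_topology(spec)
        lipids = top.molecules("lipid")
        summary = ground_truth_dict(spec, top)
        del summary["leaflet_of_molecule"]        # bulky; counts suffice here
        summary["atoms_total"] = top.n_atoms
        summary["atoms_per_lipid"] = len(top.molecule_atoms(lipids[0]))
        summary["n_waters"] = len(top.molecules("water"))
        summary["n_ions"] = len(top.molecules("ion"))
        with open(out / f"{lipid}_ground_truth.json", "w") as fh:
            json.dump(summary, fh, indent=1)
        print(f"{lipid.upper()}-like system: {len(lipids)} lipids x "
              f"{summary['atoms_per_lipid']} atoms, {top.n_atoms} atoms total,"
              f" {spec.n_frames} frames planned")

    # small format sample: 2 lipids/leaflet, 3 frames
    sample = dataclasses.replace(
        SPECS["dppc"](), n_lipids_per_leaflet=2, n_frames=3, n_waters=10,
        n_cations=2, n_anions=2, dtype="float64")
    top = generate_topology(sample)
    traj = generate_trajectory(top, sample)
    write_multimodel_pdb(out / "sample_dppc.pdb", top, traj)
    print(f"wrote format sample {out / 'sample_dppc.pdb'} "
          f"({traj.n_frames} MODELs, {top.n_atoms} atoms)")


if __name__ == "__main__":
    main()
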