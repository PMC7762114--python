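"""Shared study conditions for the numbered analysis scripts.

Two bilayer systems mirror the studied pair: a saturated-chain
phosphatidylcholine (DPPC-like) bilayer and an unsaturated-chain
phosphatidylethanolamine (POPE-like) bilayer, each with 144 lipids per
leaflet in a 95 × 86 × 196 Å box at 310 K, a protein probe bound to the
upper (contact) leaflet, waters and NaCl.  Per-leaflet anomalous-diffusion
parameters follow the measured sub-diffusive exponents for each bilayer;
the generalized diffusion coefficients use the package's documented
defaults (DPPC ≈ 2× POPE, contact > noncontact for DPPC).

Trajectories are 250 frames at 0.05 ns (12.5 ns at the 20 frames/ns saving
rate); every script regenerates them deterministically from the seed, so
nothing large needs to be stored on disk.
"""

from pathlib import Path

from memdyn.pipeline import RunConfig
from memdyn.synthetic import SyntheticSpec

RESULTS = Path(__file__).resolve().parent.parent / "results"
TEMPERATURE = 310.0
SEED = 2020
N_FRAMES = 250


def dppc_spec(seed: int = SEED) -> SyntheticSpec:
    return SyntheticSpec(
        lipid_template="DPPC",
        leaflet_alpha={"contact": 0.105, "noncontact": 0.127},
        leaflet_D={"contact": 0.6, "noncontact": 0.3},
        n_frames=N_FRAMES, n_waters=600, protein_insertion=6.0,
        rng_seed=seed, dtype="float32")


def pope_spec(seed: int = SEED) -> SyntheticSpec:
    return SyntheticSpec(
        lipid_template="POPE",
        leaflet_alpha={"contact": 0.300, "noncontact": 0.244},
        leaflet_D={"contact": 0.3, "noncontact": 0.15},
        n_frames=N_FRAMES, n_waters=600, protein_insertion=3.0,
        rng_seed=seed, dtype="float32")


SPECS = {"dppc": dppc_spec, "pope": pope_spec}


def config_for(lipid: str, outdir: Path, analyses) -> RunConfig:
    return RunConfig(
        synthetic=SPECS[lipid](), outdir=str(outdir), seed=SEED,
        analyses=tuple(analyses), temperature=TEMPERATURE,
        interaction_stride=50, entropy_points=10, entropy_max_molecules=16)
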