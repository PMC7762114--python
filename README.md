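# memdyn — protein–membrane trajectory analysis

`memdyn` analyzes molecular-dynamics trajectories of a peripheral protein
bound to a phospholipid bilayer — the setting of β2-glycoprotein-1 binding
to DPPC or POPE membranes — and characterizes both the binding and the
membrane's response:

* **Interaction mapping** — per-frame detection of hydrogen bonds
  (energy criterion: E > 25% of a 25 kJ/mol optimum, i.e. strictly above
  6.25 kJ/mol), hydrophobic (HP) contacts, ionic interactions, and water
  bridges (a water H-bonded to two distinct molecules); time series and
  residue × lipid-atom count maps.
* **Anomalous lipid diffusion** — fixed-origin mean squared displacement of
  lipid geometric centers per leaflet,
  MSD(t) = (1/N) Σᵢ |rᵢ(t) − rᵢ(0)|², fitted to MSD = 6 D_α t^α.
* **Passive microrheology** — the generalized Stokes–Einstein relation
  |G*|(ω) ≈ k_B T / (π R_g MSD(1/ω) Γ[1+α(ω)]), with
  G′ = |G*| cos(πα/2), G″ = |G*| sin(πα/2) and the mean lipid radius of
  gyration R_g as probe radius.
* **Schlitter conformational entropy** —
  S = k_B ln det(1 + (k_B T e²/ħ²) M^½ σ M^½) from the n×n atom covariance
  σ estimated from mean-subtracted, concatenated x/y/z coordinate series
  (F frames → 3F realizations), as an entropy-vs-time curve averaged over
  contact-leaflet lipids.
* **Membrane profiles** — electron density along the bilayer normal,
  peak-to-peak bilayer thickness, interior water counts, and protein
  penetration depth past the contact-leaflet phosphorus plane.
* **Artefact repair** — automatic detection and leveling of box-length
  molecule jumps that some simulation engines write into saved
  trajectories.

Because real protein–membrane MD trajectories are rarely shared, the
package ships a first-class synthetic generator: a planar two-leaflet
bilayer (DPPC-like 130-atom or POPE-like 125-atom lipids, 144 per leaflet
by default), a typed coarse protein probe, waters and ions, where lipid
centers follow exact fractional Brownian motion with chosen per-leaflet
(α, D_α), intramolecular fluctuations are Gaussian with a prescribed
covariance, and contacts can be planted with geometry strictly inside or
outside the detection thresholds.  Every analysis stage is therefore
testable against analytic ground truth.

## Worked example

```python
import numpy as np
from memdyn import (SyntheticSpec, generate_topology, generate_trajectory,
                    leaflet_msd_fits, radius_of_gyration, gser_moduli)

spec = SyntheticSpec(n_lipids_per_leaflet=144, lipid_template="DPPC",
                     leaflet_alpha={"contact": 0.105, "noncontact": 0.127},
                     leaflet_D={"contact": 0.6, "noncontact": 0.3},
                     n_frames=250, rng_seed=2020, dtype="float32")
top = generate_topology(spec)
traj = generate_trajectory(top, spec)

fits = leaflet_msd_fits(traj, top)
for leaflet, (msd, fit) in fits.items():
    print(leaflet, round(fit.alpha, 3), round(fit.d_alpha, 3))

rg, _ = radius_of_gyration(traj, top, "lipid")
moduli = gser_moduli(fits["contact"][1], temperature=310.0, probe_radius=rg,
                     omega=[1.0])
ratio = moduli.g_prime_kpa[0] / moduli.g_double_prime_kpa[0]
print("Rg", round(rg, 2), "G'/G''", round(ratio, 2))
```

prints

```
contact 0.08 0.829
noncontact 0.074 0.552
Rg 6.67 G'/G'' 7.94
```

Both leaflets come out strongly sub-diffusive (α ≪ 1) with the contact
leaflet's generalized diffusion coefficient larger, and the storage
modulus dominates the loss modulus (G′/G″ ≈ 8) — a confined, elastic
membrane environment.  The fitted α sits below the planted exponents
because the geometric centers also carry intramolecular fluctuation
noise, which adds a constant MSD offset; the same bias affects centers
computed from real trajectories.

The numbered drivers under `analysis/` run the full study — system
construction, interaction mapping, diffusion, microrheology, entropy,
membrane profiles, and a DPPC-vs-POPE comparison — writing their tables
under `results/`:

```sh
python analysis/01_simulate_bilayers.py
python analysis/02_interaction_mapping.py
...
python analysis/07_compare_bilayers.py
```

A thin CLI wraps the same pipeline: `memdyn run-all --config cfg.json`,
plus per-analysis subcommands (`simulate`, `interactions`, `msd`,
`rheology`, `entropy`, `profiles`, `compare`).

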