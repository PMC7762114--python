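# Methods

This note documents the models implemented in `memdyn`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
validation does and does not establish about real data.

## Trajectory model and units

A trajectory is an ordered stack of Cartesian frames in Å with timestamps
in ns and a constant orthorhombic box (Lx, Ly, Lz).  Internal units are
Å / ns / amu / K, with kJ/mol for interaction energies; SI constants
(k_B = 1.380649×10⁻²³ J/K, ħ = 1.054571817×10⁻³⁴ J·s,
R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹) enter only inside the entropy and
rheology formulas.  Files are exchanged as multi-model PDB
(MODEL/ENDMDL, CRYST1); since PDB stores no timestamps, the reader
synthesizes times from a frame interval (default 0.05 ns, i.e. 20 frames
per ns — the saving rate of a 50 ns run at a 2 fs step with one frame per
25,000 steps).  Triclinic boxes are not supported.

### Atom typing

Typing is table-driven by residue and atom name: H-bond donors (heavy
atoms with a polar hydrogen), acceptors (O/N with lone pairs, including
the lipid phosphate oxygens O13/O14 and ester/carbonyl oxygens),
hydrophobic atoms (carbons with no covalent bond to N/O/P — the acyl tail
carbons), and a formal charge class (+1 Lys-NZ, choline/ethanolamine N,
Na⁺/K⁺; −1 Asp-OD, phosphate O13/O14, Cl⁻).  Unknown residues fall back
to all-neutral typing with a logged warning.  Tables are exportable and
loadable as JSON.  Hydrogens are associated to their covalent heavy atom
by nearest-neighbor distance within the residue, judged on the mean
structure of the first frames so random fluctuations cannot flip the
assignment.

### Jump leveling

Simulation engines occasionally translate a whole molecule by one box
length between consecutive saved frames.  The repair compares each
molecule's center between consecutive frames and, when a per-axis
displacement exceeds L/2, shifts the trailing trajectory by the integer
multiple of L that minimizes it.  Consecutive-frame detection (rather
than deviation from the first frame only) handles multiple and opposing
jumps and makes the operation idempotent; molecules are shifted whole.
This assumes genuine inter-frame motion stays below half a box length,
which holds by orders of magnitude at these saving rates.

## Interaction detection

* **Hydrogen bonds.**  The energy of a donor–H···acceptor triple is
  modeled as a product of two clamped linear ramps scaled to a 25 kJ/mol
  optimum: full strength for H···A ≤ 2.1 Å falling to zero at 2.6 Å, and
  zero at a donor angle of 100° rising to full at 180°.  A bond is
  counted when the energy strictly exceeds 25% of the optimum
  (6.25 kJ/mol).  The product form is continuous and monotone in both
  arguments and reproduces the threshold semantics of the energy-based
  criterion used by MD analysis engines; the exact published functional
  form of those engines is proprietary, so the ramp constants are exposed
  in `InteractionParams`.  A donor may form several simultaneous bonds
  (no best-acceptor pruning); acceptor = donor is excluded.
* **HP contacts.**  Pairs of hydrophobic atoms from different residues
  within 5.0 Å (a conventional hydrophobic-contact radius; configurable).
  Heavy atoms only.
* **Ionic interactions.**  Oppositely charge-classed atoms within 5.0 Å,
  excluding pairs within one residue (a zwitterionic headgroup's own
  N⁺/phosphate-O⁻ pair is permanent structure, not an interaction);
  records note whether a solvent ion participates.
* **Water bridges.**  A water simultaneously H-bonded — as donor or
  acceptor — to atoms of two distinct non-water molecules; one record per
  (water, unordered partner-atom pair).

Neighbor searches use periodic KD-trees; correctness is enforced by tests
against exhaustive O(n²)/O(n³) enumeration with a 27-image minimum-image
oracle.  Counts aggregate into labeled matrices (protein residue ×
lipid-atom name, or lipid-atom × lipid-atom for bridges) and per-frame
time series with participating-lipid statistics.  Scope labels follow
the field's usage for this system: protein↔lipid contacts are the
"intermolecular" ones, while lipid–lipid contacts are reported under a
bilayer-internal label.

## Lipid dynamics

MSD is the fixed-origin ensemble average over molecule geometric centers
(unweighted atom mean, hydrogens included); a multi-origin sliding-window
variant exists behind a flag but is not the default, because the
fixed-origin definition is what the anomalous-diffusion fit targets.
Leaflets are assigned at frame 0 by center-z against the bilayer midplane;
the leaflet whose mean phosphorus plane is nearer the protein's geometric
center is the "contact" leaflet (lipid flip-flop is negligible on these
time scales).  The power law MSD = 6 D_α t^α is fitted by ordinary least
squares in log–log space over all positive lags excluding the first saved
frame (configurable); parameter uncertainties come from the linear-fit
covariance, and D_α is reported in both Å²/ns^α and cm²/s^α
(D[cm²/s^α] = D[Å²/ns^α] × 10⁻¹⁶/10⁻⁹ᵅ).  The 3D form with the 6-prefactor
is the default; a lateral 4 D_α mode is available.

Caveat made explicit by the synthetic study: geometric centers of
flexible molecules carry conformational noise on top of center-of-mass
transport.  This adds a near-constant offset to the fixed-origin MSD and
biases the fitted α downward when the transport amplitude is comparable
to the fluctuation amplitude (visible in `analysis/03`, where planted
α = 0.105/0.127 fit as ≈ 0.07–0.08).  Parameter-recovery accuracy is
therefore certified on fluctuation-free center ensembles (bias ≤ 0.05 at
288 molecules × 1000 frames), which isolates generator and fit
correctness from this estimator property.

## Microrheology

The generalized Stokes–Einstein relation is evaluated in its
local-power-law approximation: |G*|(ω) = k_B T /(π R_g MSD(1/ω) Γ[1+α(ω)])
with α(ω) the logarithmic slope of the MSD at t = 1/ω, and
G′ = |G*| cos(πα/2), G″ = |G*| sin(πα/2).  The default pipeline evaluates
it on the fitted power law (α constant), matching how fitted MSD functions
are used in practice; tabulated MSD input uses log–log interpolation with
central differences.  Each lipid is approximated as a sphere of radius
R_g, the mass-weighted mean lipid radius of gyration.  Moduli are
reported in kPa; the ω grid defaults to 40 log-spaced points spanning the
inverse fitted time range.  The approximation requires α(ω) ∈ (0, 2) and
is exact for pure power laws (checked against an arbitrary-precision
evaluation and the α = 1 and α = ½ closed forms).

## Schlitter entropy

For one molecule, each atom's x/y/z series are mean-subtracted per
coordinate and concatenated (F frames → 3F realizations per atom); the
n×n covariance σ averages products of these series.  The entropy bound is
S = k_B ln det(1 + (k_B T e²/ħ²) M^½ σ M^½), evaluated in the log-domain
over eigenvalues of the symmetrically mass-weighted matrix (determinant
identical to M σ for diagonal M, numerically stabler).  Two conventions
deliberately co-exist: the default omits the conventional ½ prefactor of
Schlitter's original bound (matching how membrane entropy-vs-time curves
are often reported, where only the curve shape matters), and
`half_prefactor=True` restores the textbook form.
The identity addition keeps the determinant finite when few frames make σ
singular; negative eigenvalues beyond numerical tolerance are clamped to
zero with a warning, so S ≥ 0 always.  Entropy-vs-time curves use
cumulative windows [0, t] and average over the contact-leaflet lipids;
coordinates are not centered by default (removing overall translation is
optional), accepting the known overestimation in exchange for matching
the curve-shape use of the quantity.  Gaussianity diagnostics (pairwise
correlations of the concatenated series, per-atom histograms) are
provided because the bound assumes Gaussian fluctuations.

## Membrane profiles

Electron density assigns each atom its atomic number of electrons to a
1 Å z-bin (point assignment, no Gaussian spreading), normalized by
Lx·Ly·bin volume and averaged over a frame window, per component (lipid,
water, protein, ion).  Bilayer thickness is the peak-to-peak distance of
the lipid density, taking the highest peak on each side of the lipid
density centroid — robust to interior bumps from interdigitating tails.
Penetration depth per frame is the distance of the deepest protein atom
past the contact-leaflet phosphorus plane toward the bilayer center
(never negative), with the owning residue reported; the phosphorus plane
is the reference because P atoms define the head plane in both lipids.
Interior waters are water oxygens strictly between the two headgroup peak
planes.

## The synthetic generator

The generator emulates the study system — 144 lipids per leaflet in a
95 × 86 × 196 Å box, DPPC-like (130-atom) or POPE-like (125-atom) lipids
with PDB-style head-atom names (P, N, O11–O14, O21/O22, O31/O32,
C11/C12, tail carbons C2x/C3x), a typed coarse protein, waters, and
monovalent ions — while keeping every statistic analytically known:

* **Center transport**: independent 3D fractional Brownian motion per
  lipid with per-leaflet (α, D_α), sampled exactly via Cholesky
  factorization of the fractional-Gaussian-noise covariance, so the
  ensemble MSD is exactly 6 D_α t^α at any length the factorization can
  handle (thousands of frames).  The exact sampler, rather than an
  approximate spectral one, is what lets recovery tests attribute any fit
  bias to the estimator instead of the generator.
* **Internal fluctuations**: Gaussian with a prescribed PSD atom
  covariance, drawn independently per Cartesian axis so the concatenated
  x/y/z covariance estimator targets it directly.  The default covariance
  has head-atom variance 0.2 Å², tail variance 0.5 Å², correlations
  decaying as exp(−d/15 Å) over the template geometry, and hydrogens
  rigidly co-moving with their parent heavy atoms.  Compact headgroups
  thus fluctuate more coherently than extended tails, reproducing the
  head-rigidity seen in real bilayers while keeping bonded geometry
  approximately intact.
* **Leaflet geometry**: planar z-slabs with a configurable
  phosphorus-plane separation (default 40 Å, the head-to-head distance of
  the studied bilayers) and jittered-grid lateral packing; each lipid is
  anchored at its P atom.
* **Planted contacts**: each planted H-bond, HP pair, ionic pair or water
  bridge is relocated to a verified clash-free site (≥ 7 Å from all other
  atoms, sites ≥ 14 Å apart) and frozen in every frame with geometry
  strictly inside or outside the thresholds, so planted counts are exact
  ground truth.  A planted water bridge necessarily contributes two
  genuine water H-bond records.
* **Artefacts**: whole-molecule ±L jumps can be injected at chosen frames
  to exercise the leveling repair.

Default per-leaflet transport parameters follow the measured sub-diffusive
exponents of the studied bilayers (DPPC ≈ 0.105/0.127,
POPE ≈ 0.300/0.244 for contact/noncontact); the D_α magnitudes
(0.6/0.3 Å²/ns^α for DPPC, half that for POPE) are chosen once as
realistic orders of magnitude consistent with the qualitative findings
(DPPC ≈ 2× POPE; contact > noncontact), since no numeric D_α values are
available to copy.  Waters and ions are static scenery; there is no
force field, thermostat, or water dynamics.

**What passing tests show — and don't.**  The synthetic systems certify
algorithmic correctness: detectors equal brute-force enumeration, planted
truth is recovered exactly, the MSD/fit machinery is unbiased on exact
fBm, the entropy estimator converges to closed forms, and profiles
recover constructed geometry.  They do not certify force-field realism:
lipid conformations are schematic (zigzag chains, compact stacked heads),
solvent is static, the protein is a rigid typed cluster, and absolute
values of entropy plateaus, moduli, thickness or contact counts on
synthetic systems are properties of the generator's defaults, not
predictions for real membranes.  On full-atom synthetic bilayers the
electron-density headgroup peaks sit ~3 Å inside the constructed P-planes
(the phosphate/glycerol band dominates), so peak-to-peak thickness reads
a few Å below the P–P distance — as it does for real bilayers.

## Problem sizes

The analysis drivers run 288 lipids × 250 frames (12.5 ns at 20
frames/ns) in float32, which resolves every qualitative contrast the
study design plants; the acceptance script uses the full 1000-frame
bookkeeping wherever the quantity is about bookkeeping (covariance
realizations, sampling arithmetic) and 288 × 1000 × 5-seed ensembles for
parameter recovery.  An end-to-end 288-lipid run completes in well under
a minute per bilayer on one CPU.

## Known limitations

* Orthorhombic, constant boxes only; no DCD/XTC/TRR readers.
* The H-bond energy's acceptor-geometry factor is a configuration hook
  left off by default; published engine formulas differ in this term.
* Fixed-origin MSD of flexible-molecule centers carries the
  conformational-offset bias discussed above.
* Secondary-structure assignment, force-field energetics, and absolute
  free energies are out of scope.
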