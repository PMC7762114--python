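"""Synthetic bilayer+protein systems with known ground truth.

The generator emulates the study system — a planar two-leaflet phospholipid
bilayer (144 lipids per leaflet by default), a multi-residue protein probe
hovering over one leaflet, explicit waters and monovalent ions — while
keeping every statistical property analytically known:

* lipid geometric centers follow exact 3D fractional Brownian motion with
  per-leaflet ``(alpha, D_alpha)`` so the ensemble MSD is ``6 D t**alpha``;
* intramolecular fluctuations are Gaussian with a prescribed
  positive-semidefinite atom covariance (Å²), independently per Cartesian
  axis, so covariance/entropy estimators have a closed-form target;
* interactions (H-bonds, hydrophobic contacts, ionic pairs, water bridges)
  can be planted with geometry strictly inside or outside the detection
  thresholds;
* whole-molecule box-length jump artefacts can be injected for testing the
  jump-leveling repair.

Waters and ions are static scenery: no solvent dynamics is modelled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import atomtypes
from .constants import element_atomic_number, element_mass
from .core import Topology, Trajectory
from .fbm import fgn_cholesky, sample_fbm_paths
from .lipid_templates import LipidTemplate, lipid_template
from .pbc import wrap_coordinates

#: default protein fragment: residue numbers follow the membrane-binding
#: region convention of the study protein (fifth domain numbering).
DEFAULT_PROTEIN_RESIDUES = (
    (300, "THR"), (301, "LYS"), (302, "GLY"), (303, "SER"), (304, "LEU"),
    (305, "LYS"), (306, "ALA"), (307, "TRP"), (308, "TYR"), (309, "GLY"),
    (310, "ASP"), (311, "SER"), (312, "SER"), (313, "LEU"), (314, "ALA"),
    (315, "PHE"), (316, "THR"), (317, "TRP"), (318, "THR"), (319, "GLY"),
)

# side-chain atoms: (name, element, n_hydrogens) per residue, backbone first
_BACKBONE_ATOMS = (("N", "N", 1), ("CA", "C", 1), ("C", "C", 0), ("O", "O", 0))
_SIDE_ATOMS = {
    "GLY": (),
    "ALA": (("CB", "C", 3),),
    "LEU": (("CB", "C", 2), ("CG", "C", 1), ("CD1", "C", 3), ("CD2", "C", 3)),
    "PHE": (("CB", "C", 2), ("CG", "C", 0), ("CD1", "C", 1), ("CD2", "C", 1),
            ("CE1", "C", 1), ("CE2", "C", 1), ("CZ", "C", 1)),
    "TRP": (("CB", "C", 2), ("CG", "C", 0), ("CD1", "C", 1), ("NE1", "N", 1),
            ("CD2", "C", 0), ("CE2", "C", 0), ("CE3", "C", 1),
            ("CZ2", "C", 1), ("CZ3", "C", 1), ("CH2", "C", 1)),
    "SER": (("CB", "C", 2), ("OG", "O", 1)),
    "THR": (("CB", "C", 1), ("OG1", "O", 1), ("CG2", "C", 3)),
    "TYR": (("CB", "C", 2), ("CG", "C", 0), ("CD1", "C", 1), ("CD2", "C", 1),
            ("CE1", "C", 1), ("CE2", "C", 1), ("CZ", "C", 0), ("OH", "O", 1)),
    "ASP": (("CB", "C", 2), ("CG", "C", 0), ("OD1", "O", 0), ("OD2", "O", 0)),
    "LYS": (("CB", "C", 2), ("CG", "C", 2), ("CD", "C", 2), ("CE", "C", 2),
            ("NZ", "N", 3)),
}


@dataclass
class PlantedContact:
    """A contact planted with geometry inside or outside detection thresholds.

    ``partner_a`` / ``partner_b`` are ``(molecule_id, atom_name)`` selectors.
    For H-bonds ``partner_a`` is the donor heavy atom and ``partner_b`` the
    acceptor; for water bridges ``water`` names the bridging water molecule
    and both partners are acceptor atoms of distinct non-water molecules.
    ``geometry`` overrides the default placement (keys: ``d_ha``,
    ``theta_deg`` for H-bond-like kinds; ``distance`` for hp/ionic).
    """

    kind: str
    partner_a: tuple
    partner_b: tuple
    water: int | None = None
    geometry: dict = field(default_factory=dict)
    expected_detected: bool = True

    def __post_init__(self):
        if self.kind not in ("hbond", "hp", "ionic", "water_bridge"):
            raise ValueError(f"unknown contact kind {self.kind!r}")
        if self.kind == "water_bridge" and self.water is None:
            raise ValueError("water_bridge requires a water molecule id")


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic bilayer+protein system.

    Defaults reproduce the study conditions: 144 DPPC-like lipids per
    leaflet in a 95 × 86 × 196 Å box, 1000 frames saved every 0.05 ns
    (20 frames/ns over 50 ns), sub-diffusive leaflet dynamics with the
    contact leaflet distinguished from the noncontact one.
    """

    n_lipids_per_leaflet: int = 144
    lipid_template: str = "DPPC"
    minimal_atoms: int = 12
    leaflet_alpha: dict = field(
        default_factory=lambda: {"contact": 0.105, "noncontact": 0.127})
    leaflet_D: dict = field(
        default_factory=lambda: {"contact": 0.6, "noncontact": 0.3})
    internal_covariance: np.ndarray | None = None
    head_variance: float = 0.2      # Å², used when no covariance given
    tail_variance: float = 0.5
    correlation_length: float = 15.0  # Å, fluctuation correlation decay
    n_frames: int = 1000
    frame_interval: float = 0.05    # ns
    box: tuple = (95.0, 86.0, 196.0)
    head_to_head: float = 40.0      # Å between leaflet head planes
    rng_seed: int = 0
    include_protein: bool = True
    protein_residues: tuple = DEFAULT_PROTEIN_RESIDUES
    protein_offset: float = 8.0     # Å of protein base above contact plane
    protein_insertion: float = 0.0  # Å the deepest residues dip below it
    n_waters: int = 1000
    n_cations: int = 20
    n_anions: int = 20
    cation: str = "NA"
    planted_interactions: list = field(default_factory=list)
    jump_frames: list = field(default_factory=list)
    wrap: bool = False
    dtype: str = "float64"

    def validate(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be at least 2")
        if self.n_lipids_per_leaflet < 1:
            raise ValueError("need at least one lipid per leaflet")
        for leaflet in ("contact", "noncontact"):
            a = self.leaflet_alpha[leaflet]
            d = self.leaflet_D[leaflet]
            if not 0 < a <= 2:
                raise ValueError("alpha must lie in (0, 2]")
            if d < 0:
                raise ValueError("D must be non-negative")
        if np.any(np.asarray(self.box) <= 0):
            raise ValueError("box lengths must be positive")
        if self.internal_covariance is not None:
            c = np.asarray(self.internal_covariance)
            if c.ndim != 2 or c.shape[0] != c.shape[1]:
                raise ValueError("internal covariance must be square")
            if not np.allclose(c, c.T, atol=1e-10):
                raise ValueError("internal covariance must be symmetric")

    def template(self) -> LipidTemplate:
        return lipid_template(self.lipid_template, self.minimal_atoms)


def default_internal_covariance(template: LipidTemplate,
                                head_variance: float = 0.2,
                                tail_variance: float = 0.5,
                                correlation_length: float = 15.0
                                ) -> np.ndarray:
    """Distance-correlated PSD atom covariance: rigid-ish head, floppier tail.

    Heavy-atom fluctuations have variance ``head_variance`` for head atoms
    and ``tail_variance`` for tail atoms, with pair correlations decaying
    as ``exp(-d_ij / correlation_length)`` over the template geometry (an
    exponential kernel, positive semidefinite by construction).  Nearby
    atoms therefore move almost together — bond geometry is approximately
    preserved — while distant atoms decorrelate; because headgroups are
    spatially compact and tails extended, head coordinates come out more
    correlated than tail coordinates, as seen in real bilayers.  Each
    hydrogen is perfectly correlated with its parent heavy atom (rigid
    X–H bonds): the heavy-atom covariance is expanded through the
    hydrogen-parent map.
    """
    heads = template.head_mask()
    # group leader: heavy atoms lead themselves, hydrogens their parent
    leader = np.array([p if p >= 0 else i
                       for i, p in enumerate(template.h_parent)])
    heavy = np.array([p < 0 for p in template.h_parent])
    idx = np.where(heavy)[0]
    pos = template.offsets[idx]
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2)
    sd = np.where(heads[idx], np.sqrt(head_variance),
                  np.sqrt(tail_variance))
    n = template.n_atoms
    cov_heavy = np.zeros((n, n))
    cov_heavy[np.ix_(idx, idx)] = np.outer(sd, sd) * np.exp(
        -d / correlation_length)
    return cov_heavy[np.ix_(leader, leader)]


def _psd_factor(cov: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Square root of a PSD matrix via eigendecomposition; errors if not PSD."""
    cov = np.asarray(cov, dtype=float)
    if not np.any(cov):
        return np.zeros_like(cov)
    w, v = np.linalg.eigh(0.5 * (cov + cov.T))
    floor = -tol * max(w.max(), 1.0)
    if w.min() < floor:
        raise np.linalg.LinAlgError(
            f"internal covariance not PSD (min eigenvalue {w.min():.3g})")
    return v * np.sqrt(np.clip(w, 0.0, None))


# ---------------------------------------------------------------------------
# system construction


def _protein_atoms(residues, origin, insertion_resids, insertion):
    """Build the coarse protein chain; returns per-atom lists + coordinates."""
    names, elements, h_parent, resnames, resids, coords = [], [], [], [], [], []
    n_cols = max(1, int(np.ceil(np.sqrt(len(residues)))))
    for ridx, (resid, resname) in enumerate(residues):
        resname = resname.upper()
        if resname not in _SIDE_ATOMS:
            raise ValueError(f"unsupported protein residue {resname!r}")
        cx = origin[0] + 9.5 * (ridx % n_cols)
        cy = origin[1] + 9.5 * (ridx // n_cols)
        cz = origin[2]
        if resid in insertion_resids:
            cz -= insertion
        base = len(names)
        atoms = _BACKBONE_ATOMS + _SIDE_ATOMS[resname]
        hz = 0
        for j, (name, element, n_h) in enumerate(atoms):
            heavy_index = len(names)
            names.append(name)
            elements.append(element)
            h_parent.append(-1)
            resnames.append(resname)
            resids.append(resid)
            # backbone across the top; side chain hangs toward -z but stays
            # compact (rings and long chains fold laterally past 5 atoms)
            if j < 4:
                coords.append((cx + 1.4 * j, cy, cz))
            else:
                depth_steps = min(j - 3, 5)
                lateral = 1.3 * max(0, j - 8)
                coords.append((cx + 0.6 * ((j - 4) % 2) + lateral,
                               cy + 1.5, cz - 1.4 * depth_steps))
            h_dirs = ((0.0, -0.62, 0.15), (0.35, 0.5, 0.45),
                      (-0.35, 0.5, 0.45))
            for k in range(n_h):
                names.append(f"H{base + hz}")
                hz += 1
                elements.append("H")
                h_parent.append(heavy_index)
                resnames.append(resname)
                resids.append(resid)
                px, py, pz = coords[heavy_index]
                dx, dy, dz = h_dirs[k]
                coords.append((px + dx, py + dy, pz + dz))
    return names, elements, h_parent, resnames, resids, np.array(coords)


def _build_system(spec: SyntheticSpec):
    """Deterministic reference layout: (Topology, ref_coords, meta)."""
    spec.validate()
    rng = np.random.default_rng([spec.rng_seed, 0])
    box = np.asarray(spec.box, dtype=float)
    template = spec.template()
    nt = template.n_atoms

    names, elements, h_parent = [], [], []
    resnames, resids, mol_ids, chains = [], [], [], []
    coords = []
    molecule_kind = {}
    mol = 0

    z_mid = box[2] / 2.0
    planes = {"upper": z_mid + spec.head_to_head / 2.0,
              "lower": z_mid - spec.head_to_head / 2.0}
    n_side = int(np.ceil(np.sqrt(spec.n_lipids_per_leaflet)))
    dx, dy = box[0] / n_side, box[1] / n_side
    leaflet_of = {}
    lipid_resid = 0
    # anchor each lipid at its phosphorus so head planes are P planes
    p_z = float(template.offsets[template.names.index("P"), 2])
    for leaflet in ("upper", "lower"):
        sign = -1.0 if leaflet == "upper" else 1.0   # tails toward midplane
        for k in range(spec.n_lipids_per_leaflet):
            lipid_resid += 1
            ix, iy = k % n_side, k // n_side
            x0 = (ix + 0.5) * dx + rng.uniform(-0.12 * dx, 0.12 * dx)
            y0 = (iy + 0.5) * dy + rng.uniform(-0.12 * dy, 0.12 * dy)
            offs = template.offsets.copy()
            offs[:, 2] = -sign * (offs[:, 2] - p_z)  # tails toward midplane
            pos = offs + np.array([x0, y0, planes[leaflet]])
            coords.append(pos)
            base_h = len(names)
            names.extend(template.names)
            elements.extend(template.elements)
            h_parent.extend(p + base_h if p >= 0 else -1
                            for p in template.h_parent)
            resnames.extend([template.resname] * nt)
            resids.extend([lipid_resid] * nt)
            mol_ids.extend([mol] * nt)
            chains.extend(["L"] * nt)
            molecule_kind[mol] = "lipid"
            leaflet_of[mol] = leaflet
            mol += 1

    protein_mol = None
    if spec.include_protein and spec.protein_residues:
        n_cols = max(1, int(np.ceil(np.sqrt(len(spec.protein_residues)))))
        width = 9.5 * n_cols
        origin = (box[0] / 2.0 - width / 2.0, box[1] / 2.0 - width / 2.0,
                  planes["upper"] + spec.protein_offset)
        deepest = {r for r, n in spec.protein_residues
                   if n.upper() in ("LEU", "PHE")}
        if not deepest:
            deepest = {spec.protein_residues[len(spec.protein_residues) // 2][0]}
        (p_names, p_el, p_par, p_resn, p_resi,
         p_xyz) = _protein_atoms(spec.protein_residues, origin, set(), 0.0)
        if spec.protein_insertion > 0:
            # sink the designated residues so their deepest atom sits exactly
            # protein_insertion below the contact head plane
            sel = np.isin(p_resi, list(deepest))
            target = planes["upper"] - spec.protein_insertion
            p_xyz[sel, 2] -= p_xyz[sel, 2].min() - target
        base_h = len(names)
        names.extend(p_names)
        elements.extend(p_el)
        h_parent.extend(p + base_h if p >= 0 else -1 for p in p_par)
        resnames.extend(p_resn)
        resids.extend(p_resi)
        mol_ids.extend([mol] * len(p_names))
        chains.extend(["A"] * len(p_names))
        molecule_kind[mol] = "protein"
        coords.append(p_xyz)
        protein_mol = mol
        mol += 1

    # static waters in the two solvent slabs, clear of the protruding heads
    slabs = [(3.0, planes["lower"] - 6.0),
             (planes["upper"] + 6.0, box[2] - 3.0)]
    for w in range(spec.n_waters):
        lo, hi = slabs[w % 2]
        o = np.array([rng.uniform(0, box[0]), rng.uniform(0, box[1]),
                      rng.uniform(lo, hi)])
        base_h = len(names)
        names.extend(["O", "H1", "H2"])
        elements.extend(["O", "H", "H"])
        h_parent.extend([-1, base_h, base_h])
        resnames.extend(["HOH"] * 3)
        resids.extend([w + 1] * 3)
        mol_ids.extend([mol] * 3)
        chains.extend(["W"] * 3)
        molecule_kind[mol] = "water"
        coords.append(np.stack([o, o + (0.96, 0, 0), o + (-0.24, 0.93, 0)]))
        mol += 1

    ion_resid = 0
    for ion_name, count in ((spec.cation.upper(), spec.n_cations),
                            ("CL", spec.n_anions)):
        for _ in range(count):
            ion_resid += 1
            lo, hi = slabs[ion_resid % 2]
            p = np.array([rng.uniform(0, box[0]), rng.uniform(0, box[1]),
                          rng.uniform(lo, hi)])
            names.append(ion_name)
            elements.append(ion_name)
            h_parent.append(-1)
            resnames.append(ion_name)
            resids.append(ion_resid)
            mol_ids.append(mol)
            chains.append("I")
            molecule_kind[mol] = "ion"
            coords.append(p[None, :])
            mol += 1

    names = np.array(names)
    elements = np.array(elements)
    resnames = np.array(resnames)
    is_donor, is_acceptor, is_hydrophobic, charge = atomtypes.classify_atoms(
        names, resnames)
    topology = Topology(
        names=names, elements=elements,
        masses=np.array([element_mass(e) for e in elements]),
        atomic_numbers=np.array([element_atomic_number(e) for e in elements]),
        resnames=resnames, resids=np.array(resids),
        molecule_ids=np.array(mol_ids), chains=np.array(chains),
        molecule_kind=molecule_kind,
        is_donor=is_donor, is_acceptor=is_acceptor,
        is_hydrophobic=is_hydrophobic, charge_class=charge,
        h_parent=np.array(h_parent),
    )
    topology.validate()
    meta = {"leaflet_of": leaflet_of, "protein_mol": protein_mol,
            "planes": planes, "template": template}
    return topology, np.concatenate(coords, axis=0), meta


def generate_topology(spec: SyntheticSpec) -> Topology:
    """Build the static system description for a synthetic spec."""
    topology, _, meta = _build_system(spec)
    topology.leaflet_ground_truth = dict(meta["leaflet_of"])
    return topology


def generate_trajectory(topology: Topology, spec: SyntheticSpec) -> Trajectory:
    """Generate frames: fBm lipid centers + Gaussian internal fluctuations.

    Deterministic under ``spec.rng_seed``; the expected ensemble MSD of the
    lipid centers in leaflet ℓ is exactly ``6 * D_ℓ * t**alpha_ℓ``.
    """
    spec.validate()
    _, ref, meta = _build_system(spec)
    if topology.n_atoms != ref.shape[0]:
        raise ValueError("topology does not match the spec system")
    rng = np.random.default_rng([spec.rng_seed, 1])
    F = spec.n_frames
    dt = spec.frame_interval
    dtype = np.dtype(spec.dtype)
    coords = np.empty((F, topology.n_atoms, 3), dtype=dtype)
    coords[:] = ref[None, :, :]

    leaflet_of = meta["leaflet_of"]
    label = {"upper": "contact", "noncontact": "noncontact"}
    # per-leaflet fBm of lipid geometric centers
    for leaflet, key in (("upper", "contact"), ("lower", "noncontact")):
        mols = [m for m, l in leaflet_of.items() if l == leaflet]
        if not mols:
            continue
        alpha = spec.leaflet_alpha[key]
        d_alpha = spec.leaflet_D[key]
        if d_alpha > 0 and F > 1:
            chol = fgn_cholesky(F - 1, alpha, d_alpha, dt)
        else:
            chol = None
        disp = sample_fbm_paths(3 * len(mols), F - 1, alpha, d_alpha, dt,
                                rng, chol=chol)
        disp = disp.reshape(F, len(mols), 3)
        for j, m in enumerate(mols):
            idx = topology.molecule_atoms(m)
            coords[:, idx, :] += disp[:, j, None, :].astype(dtype)

    # internal Gaussian fluctuations, independent per axis and per frame
    template = meta["template"]
    cov = spec.internal_covariance
    if cov is None:
        cov = default_internal_covariance(template, spec.head_variance,
                                          spec.tail_variance,
                                          spec.correlation_length)
    factor = _psd_factor(cov)
    if np.any(factor):
        lipid_mols = topology.molecules("lipid")
        nt = template.n_atoms
        lipid_atoms = np.concatenate(
            [topology.molecule_atoms(m) for m in lipid_mols])
        n_lip = len(lipid_mols)
        chunk = max(1, int(2e6 / max(1, nt * n_lip)))
        for f0 in range(0, F, chunk):
            f1 = min(F, f0 + chunk)
            z = rng.standard_normal((nt, (f1 - f0) * n_lip * 3))
            fluct = (factor @ z).reshape(nt, f1 - f0, n_lip, 3)
            fluct = np.moveaxis(fluct, 0, 2).reshape(f1 - f0, n_lip * nt, 3)
            coords[f0:f1, lipid_atoms, :] += fluct.astype(dtype)

    times = np.arange(F, dtype=float) * dt
    box = np.asarray(spec.box, dtype=float)
    if spec.wrap:
        coords = wrap_coordinates(coords, box)
    return Trajectory(coords, times, box)


# ---------------------------------------------------------------------------
# planted contacts and jump artefacts

_DEF_GEOM = {"hbond": {"d_ha": 2.1, "theta_deg": 180.0},
             "water_bridge": {"d_ha": 2.1, "theta_deg": 180.0},
             "hp": {"distance": 4.0},
             "ionic": {"distance": 3.0}}

_XHAT = np.array([1.0, 0.0, 0.0])
_YHAT = np.array([0.0, 1.0, 0.0])
_ZHAT = np.array([0.0, 0.0, 1.0])


def _resolve(topology: Topology, selector):
    mol, name = selector
    idx = topology.molecule_atoms(mol)
    hits = idx[topology.names[idx] == name]
    if len(hits) == 0:
        raise KeyError(f"atom {name!r} not found in molecule {mol}")
    return int(hits[0])


def _free_sites(coords0, box, n_sites, clearance=7.0, spacing=14.0):
    """Deterministic contact workbench: grid points ≥ ``clearance`` from all
    atoms and ≥ ``spacing`` apart, scanned top-down through the box."""
    from scipy.spatial import cKDTree
    tree = cKDTree(coords0)
    sites = []
    box = np.asarray(box, dtype=float)
    for z in np.arange(box[2] - 10.0, 8.0, -6.0):
        for x in np.arange(8.0, box[0] - 8.0, 8.0):
            for y in np.arange(8.0, box[1] - 8.0, 8.0):
                p = np.array([x, y, z])
                if tree.query(p)[0] < clearance:
                    continue
                if any(np.linalg.norm(p - s) < spacing for s in sites):
                    continue
                sites.append(p)
                if len(sites) == n_sites:
                    return sites
    return sites


def _park_other_hydrogens(topology, coords, heavy, keep, direction):
    """Point unused hydrogens of ``heavy`` away from the contact axis."""
    kids = np.where(topology.h_parent == heavy)[0]
    for n, h in enumerate(k for k in kids if k != keep):
        off = -direction + 0.25 * (n + 1) * _ZHAT
        off = off / np.linalg.norm(off)
        coords[:, h] = coords[0, heavy] + off


def _acceptor_arm(topology, coords, donor, acceptor, site, d_ha, theta_deg,
                  axis):
    """Freeze a donor–H···acceptor triple anchored at ``site``."""
    kids = np.where(topology.h_parent == donor)[0]
    if len(kids) == 0:
        raise ValueError("planted H-bond donor has no hydrogen")
    h = int(kids[0])
    coords[:, donor] = site
    h_pos = site + axis * 1.0
    coords[:, h] = h_pos
    th = np.radians(theta_deg)
    perp = _ZHAT if abs(axis[2]) < 0.9 else _YHAT
    v = -np.cos(th) * axis + np.sin(th) * perp
    coords[:, acceptor] = h_pos + d_ha * (v / np.linalg.norm(v))
    _park_other_hydrogens(topology, coords, donor, h, axis)
    _park_other_hydrogens(topology, coords, acceptor, None, axis)
    return h


def plant_contacts(trajectory: Trajectory, topology: Topology,
                   contacts: list):
    """Freeze planted contact geometries into every frame.

    Each contact's atoms are relocated to a free site (≥7 Å from every
    other atom, sites ≥14 Å apart) so the planted geometry is the only
    contact those atoms participate in; the geometry then holds exactly in
    every frame.  Returns ``(trajectory, ground_truth)`` where
    ``ground_truth`` maps each kind to the number of planted contacts
    expected to be detected per frame, plus a ``skipped`` list of contacts
    for which no clash-free site existed.
    """
    coords = trajectory.coords.copy()
    expected = {"hbond": 0, "hp": 0, "ionic": 0, "water_bridge": 0}
    skipped = []
    box = trajectory.box if trajectory.box is not None else \
        coords[0].max(axis=0) + 20.0
    sites = _free_sites(coords[0], box, len(contacts))
    free = iter(sites)
    for c in contacts:
        site = next(free, None)
        if site is None:
            skipped.append(c)
            continue
        geom = {**_DEF_GEOM[c.kind], **c.geometry}
        a = _resolve(topology, c.partner_a)
        b = _resolve(topology, c.partner_b)
        if c.kind == "hbond":
            _acceptor_arm(topology, coords, a, b, site, geom["d_ha"],
                          geom["theta_deg"], _XHAT)
        elif c.kind in ("hp", "ionic"):
            coords[:, a] = site
            coords[:, b] = site + geom["distance"] * _XHAT
        else:  # water bridge: water donates to both partner acceptors
            if topology.molecule_kind[c.water] != "water":
                raise ValueError("bridge selector must name a water molecule")
            w_atoms = topology.molecule_atoms(c.water)
            o = int(w_atoms[topology.elements[w_atoms] != "H"][0])
            hs = [int(i) for i in w_atoms if topology.elements[i] == "H"]
            coords[:, o] = site
            th = np.radians(geom["theta_deg"])
            for h, axis, partner in ((hs[0], _XHAT, a), (hs[1], _YHAT, b)):
                h_pos = site + axis * 1.0
                coords[:, h] = h_pos
                v = -np.cos(th) * axis + np.sin(th) * _ZHAT
                coords[:, partner] = h_pos + geom["d_ha"] * (v / np.linalg.norm(v))
                _park_other_hydrogens(topology, coords, partner, None, axis)
        if c.expected_detected:
            expected[c.kind] += 1
    truth = {**expected, "skipped": skipped}
    return Trajectory(coords, trajectory.times.copy(), trajectory.box), truth


def inject_jumps(trajectory: Trajectory, topology: Topology,
                 jumps: list) -> Trajectory:
    """Translate molecules by ±L along an axis from a frame onward.

    ``jumps`` is a list of ``(frame, molecule_id, axis, sign)`` mimicking
    the box-length artefact occasionally produced by simulation engines.
    """
    if not jumps:
        return trajectory.copy()
    if trajectory.box is None:
        raise ValueError("jump injection requires a box")
    coords = trajectory.coords.copy()
    for frame, mol, axis, sign in jumps:
        if not 0 <= frame < trajectory.n_frames:
            raise IndexError(f"jump frame {frame} out of range")
        idx = topology.molecule_atoms(mol)
        coords[frame:, idx, axis] += np.sign(sign) * trajectory.box[axis]
    return Trajectory(coords, trajectory.times.copy(), trajectory.box)


def ground_truth_dict(spec: SyntheticSpec, topology: Topology,
                      planted: dict | None = None) -> dict:
    """JSON-serializable ground truth of a generated system."""
    leaflets = getattr(topology, "leaflet_ground_truth", {})
    gt = {
        "leaflet_alpha": dict(spec.leaflet_alpha),
        "leaflet_D_A2_per_ns_alpha": dict(spec.leaflet_D),
        "n_lipids_per_leaflet": spec.n_lipids_per_leaflet,
        "lipid_template": spec.lipid_template,
        "frame_interval_ns": spec.frame_interval,
        "n_frames": spec.n_frames,
        "box_A": list(spec.box),
        "rng_seed": spec.rng_seed,
        "leaflet_of_molecule": {str(k): v for k, v in leaflets.items()},
    }
    if planted is not None:
        gt["planted_detected_per_frame"] = {
            k: planted[k] for k in ("hbond", "hp", "ionic", "water_bridge")}
        gt["planted_skipped"] = len(planted.get("skipped", ()))
    return gt


def write_ground_truth(path, spec: SyntheticSpec, topology: Topology,
                       planted: dict | None = None) -> None:
    with open(path, "w") as fh:
        json.dump(ground_truth_dict(spec, topology, planted), fh, indent=1)
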