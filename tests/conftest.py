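"""Shared fixtures and brute-force oracles.

The oracles deliberately use naive O(n²)/O(n³) enumeration and explicit
27-image periodic scans so they stay independent of the package's
KD-tree/minimum-image implementations.
"""

import numpy as np
import pytest

from memdyn.core import Topology
from memdyn.interactions import InteractionParams, hbond_energy
from memdyn.synthetic import SyntheticSpec


def brute_min_image(x1, x2, box):
    """Minimum distance over the 27 periodic images (oracle)."""
    best = np.inf
    for ix in (-1, 0, 1):
        for iy in (-1, 0, 1):
            for iz in (-1, 0, 1):
                shift = np.array([ix, iy, iz]) * np.asarray(box)
                best = min(best, float(np.linalg.norm(
                    np.asarray(x2) + shift - np.asarray(x1))))
    return best


def brute_angle(center, a, b, box):
    """Angle a-center-b in degrees using minimum-image vectors."""
    def mi(vec):
        if box is None:
            return vec
        return vec - np.asarray(box) * np.round(vec / np.asarray(box))
    va = mi(np.asarray(a) - np.asarray(center))
    vb = mi(np.asarray(b) - np.asarray(center))
    c = np.dot(va, vb) / (np.linalg.norm(va) * np.linalg.norm(vb))
    return np.degrees(np.arccos(np.clip(c, -1, 1)))


def brute_hbonds(coords, top, params=None, box=None):
    """Exhaustive donor–H···acceptor scan; returns sorted triples."""
    if params is None:
        params = InteractionParams()
    found = []
    for h in range(top.n_atoms):
        if top.elements[h] != "H":
            continue
        donor = top.h_parent[h]
        if donor < 0 or not top.is_donor[donor]:
            continue
        for acc in range(top.n_atoms):
            if not top.is_acceptor[acc] or acc in (donor, h):
                continue
            d = (brute_min_image(coords[h], coords[acc], box)
                 if box is not None
                 else float(np.linalg.norm(coords[acc] - coords[h])))
            theta = brute_angle(coords[h], coords[donor], coords[acc], box)
            if hbond_energy(d, theta, params) > params.hb_threshold:
                found.append((int(donor), int(h), int(acc)))
    return sorted(found)


def brute_pairs(coords, top, sel, cutoff, box, exclude_same_residue):
    found = []
    idx = np.where(sel)[0]
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            i, j = int(idx[a]), int(idx[b])
            if exclude_same_residue and (
                    top.molecule_ids[i] == top.molecule_ids[j]
                    and top.resids[i] == top.resids[j]):
                continue
            d = (brute_min_image(coords[i], coords[j], box)
                 if box is not None
                 else float(np.linalg.norm(coords[j] - coords[i])))
            if d <= cutoff:
                found.append((i, j))
    return sorted(found)


def brute_ionic(coords, top, params=None, box=None):
    if params is None:
        params = InteractionParams()
    found = []
    for i in np.where(top.charge_class > 0)[0]:
        for j in np.where(top.charge_class < 0)[0]:
            if (top.molecule_ids[i] == top.molecule_ids[j]
                    and top.resids[i] == top.resids[j]):
                continue
            d = (brute_min_image(coords[i], coords[j], box)
                 if box is not None
                 else float(np.linalg.norm(coords[j] - coords[i])))
            if d <= params.ionic_cutoff:
                found.append((int(i), int(j)))
    return sorted(found)


def make_topology(elements, *, names=None, resids=None, mol_ids=None,
                  kinds=None, donors=(), acceptors=(), hydrophobic=(),
                  charges=None, h_parent=None, resnames=None):
    """Hand-build a tiny topology for oracle tests.

    ``donors``/``acceptors``/``hydrophobic`` are atom-index collections;
    ``charges`` maps atom index -> ±1; ``kinds`` maps molecule id -> kind
    (default: every molecule a lipid).
    """
    from memdyn.constants import element_atomic_number, element_mass
    n = len(elements)
    elements = np.array(elements)
    names = np.array(names if names is not None
                     else [f"{e}{i}" for i, e in enumerate(elements)])
    mol_ids = np.array(mol_ids if mol_ids is not None else [0] * n)
    resids = np.array(resids if resids is not None else mol_ids + 1)
    resnames = np.array(resnames if resnames is not None else ["UNK"] * n)
    kinds = kinds or {int(m): "lipid" for m in np.unique(mol_ids)}
    is_donor = np.zeros(n, bool)
    is_donor[list(donors)] = True
    is_acceptor = np.zeros(n, bool)
    is_acceptor[list(acceptors)] = True
    is_hydro = np.zeros(n, bool)
    is_hydro[list(hydrophobic)] = True
    charge = np.zeros(n, np.int8)
    for i, c in (charges or {}).items():
        charge[i] = c
    if h_parent is None:
        h_parent = np.full(n, -1)
        for i in range(n):
            if elements[i] == "H":
                same = [j for j in range(n)
                        if mol_ids[j] == mol_ids[i] and elements[j] != "H"]
                h_parent[i] = same[0]
    return Topology(
        names=names, elements=elements,
        masses=np.array([element_mass(e) for e in elements]),
        atomic_numbers=np.array([element_atomic_number(e) for e in elements]),
        resnames=resnames, resids=resids, molecule_ids=mol_ids,
        chains=np.array(["A"] * n), molecule_kind=kinds,
        is_donor=is_donor, is_acceptor=is_acceptor, is_hydrophobic=is_hydro,
        charge_class=charge, h_parent=np.array(h_parent))


def random_typed_topology(rng, n_atoms=60, n_mols=6, box=(20.0, 20.0, 20.0)):
    """Random small system with mixed typing for detector-oracle tests."""
    mol_ids = np.sort(rng.integers(0, n_mols, n_atoms))
    elements, donors, acceptors, hydro, charges, h_parent = [], [], [], [], {}, []
    for i in range(n_atoms):
        r = rng.random()
        if r < 0.3 and i > 0 and mol_ids[i] == mol_ids[i - 1] \
                and elements[i - 1] in ("N", "O"):
            elements.append("H")
            h_parent.append(i - 1)
            donors.append(i - 1)
        else:
            e = rng.choice(["C", "N", "O"], p=[0.5, 0.2, 0.3])
            elements.append(str(e))
            h_parent.append(-1)
            if e == "O" and rng.random() < 0.8:
                acceptors.append(i)
            if e == "N" and rng.random() < 0.4:
                acceptors.append(i)
            if e == "C" and rng.random() < 0.6:
                hydro.append(i)
            if rng.random() < 0.15:
                charges[i] = int(rng.choice([-1, 1]))
    top = make_topology(elements, mol_ids=mol_ids, donors=donors,
                        acceptors=acceptors, hydrophobic=hydro,
                        charges=charges, h_parent=h_parent)
    coords = rng.uniform(0, box[0], (n_atoms, 3))
    coords[:, 1] *= box[1] / box[0]
    coords[:, 2] *= box[2] / box[0]
    return top, coords


@pytest.fixture
def sparse_spec():
    """Small, widely spaced system where planted contacts are the only ones."""
    return SyntheticSpec(
        n_lipids_per_leaflet=4, lipid_template="minimal", minimal_atoms=10,
        leaflet_alpha={"contact": 1.0, "noncontact": 1.0},
        leaflet_D={"contact": 0.0, "noncontact": 0.0},
        internal_covariance=np.zeros((10, 10)),
        n_frames=3, box=(120.0, 120.0, 200.0), head_to_head=60.0,
        n_waters=4, n_cations=1, n_anions=1, rng_seed=7,
        protein_offset=20.0)
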