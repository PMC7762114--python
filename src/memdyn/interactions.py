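"""Per-frame contact detection and aggregation.

Four contact types are detected, following the energy- and
distance-criterion conventions common to MD analysis engines:

* **H-bonds** — donor–H···acceptor triples whose modelled energy exceeds a
  threshold fraction (default 25%) of an optimum energy (default
  25 kJ/mol), i.e. E > 6.25 kJ/mol strictly.  The energy is a product of a
  linear ramp in the hydrogen–acceptor distance (full strength at ≤2.1 Å,
  zero at ≥2.6 Å) and a linear ramp in the donor–H–acceptor angle (zero at
  ≤100°, full at 180°), scaled to the optimum.
* **Hydrophobic (HP) contacts** — pairs of hydrophobic heavy atoms from
  different residues within a distance cutoff (default 5 Å).
* **Ionic interactions** — pairs of oppositely charge-classed atoms within
  a cutoff (default 5 Å), tagged when a solvent ion participates.
* **Water bridges** — a water simultaneously H-bonded (as donor or
  acceptor) to atoms of two distinct non-water molecules.

Neighbor searches use periodic KD-trees; tests enforce equality with
brute-force enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import Topology, Trajectory
from .pbc import minimum_image_vector, wrap_coordinates

KINDS = ("hbond", "hp", "ionic", "water_bridge")


@dataclass
class InteractionParams:
    """Detection thresholds; defaults follow the analysis conventions."""

    hb_optimal_energy: float = 25.0     # kJ/mol
    hb_threshold_fraction: float = 0.25
    hb_d_plateau: float = 2.1           # Å, H···A distance of full strength
    hb_d_zero: float = 2.6              # Å, H···A distance of zero energy
    hb_angle_floor: float = 100.0       # deg, donor angle of zero energy
    hb_angle_span: float = 80.0         # deg, ramp up to 180°
    hp_cutoff: float = 5.0              # Å
    ionic_cutoff: float = 5.0           # Å

    def __post_init__(self):
        if not 0 < self.hb_threshold_fraction < 1:
            raise ValueError("threshold fraction must lie in (0, 1)")
        if self.hb_d_plateau >= self.hb_d_zero:
            raise ValueError("distance plateau must precede the zero point")
        if self.hp_cutoff <= 0 or self.ionic_cutoff <= 0:
            raise ValueError("cutoffs must be positive")

    @property
    def hb_threshold(self) -> float:
        """H-bond energy threshold in kJ/mol (fraction × optimum)."""
        return self.hb_threshold_fraction * self.hb_optimal_energy


@dataclass
class InteractionRecord:
    kind: str
    frame: int
    atoms: tuple           # (i, j) or (donor, H, acceptor) or (water_mol, i, j)
    scope: str
    energy: float | None = None
    solvent_ion: bool = False


def hbond_energy(d_ha: float, theta_deg: float,
                 params: InteractionParams | None = None) -> float:
    """H-bond energy (kJ/mol) from H···acceptor distance and donor angle.

    Product of the clamped distance and angle ramps scaled to the optimum;
    continuous, non-increasing in distance, non-decreasing in angle.
    """
    if params is None:
        params = InteractionParams()
    d_ha = np.asarray(d_ha, dtype=float)
    theta_deg = np.asarray(theta_deg, dtype=float)
    f_d = np.clip((params.hb_d_zero - np.maximum(d_ha, params.hb_d_plateau))
                  / (params.hb_d_zero - params.hb_d_plateau), 0.0, 1.0)
    f_a = np.clip((theta_deg - params.hb_angle_floor) / params.hb_angle_span,
                  0.0, 1.0)
    e = params.hb_optimal_energy * f_d * f_a
    return float(e) if e.ndim == 0 else e


def _scope(topology: Topology, mol_i: int, mol_j: int) -> str:
    a = topology.molecule_kind[mol_i]
    b = topology.molecule_kind[mol_j]
    pair = frozenset((a, b))
    if pair == {"protein", "lipid"}:
        return "protein-lipid"
    if pair == {"lipid"}:
        return "lipid-lipid"
    if pair == {"protein"}:
        return "protein"
    if pair == {"lipid", "water"}:
        return "lipid-water"
    if "ion" in pair:
        return "ion"
    return "-".join(sorted(pair))


def _tree(points, box):
    if box is None:
        return cKDTree(points), points
    wrapped = wrap_coordinates(points, box)
    # guard against points mapped exactly onto the upper boundary
    wrapped = np.where(wrapped >= box, 0.0, wrapped)
    return cKDTree(wrapped, boxsize=box), wrapped


def detect_hbonds(coords: np.ndarray, topology: Topology,
                  params: InteractionParams | None = None,
                  box=None, frame: int = 0) -> list:
    """All donor–H···acceptor triples with energy strictly above threshold."""
    if params is None:
        params = InteractionParams()
    is_h = topology.elements == "H"
    hydrogens = np.where(is_h & (topology.h_parent >= 0)
                         & topology.is_donor[np.clip(topology.h_parent, 0, None)])[0]
    acceptors = np.where(topology.is_acceptor)[0]
    records = []
    if len(hydrogens) == 0 or len(acceptors) == 0:
        return records
    tree, acc_pts = _tree(coords[acceptors], box)
    h_pts = coords[hydrogens] if box is None else wrap_coordinates(
        coords[hydrogens], box)
    h_pts = h_pts if box is None else np.where(h_pts >= box, 0.0, h_pts)
    neighbors = tree.query_ball_point(h_pts, params.hb_d_zero)
    for hi, cand in zip(hydrogens, neighbors):
        donor = int(topology.h_parent[hi])
        for ci in cand:
            acc = int(acceptors[ci])
            if acc == donor or acc == hi:
                continue
            v_hd = minimum_image_vector(coords[hi], coords[donor], box)
            v_ha = minimum_image_vector(coords[hi], coords[acc], box)
            d_ha = np.linalg.norm(v_ha)
            if d_ha == 0.0:
                continue
            cosang = np.dot(v_hd, v_ha) / (np.linalg.norm(v_hd) * d_ha)
            theta = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            e = hbond_energy(d_ha, theta, params)
            if e > params.hb_threshold:
                records.append(InteractionRecord(
                    kind="hbond", frame=frame,
                    atoms=(donor, int(hi), acc),
                    scope=_scope(topology, topology.molecule_ids[donor],
                                 topology.molecule_ids[acc]),
                    energy=e))
    return records


def detect_hp_contacts(coords: np.ndarray, topology: Topology,
                       params: InteractionParams | None = None,
                       box=None, frame: int = 0) -> list:
    """Hydrophobic-atom pairs within the cutoff, same-residue pairs excluded."""
    if params is None:
        params = InteractionParams()
    hydro = np.where(topology.is_hydrophobic)[0]
    records = []
    if len(hydro) < 2:
        return records
    tree, _ = _tree(coords[hydro], box)
    for ia, ib in sorted(tree.query_pairs(params.hp_cutoff)):
        i, j = int(hydro[ia]), int(hydro[ib])
        same_residue = (topology.molecule_ids[i] == topology.molecule_ids[j]
                        and topology.resids[i] == topology.resids[j])
        if same_residue:
            continue
        records.append(InteractionRecord(
            kind="hp", frame=frame, atoms=(min(i, j), max(i, j)),
            scope=_scope(topology, topology.molecule_ids[i],
                         topology.molecule_ids[j])))
    return records


def detect_ionic(coords: np.ndarray, topology: Topology,
                 params: InteractionParams | None = None,
                 box=None, frame: int = 0) -> list:
    """Oppositely charge-classed atom pairs within the cutoff.

    Pairs within one residue (e.g. the N⁺/phosphate-O⁻ of a single
    zwitterionic headgroup) are excluded.
    """
    if params is None:
        params = InteractionParams()
    pos = np.where(topology.charge_class > 0)[0]
    neg = np.where(topology.charge_class < 0)[0]
    records = []
    if len(pos) == 0 or len(neg) == 0:
        return records
    tree, _ = _tree(coords[neg], box)
    pos_pts = coords[pos] if box is None else wrap_coordinates(coords[pos], box)
    pos_pts = pos_pts if box is None else np.where(pos_pts >= box, 0.0, pos_pts)
    neighbors = tree.query_ball_point(pos_pts, params.ionic_cutoff)
    kinds = topology.atom_kind
    for pi, cand in zip(pos, neighbors):
        for ci in cand:
            ni = int(neg[ci])
            if (topology.molecule_ids[pi] == topology.molecule_ids[ni]
                    and topology.resids[pi] == topology.resids[ni]):
                continue
            records.append(InteractionRecord(
                kind="ionic", frame=frame, atoms=(int(pi), ni),
                scope=_scope(topology, topology.molecule_ids[pi],
                             topology.molecule_ids[ni]),
                solvent_ion=bool(kinds[pi] == "ion" or kinds[ni] == "ion")))
    return records


def detect_water_bridges(coords: np.ndarray, topology: Topology,
                         params: InteractionParams | None = None,
                         box=None, frame: int = 0,
                         hbonds: list | None = None) -> list:
    """Waters H-bonded to atoms of two distinct non-water molecules.

    One record per (water, unordered partner-atom pair); ``atoms`` carries
    ``(water_molecule_id, partner_atom_i, partner_atom_j)``.
    """
    if hbonds is None:
        hbonds = detect_hbonds(coords, topology, params, box, frame)
    kinds = topology.atom_kind
    partners = {}
    for rec in hbonds:
        donor, _, acc = rec.atoms
        dw = kinds[donor] == "water"
        aw = kinds[acc] == "water"
        if dw == aw:                       # water-water or no water at all
            continue
        water_atom, partner = (donor, acc) if dw else (acc, donor)
        wmol = int(topology.molecule_ids[water_atom])
        partners.setdefault(wmol, set()).add(int(partner))
    records = []
    for wmol, atoms in sorted(partners.items()):
        for i, j in combinations(sorted(atoms), 2):
            mi, mj = topology.molecule_ids[i], topology.molecule_ids[j]
            if mi == mj:
                continue
            records.append(InteractionRecord(
                kind="water_bridge", frame=frame, atoms=(wmol, i, j),
                scope=_scope(topology, mi, mj)))
    return records


_DETECTORS = {"hbond": detect_hbonds, "hp": detect_hp_contacts,
              "ionic": detect_ionic, "water_bridge": detect_water_bridges}


def detect_frame(coords, topology, params=None, box=None, frame=0,
                 kinds=KINDS) -> list:
    """Run the requested detectors on one frame (H-bonds shared with bridges)."""
    records = []
    hb = None
    if "hbond" in kinds or "water_bridge" in kinds:
        hb = detect_hbonds(coords, topology, params, box, frame)
    if "hbond" in kinds:
        records.extend(hb)
    if "hp" in kinds:
        records.extend(detect_hp_contacts(coords, topology, params, box, frame))
    if "ionic" in kinds:
        records.extend(detect_ionic(coords, topology, params, box, frame))
    if "water_bridge" in kinds:
        records.extend(detect_water_bridges(coords, topology, params, box,
                                            frame, hbonds=hb))
    return records


# ---------------------------------------------------------------------------
# aggregation


def _record_endpoints(rec: InteractionRecord):
    if rec.kind == "hbond":
        return rec.atoms[0], rec.atoms[2]
    if rec.kind == "water_bridge":
        return rec.atoms[1], rec.atoms[2]
    return rec.atoms


def _atom_label(topology: Topology, atom: int, scheme: str) -> str:
    if scheme == "residue":
        return f"{topology.resids[atom]} {str(topology.resnames[atom]).capitalize()}"
    if scheme == "atom_name":
        return str(topology.names[atom])
    raise ValueError(f"unknown label scheme {scheme!r}")


def build_interaction_map(records, topology: Topology,
                          rows=("protein", "residue"),
                          cols=("lipid", "atom_name")) -> pd.DataFrame:
    """Aggregate records into a labelled count matrix.

    ``rows``/``cols`` are ``(molecule_kind, scheme)`` with scheme
    ``residue`` (e.g. ``246 Lys``) or ``atom_name`` (e.g. ``O13``).  Each
    record contributes one count at the cell addressed by its endpoint on
    the row side and its endpoint on the column side; records lacking an
    endpoint of the requested kind are skipped.  For symmetric maps
    (rows == cols, e.g. lipid-atom × lipid-atom water bridges) the
    endpoints are sorted so each record lands in one cell.
    """
    row_kind, row_scheme = rows
    col_kind, col_scheme = cols
    kinds = topology.atom_kind
    cells = {}
    symmetric = rows == cols
    for rec in records:
        i, j = _record_endpoints(rec)
        ki, kj = kinds[i], kinds[j]
        if symmetric:
            if ki != row_kind or kj != row_kind:
                continue
            li = _atom_label(topology, i, row_scheme)
            lj = _atom_label(topology, j, col_scheme)
            cell = (min(li, lj), max(li, lj))
        else:
            if ki == row_kind and kj == col_kind:
                r, c = i, j
            elif kj == row_kind and ki == col_kind:
                r, c = j, i
            else:
                continue
            cell = (_atom_label(topology, r, row_scheme),
                    _atom_label(topology, c, col_scheme))
        cells[cell] = cells.get(cell, 0) + 1
    if not cells:
        return pd.DataFrame(dtype=int)
    df = pd.Series(cells).unstack(fill_value=0).astype(int)
    df.index.name = f"{row_kind}_{row_scheme}"
    df.columns.name = f"{col_kind}_{col_scheme}"
    return df


def records_to_frame(records, topology: Topology) -> pd.DataFrame:
    """Flat table of records (TSV-friendly)."""
    rows = []
    for rec in records:
        i, j = _record_endpoints(rec)
        rows.append({
            "frame": rec.frame, "kind": rec.kind, "scope": rec.scope,
            "atom_i": i, "atom_j": j,
            "name_i": topology.names[i], "name_j": topology.names[j],
            "res_i": f"{topology.resids[i]} {topology.resnames[i]}",
            "res_j": f"{topology.resids[j]} {topology.resnames[j]}",
            "energy_kJ_mol": rec.energy if rec.energy is not None else np.nan,
            "solvent_ion": rec.solvent_ion,
        })
    return pd.DataFrame(rows)


def interaction_time_series(trajectory: Trajectory, topology: Topology,
                            params: InteractionParams | None = None,
                            scope: str = "protein-lipid",
                            kinds=("hbond", "hp"),
                            frames=None) -> pd.DataFrame:
    """Per-frame counts in scope plus participating-lipid statistics.

    For each analyzed frame and kind: the number of records whose scope
    matches, the number of distinct lipid molecules involved, and the
    min/max records per participating lipid.  ``frames`` may be an iterable
    of frame indices (default: all frames).
    """
    if frames is None:
        frames = range(trajectory.n_frames)
    rows = []
    for f in frames:
        recs = detect_frame(trajectory.coords[f], topology, params,
                            trajectory.box, frame=f, kinds=kinds)
        for kind in kinds:
            scoped = [r for r in recs if r.kind == kind and r.scope == scope]
            per_lipid = {}
            for r in scoped:
                for atom in _record_endpoints(r):
                    mol = int(topology.molecule_ids[atom])
                    if topology.molecule_kind[mol] == "lipid":
                        per_lipid[mol] = per_lipid.get(mol, 0) + 1
            rows.append({
                "frame": f, "time_ns": trajectory.times[f], "kind": kind,
                "count": len(scoped),
                "n_lipids": len(per_lipid),
                "per_lipid_min": min(per_lipid.values()) if per_lipid else 0,
                "per_lipid_max": max(per_lipid.values()) if per_lipid else 0,
            })
    return pd.DataFrame(rows)
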