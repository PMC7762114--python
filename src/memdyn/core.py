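"""Core in-memory containers: :class:`Topology` and :class:`Trajectory`.

A topology is a static description of the system (atom names, elements,
masses, residue/molecule grouping, hydrogen-bond donor/acceptor flags,
hydrophobicity, formal charge class).  A trajectory is an ordered stack of
coordinate frames in Å with timestamps in ns and an orthorhombic box.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

MOLECULE_KINDS = ("lipid", "protein", "water", "ion")


@dataclass
class Topology:
    """Static atom/residue/molecule description.

    All per-atom arrays have length ``n_atoms``.  ``molecule_ids`` partition
    atoms into molecules; ``molecule_kind`` maps each molecule id to one of
    ``lipid``, ``protein``, ``water``, ``ion``.  ``h_parent[i]`` is the index
    of the heavy atom covalently bonded to hydrogen ``i`` (−1 for heavy
    atoms).  ``is_donor`` is set on heavy atoms that can donate an H-bond
    through an attached hydrogen.
    """

    names: np.ndarray
    elements: np.ndarray
    masses: np.ndarray
    atomic_numbers: np.ndarray
    resnames: np.ndarray
    resids: np.ndarray
    molecule_ids: np.ndarray
    chains: np.ndarray
    molecule_kind: dict
    is_donor: np.ndarray
    is_acceptor: np.ndarray
    is_hydrophobic: np.ndarray
    charge_class: np.ndarray
    h_parent: np.ndarray
    serials: np.ndarray | None = None
    _mol_atoms: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.serials is None:
            self.serials = np.arange(1, self.n_atoms + 1)
        self._mol_atoms = None

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def atom_kind(self) -> np.ndarray:
        """Per-atom molecule kind (vector of strings)."""
        return np.array([self.molecule_kind[m] for m in self.molecule_ids])

    def molecules(self, kind: str | None = None) -> list:
        """Molecule ids, optionally restricted to one kind, in id order."""
        ids = sorted(self.molecule_kind)
        if kind is None:
            return ids
        return [m for m in ids if self.molecule_kind[m] == kind]

    def molecule_atoms(self, mol_id: int) -> np.ndarray:
        """Atom indices belonging to molecule ``mol_id``."""
        if self._mol_atoms is None:
            order = np.argsort(self.molecule_ids, kind="stable")
            ids, starts = np.unique(self.molecule_ids[order], return_index=True)
            splits = np.split(order, starts[1:])
            self._mol_atoms = {int(i): np.sort(s) for i, s in zip(ids, splits)}
        return self._mol_atoms[int(mol_id)]

    def validate(self) -> None:
        n = self.n_atoms
        for arr in (self.elements, self.masses, self.resnames, self.resids,
                    self.molecule_ids, self.is_donor, self.is_acceptor,
                    self.is_hydrophobic, self.charge_class, self.h_parent):
            if len(arr) != n:
                raise ValueError("topology arrays have inconsistent lengths")
        if np.any(self.masses <= 0):
            raise ValueError("atom masses must be positive")
        is_h = self.elements == "H"
        if np.any(self.h_parent[is_h] < 0):
            raise ValueError("every hydrogen must be bonded to one heavy atom")
        if set(np.unique(self.molecule_ids)) != set(self.molecule_kind):
            raise ValueError("molecule_kind must cover exactly the molecule ids")
        for kind in self.molecule_kind.values():
            if kind not in MOLECULE_KINDS:
                raise ValueError(f"unknown molecule kind {kind!r}")


@dataclass
class Trajectory:
    """Ordered coordinate frames (Å), frame times (ns) and orthorhombic box.

    ``coords`` has shape ``(n_frames, n_atoms, 3)``.  ``box`` is the constant
    ``(Lx, Ly, Lz)`` in Å, or ``None`` when unknown.
    """

    coords: np.ndarray
    times: np.ndarray
    box: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if len(self.times) != self.coords.shape[0]:
            raise ValueError("one timestamp per frame required")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3)
            if np.any(self.box <= 0):
                raise ValueError("box lengths must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def copy(self) -> "Trajectory":
        return Trajectory(self.coords.copy(), self.times.copy(),
                          None if self.box is None else self.box.copy())

    def slice_frames(self, sel) -> "Trajectory":
        idx = np.arange(self.n_frames)[sel]
        return Trajectory(self.coords[idx], self.times[idx], self.box)


def molecule_indicator(topology: Topology, mol_ids=None,
                       weights: np.ndarray | None = None) -> tuple:
    """Sparse (n_molecules × n_atoms) averaging matrix for molecule centers.

    With ``weights=None`` each row averages atom positions uniformly
    (geometric center); with per-atom ``weights`` (e.g. masses) rows are
    weight-normalized.  Returns ``(mol_ids, matrix)``.
    """
    if mol_ids is None:
        mol_ids = topology.molecules()
    rows, cols, vals = [], [], []
    for r, m in enumerate(mol_ids):
        idx = topology.molecule_atoms(m)
        if len(idx) == 0:
            raise ValueError(f"molecule {m} has no atoms")
        if weights is None:
            w = np.full(len(idx), 1.0 / len(idx))
        else:
            w = weights[idx] / weights[idx].sum()
        rows.extend([r] * len(idx))
        cols.extend(idx)
        vals.extend(w)
    mat = sparse.csr_matrix((vals, (rows, cols)),
                            shape=(len(mol_ids), topology.n_atoms))
    return list(mol_ids), mat


def molecule_center_paths(trajectory: Trajectory, topology: Topology,
                          mol_ids=None, weights: np.ndarray | None = None):
    """Per-molecule center paths, shape ``(n_frames, n_molecules, 3)``."""
    mol_ids, mat = molecule_indicator(topology, mol_ids, weights)
    f, n, _ = trajectory.coords.shape
    flat = trajectory.coords.transpose(1, 0, 2).reshape(n, f * 3)
    centers = (mat @ flat).reshape(len(mol_ids), f, 3).transpose(1, 0, 2)
    return mol_ids, centers
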