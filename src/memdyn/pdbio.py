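"""Multi-model PDB reading and writing (MDAnalysis-backed).

Trajectories are exchanged as multi-model PDB files (MODEL/ENDMDL records,
CRYST1 for the orthorhombic box).  On read, atom typing is inferred from
residue + atom-name tables; hydrogens are associated to their nearest
heavy atom within the same residue; protein residues sharing a chain form
one molecule while every lipid, water and ion residue is its own molecule.
PDB stores no timestamps, so frame times are synthesized from a frame
interval (default 0.05 ns — 20 frames per ns).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np

from . import atomtypes
from .constants import element_atomic_number, element_mass
from .core import Topology, Trajectory

log = logging.getLogger(__name__)

_UNITARY = np.array([1.0, 1.0, 1.0])


def _mda():
    import MDAnalysis as mda
    return mda


def _header_cryst1(path):
    """First CRYST1 record of the file (MDAnalysis applies CRYST1 only
    inside MODEL blocks, but multi-frame writers put one in the header)."""
    with open(path) as fh:
        for line in fh:
            if line.startswith("CRYST1"):
                b = np.array([float(line[6:15]), float(line[15:24]),
                              float(line[24:33])])
                if np.all(b > 0) and not np.allclose(b, _UNITARY):
                    return b
                return None
            if line.startswith(("MODEL", "ATOM", "HETATM")):
                return None
    return None


def read_multimodel_pdb(path, frame_interval: float = 0.05,
                        typing_tables: dict | None = None):
    """Read a multi-model PDB into ``(Topology, Trajectory)``.

    Coordinates in Å; CRYST1 becomes the box (a missing or unitary CRYST1
    leaves the box unset with a warning).  Unknown residue names get a
    neutral, non-donor typing.
    """
    mda = _mda()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    atoms = u.atoms
    names = atoms.names.astype(str)
    resnames = atoms.resnames.astype(str)
    resids = atoms.resids.astype(int)
    try:
        chains = atoms.chainIDs.astype(str)
    except (AttributeError, mda.exceptions.NoDataError):
        chains = np.array([""] * len(names))
    elements = np.array([atomtypes.infer_element(n, r)
                         for n, r in zip(names, resnames)])

    coords = np.empty((len(u.trajectory), len(names), 3))
    box = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for f, ts in enumerate(u.trajectory):
            coords[f] = ts.positions
            if ts.dimensions is not None and box is None:
                b = np.asarray(ts.dimensions[:3], dtype=float)
                if np.all(b > 0) and not np.allclose(b, _UNITARY):
                    box = b
    if box is None:
        box = _header_cryst1(path)
    if box is None:
        log.warning("no usable CRYST1 record: box left unset")

    # molecule grouping: contiguous protein residues per chain -> one molecule
    mol_ids = np.empty(len(names), dtype=int)
    molecule_kind = {}
    mol = -1
    prev = None
    for i in range(len(names)):
        kind = atomtypes.molecule_kind_of_resname(resnames[i])
        res_key = (chains[i], resids[i], resnames[i])
        if kind == "protein":
            key = ("protein", chains[i])
        else:
            key = (kind, res_key)
        if key != prev:
            mol += 1
            molecule_kind[mol] = kind
            prev = key
        mol_ids[i] = mol

    # hydrogens bond to the nearest heavy atom in the same residue, judged
    # on the mean structure of the first frames (robust to fluctuations)
    h_parent = np.full(len(names), -1, dtype=int)
    pos0 = coords[:min(len(coords), 20)].mean(axis=0)
    res_key_arr = np.array([f"{c}|{r}|{rn}" for c, r, rn
                            in zip(chains, resids, resnames)])
    for key in np.unique(res_key_arr):
        idx = np.where(res_key_arr == key)[0]
        heavies = idx[elements[idx] != "H"]
        hydros = idx[elements[idx] == "H"]
        if len(hydros) and not len(heavies):
            raise ValueError("residue with hydrogens but no heavy atoms")
        for h in hydros:
            d = np.linalg.norm(pos0[heavies] - pos0[h], axis=1)
            h_parent[h] = heavies[np.argmin(d)]

    is_donor, is_acceptor, is_hydrophobic, charge = atomtypes.classify_atoms(
        names, resnames, typing_tables)
    topology = Topology(
        names=names, elements=elements,
        masses=np.array([element_mass(e) for e in elements]),
        atomic_numbers=np.array([element_atomic_number(e) for e in elements]),
        resnames=resnames, resids=resids, molecule_ids=mol_ids,
        chains=chains, molecule_kind=molecule_kind,
        is_donor=is_donor, is_acceptor=is_acceptor,
        is_hydrophobic=is_hydrophobic, charge_class=charge,
        h_parent=h_parent, serials=np.asarray(atoms.ids, dtype=int),
    )
    topology.validate()
    times = np.arange(coords.shape[0], dtype=float) * frame_interval
    return topology, Trajectory(coords, times, box)


def write_multimodel_pdb(path, topology: Topology,
                         trajectory: Trajectory) -> None:
    """Write a trajectory as a multi-model PDB (one MODEL per frame)."""
    mda = _mda()
    from MDAnalysis.coordinates.memory import MemoryReader

    # residues = runs of constant (molecule, resid, resname)
    keys = list(zip(topology.molecule_ids, topology.resids, topology.resnames))
    resindex = np.zeros(topology.n_atoms, dtype=int)
    res_resids, res_resnames = [], []
    r = -1
    prev = None
    for i, key in enumerate(keys):
        if key != prev:
            r += 1
            res_resids.append(int(topology.resids[i]))
            res_resnames.append(str(topology.resnames[i]))
            prev = key
        resindex[i] = r
    n_res = r + 1

    u = mda.Universe.empty(topology.n_atoms, n_residues=n_res,
                           atom_resindex=resindex,
                           residue_segindex=np.zeros(n_res, dtype=int),
                           trajectory=True)
    u.add_TopologyAttr("names", topology.names.astype(str))
    u.add_TopologyAttr("resnames", res_resnames)
    u.add_TopologyAttr("resids", res_resids)
    u.add_TopologyAttr("chainIDs", topology.chains.astype(str))
    u.add_TopologyAttr("elements", topology.elements.astype(str))

    if trajectory.box is not None:
        dims = np.array([*trajectory.box, 90.0, 90.0, 90.0])
    else:
        dims = None
    u.load_new(trajectory.coords.astype(np.float32), format=MemoryReader,
               dimensions=None if dims is None
               else np.tile(dims, (trajectory.n_frames, 1)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=topology.n_atoms,
                        multiframe=True) as writer:
            for _ in u.trajectory:
                writer.write(u.atoms)
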