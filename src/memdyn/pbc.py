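"""Periodic-boundary utilities and box-size jump repair.

Simulation engines occasionally emit artefact translations of a whole
molecule by one box length between consecutive saved frames.  Such jumps
wreck displacement statistics; :func:`level_jumps` detects them (per-axis
molecule-center displacement exceeding half the box length between
consecutive frames) and shifts the trailing trajectory back by the integer
number of box lengths that minimizes the displacement, acting on whole
molecules only.
"""

from __future__ import annotations

import numpy as np

from .core import Topology, Trajectory, molecule_center_paths


def minimum_image_vector(x1, x2, box):
    """Shortest vector from ``x1`` to ``x2`` on an orthorhombic box.

    Broadcasts over leading dimensions; with ``box=None`` returns the plain
    difference.
    """
    d = np.asarray(x2, dtype=float) - np.asarray(x1, dtype=float)
    if box is None:
        return d
    box = np.asarray(box, dtype=float)
    if np.any(box <= 0):
        raise ValueError("box lengths must be positive")
    return d - box * np.round(d / box)


def minimum_image_distance(x1, x2, box):
    """Euclidean minimum-image distance between points (broadcasting)."""
    d = minimum_image_vector(x1, x2, box)
    return np.linalg.norm(d, axis=-1)


def wrap_coordinates(coords, box):
    """Wrap coordinates into ``[0, L)`` on each axis."""
    box = np.asarray(box, dtype=float)
    return coords - box * np.floor(coords / box)


def level_jumps(trajectory: Trajectory, topology: Topology) -> Trajectory:
    """Remove whole-molecule box-length jump artefacts.

    For every molecule and every pair of consecutive frames, a per-axis
    center displacement larger than half the box length is treated as a
    wrapping artefact and the molecule's trailing frames are shifted by the
    nearest integer multiple of the box length.  The operation is
    idempotent and leaves jump-free trajectories untouched.
    """
    if trajectory.box is None:
        raise ValueError("level_jumps requires a known box")
    box = trajectory.box
    mol_ids, centers = molecule_center_paths(trajectory, topology)
    if trajectory.n_frames < 2:
        return trajectory.copy()
    diffs = centers[1:] - centers[:-1]                    # (F-1, M, 3)
    shifts = -np.round(diffs / box) * box                 # 0 unless |d| > L/2
    cum = np.cumsum(shifts, axis=0)                       # (F-1, M, 3)
    if not np.any(cum):
        return trajectory.copy()
    col = np.empty(topology.n_atoms, dtype=int)
    for c, m in enumerate(mol_ids):
        col[topology.molecule_atoms(m)] = c
    out = trajectory.coords.copy()
    out[1:] += cum[:, col, :]
    return Trajectory(out, trajectory.times.copy(), box.copy())
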