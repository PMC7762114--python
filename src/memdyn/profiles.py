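"""Membrane structural profiles along the bilayer normal (z).

Electron density profiles assign each atom's electron count (atomic
number) to a z-bin; the two headgroup peaks of the lipid component define
the bilayer thickness (peak-to-peak convention).  Protein penetration
depth is measured from the contact-leaflet phosphorus plane toward the
bilayer center.  Interior water content counts water oxygens strictly
between the two headgroup peak planes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .core import Topology, Trajectory

COMPONENTS = ("lipid", "water", "protein", "ion")


@dataclass
class DensityProfile:
    z: np.ndarray                      # bin centers, Å
    density: dict                      # component -> e⁻/Å³
    bin_width: float
    frame_range: tuple

    @property
    def total(self) -> np.ndarray:
        return np.sum([self.density[c] for c in COMPONENTS], axis=0)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"z_A": self.z})
        for c in COMPONENTS:
            df[f"rho_{c}"] = self.density[c]
        df["rho_total"] = self.total
        return df


@dataclass
class PenetrationReport:
    depth: np.ndarray                  # per-frame depth, Å
    deepest_atoms: list                # per-frame atom index
    deepest_residues: list             # per-frame "resid RESNAME"
    reference_plane: np.ndarray        # per-frame P-plane z, Å


def electron_density_profile(trajectory: Trajectory, topology: Topology,
                             bin_width: float = 1.0,
                             frames=None) -> DensityProfile:
    """Per-component electron density averaged over a frame window."""
    if trajectory.box is None:
        raise ValueError("density profile requires a box")
    if frames is None:
        frames = range(trajectory.n_frames)
    frames = list(frames)
    lx, ly, lz = trajectory.box
    edges = np.arange(0.0, lz + bin_width, bin_width)
    kinds = topology.atom_kind
    volume = lx * ly * bin_width
    density = {}
    for comp in COMPONENTS:
        sel = kinds == comp
        hist = np.zeros(len(edges) - 1)
        if np.any(sel):
            weights = topology.atomic_numbers[sel].astype(float)
            for f in frames:
                z = np.mod(trajectory.coords[f, sel, 2], lz)
                hist += np.histogram(z, bins=edges, weights=weights)[0]
        density[comp] = hist / (len(frames) * volume)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return DensityProfile(z=centers, density=density, bin_width=bin_width,
                          frame_range=(frames[0], frames[-1]))


def headgroup_peak_planes(profile: DensityProfile) -> tuple:
    """z positions (Å) of the two lipid headgroup peaks, lower first.

    The lipid density is split at its weighted center and the highest peak
    on each side is taken, which is robust against interior bumps from
    interdigitating tails.
    """
    rho = profile.density["lipid"]
    if rho.max() <= 0:
        raise ValueError("no lipid density: no bilayer")
    center = float(np.sum(profile.z * rho) / np.sum(rho))
    peaks, props = find_peaks(rho, height=0.05 * rho.max())
    planes = []
    for side in (profile.z[peaks] < center, profile.z[peaks] >= center):
        cand = peaks[side]
        if len(cand) == 0:
            raise ValueError("lipid profile is not bimodal: no bilayer")
        planes.append(profile.z[cand[np.argmax(rho[cand])]])
    return float(planes[0]), float(planes[1])


def bilayer_thickness(profile: DensityProfile) -> float:
    """Peak-to-peak distance (Å) between the two lipid headgroup maxima."""
    lo, hi = headgroup_peak_planes(profile)
    return hi - lo


def penetration_depth(trajectory: Trajectory, topology: Topology,
                      contact_leaflet_mols) -> PenetrationReport:
    """Protein insertion depth past the contact-leaflet phosphorus plane.

    Per frame: reference plane = mean z of the contact leaflet's P atoms;
    depth = max(0, distance of the deepest protein atom beyond the plane
    toward the bilayer center).  Reports the residue owning the deepest
    atom each frame.
    """
    p_atoms = []
    for m in contact_leaflet_mols:
        idx = topology.molecule_atoms(m)
        p_atoms.extend(idx[topology.names[idx] == "P"])
    if not p_atoms:
        raise ValueError("contact leaflet has no phosphorus atoms")
    p_atoms = np.array(p_atoms)
    prot_atoms = np.concatenate(
        [topology.molecule_atoms(m) for m in topology.molecules("protein")])
    lipid_atoms = np.concatenate(
        [topology.molecule_atoms(m) for m in topology.molecules("lipid")])
    depths, deep_atoms, deep_res, planes = [], [], [], []
    for f in range(trajectory.n_frames):
        plane = trajectory.coords[f, p_atoms, 2].mean()
        center = trajectory.coords[f, lipid_atoms, 2].mean()
        direction = np.sign(center - plane)  # toward bilayer interior
        z = trajectory.coords[f, prot_atoms, 2]
        insert = direction * (z - plane)     # >0 means past the plane
        k = int(np.argmax(insert))
        atom = int(prot_atoms[k])
        depths.append(max(0.0, float(insert[k])))
        deep_atoms.append(atom)
        deep_res.append(f"{topology.resids[atom]} {topology.resnames[atom]}")
        planes.append(float(plane))
    return PenetrationReport(depth=np.array(depths), deepest_atoms=deep_atoms,
                             deepest_residues=deep_res,
                             reference_plane=np.array(planes))


def interior_water_count(trajectory: Trajectory, topology: Topology,
                         profile: DensityProfile | None = None,
                         frames=None) -> np.ndarray:
    """Water oxygens strictly between the two headgroup peak planes, per frame."""
    if profile is None:
        profile = electron_density_profile(trajectory, topology)
    lo, hi = headgroup_peak_planes(profile)
    kinds = topology.atom_kind
    ox = np.where((kinds == "water") & (topology.elements == "O"))[0]
    if frames is None:
        frames = range(trajectory.n_frames)
    counts = []
    for f in frames:
        z = trajectory.coords[f, ox, 2]
        counts.append(int(np.sum((z > lo) & (z < hi))))
    return np.array(counts)
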