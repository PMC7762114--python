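"""Lipid center-of-geometry dynamics: MSD, anomalous-diffusion fits, Rg.

The mean squared displacement is the fixed-origin ensemble average

    MSD(t) = (1/N) Σ_i |r_i(t) − r_i(0)|²

over molecule geometric centers (unweighted atom mean, hydrogens included
by default).  Anomalous diffusion MSD = 6 D_α t^α is fitted by ordinary
least squares in log-log space; D_α is reported both in Å²/ns^α and
cm²/s^α.  A sliding-window (multi-origin) MSD variant is available behind
a flag for variance reduction but is not the default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .constants import diffusion_A2ns_to_cm2s
from .core import Topology, Trajectory, molecule_center_paths

log = logging.getLogger(__name__)


@dataclass
class MSDSeries:
    t: np.ndarray              # lag times, ns
    msd: np.ndarray            # Å²
    n_molecules: int
    label: str = "all"

    def __post_init__(self):
        if self.t[0] != 0 or self.msd[0] != 0:
            raise ValueError("MSD series must start at (0, 0)")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("lag times must be strictly increasing")
        if np.any(self.msd < 0):
            raise ValueError("MSD must be non-negative")


@dataclass
class PowerLawFit:
    alpha: float
    d_alpha: float             # Å²/ns^α
    d_alpha_cm2s: float        # cm²/s^α
    std_alpha: float
    std_d: float               # std of D in Å²/ns^α
    t_min: float
    t_max: float
    label: str = "all"


def geometric_centers(trajectory: Trajectory, topology: Topology,
                      kind: str = "lipid", mol_ids=None,
                      include_hydrogens: bool = True,
                      mass_weighted: bool = False):
    """Per-molecule center paths ``(mol_ids, centers (F, M, 3))``.

    Operates on the trajectory as given — level jumps first when artefacts
    may be present.
    """
    if mol_ids is None:
        mol_ids = topology.molecules(kind)
    weights = None
    if mass_weighted:
        weights = topology.masses.astype(float)
    elif not include_hydrogens:
        weights = (topology.elements != "H").astype(float)
    if mass_weighted and not include_hydrogens:
        weights = topology.masses * (topology.elements != "H")
    return molecule_center_paths(trajectory, topology, mol_ids, weights)


def assign_leaflets(topology: Topology, trajectory: Trajectory,
                    frame: int = 0) -> dict:
    """Split lipids into leaflets; label the protein-facing one ``contact``.

    Lipids are classed by the sign of their center z relative to the
    bilayer midplane (mean center z of all lipids) at ``frame``; a lipid
    exactly on the midplane goes to the noncontact side (logged).  The
    leaflet whose mean head-phosphorus plane lies nearer the protein's
    geometric center is ``contact``; without a protein the labels are
    ``upper``/``lower``.
    """
    lipid_ids, centers = geometric_centers(trajectory, topology, "lipid")
    z = centers[frame, :, 2]
    midplane = z.mean()
    upper = z > midplane
    if np.any(z == midplane):
        log.info("%d lipid(s) exactly at the midplane assigned to the "
                 "noncontact side", int(np.sum(z == midplane)))
    protein_ids = topology.molecules("protein")
    if not protein_ids:
        return {m: ("upper" if u else "lower")
                for m, u in zip(lipid_ids, upper)}
    _, pc = geometric_centers(trajectory, topology, "protein")
    protein_z = pc[frame, :, 2].mean()
    plane_z = {}
    for side, mask in (("upper", upper), ("lower", ~upper)):
        atoms = []
        for m in np.asarray(lipid_ids)[mask]:
            idx = topology.molecule_atoms(m)
            atoms.extend(idx[topology.names[idx] == "P"])
        plane_z[side] = (np.mean(trajectory.coords[frame, atoms, 2])
                         if atoms else np.mean(z[mask]))
    contact_side = min(plane_z, key=lambda s: abs(plane_z[s] - protein_z))
    return {m: ("contact" if (u == (contact_side == "upper")) else "noncontact")
            for m, u in zip(lipid_ids, upper)}


def compute_msd(centers: np.ndarray, times: np.ndarray,
                label: str = "all", time_average: bool = False) -> MSDSeries:
    """Fixed-origin ensemble MSD of center paths ``(F, M, 3)``.

    With ``time_average=True`` a multi-origin (sliding-window) estimate is
    returned instead of the fixed-origin definition.
    """
    centers = np.asarray(centers, dtype=float)
    if centers.ndim == 2:
        centers = centers[:, None, :]
    f, m, _ = centers.shape
    if f < 2:
        raise ValueError("need at least two frames")
    if not time_average:
        disp = centers - centers[0]
        msd = np.mean(np.sum(disp * disp, axis=2), axis=1)
    else:
        msd = np.zeros(f)
        for lag in range(1, f):
            d = centers[lag:] - centers[:-lag]
            msd[lag] = np.mean(np.sum(d * d, axis=2))
    t = np.asarray(times, dtype=float) - times[0]
    return MSDSeries(t=t, msd=msd, n_molecules=m, label=label)


def fit_power_law(msd: MSDSeries, fit_range=None) -> PowerLawFit:
    """OLS fit of ln MSD = ln(6 D_α) + α ln t over the fit range.

    Default range: all positive lags excluding the first saved frame.
    Parameter standard deviations come from the linear-fit covariance;
    ``std_d`` is propagated from the intercept (delta method).
    """
    if fit_range is None:
        t_min = msd.t[2] if len(msd.t) > 2 else msd.t[1]
        fit_range = (t_min, msd.t[-1])
    t_lo, t_hi = fit_range
    sel = (msd.t >= t_lo) & (msd.t <= t_hi) & (msd.t > 0)
    if np.sum(sel) < 5:
        raise ValueError("need at least 5 points in the fit range")
    if np.any(msd.msd[sel] <= 0):
        raise ValueError("MSD must be positive over the fit range")
    x = np.log(msd.t[sel])
    y = np.log(msd.msd[sel])
    (alpha, intercept), cov = np.polyfit(x, y, 1, cov=True)
    d_alpha = np.exp(intercept) / 6.0
    std_alpha = float(np.sqrt(cov[0, 0]))
    std_d = float(d_alpha * np.sqrt(cov[1, 1]))
    return PowerLawFit(alpha=float(alpha), d_alpha=float(d_alpha),
                       d_alpha_cm2s=diffusion_A2ns_to_cm2s(d_alpha, alpha),
                       std_alpha=std_alpha, std_d=std_d,
                       t_min=float(t_lo), t_max=float(t_hi), label=msd.label)


def leaflet_msd_fits(trajectory: Trajectory, topology: Topology,
                     fit_range=None, time_average: bool = False):
    """MSD and power-law fit per leaflet; returns dict label -> (MSDSeries, fit)."""
    leaflets = assign_leaflets(topology, trajectory)
    out = {}
    for label in sorted(set(leaflets.values())):
        mols = [m for m, l in leaflets.items() if l == label]
        _, centers = geometric_centers(trajectory, topology, mol_ids=mols)
        msd = compute_msd(centers, trajectory.times, label=label,
                          time_average=time_average)
        out[label] = (msd, fit_power_law(msd, fit_range))
    return out


def radius_of_gyration(trajectory: Trajectory, topology: Topology,
                       kind: str = "lipid", mol_ids=None):
    """Mass-weighted radius of gyration, averaged over molecules and frames.

    Returns ``(mean_rg, per_molecule_rg)`` in Å.
    """
    if mol_ids is None:
        mol_ids = topology.molecules(kind)
    per_mol = np.empty(len(mol_ids))
    for k, m in enumerate(mol_ids):
        idx = topology.molecule_atoms(m)
        w = topology.masses[idx]
        xyz = trajectory.coords[:, idx, :]
        com = np.einsum("fij,i->fj", xyz, w) / w.sum()
        d2 = np.sum((xyz - com[:, None, :]) ** 2, axis=2)
        rg = np.sqrt(np.einsum("fi,i->f", d2, w) / w.sum())
        per_mol[k] = rg.mean()
    return float(per_mol.mean()), per_mol
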