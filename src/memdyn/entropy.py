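"""Schlitter configurational entropy from mass-weighted coordinate covariances.

For a molecule of n atoms observed over F frames, each atom's x, y and z
position series are mean-subtracted per coordinate and concatenated into a
single series of 3F realizations; the n×n covariance matrix σ averages the
products of these concatenated series.  The entropy bound is

    S = k_B · ln det(1 + (k_B T e² / ħ²) · M^{1/2} σ M^{1/2}),

with M the diagonal atomic mass matrix.  By default the conventional 1/2
prefactor of Schlitter's bound is omitted (a convention used when only
the shape of the entropy-vs-time curve matters); a ``half_prefactor``
switch restores the textbook form.  The identity addition keeps the determinant finite even when
few frames make σ singular.  The determinant is evaluated in the log
domain over the eigenvalues of the symmetrically mass-weighted matrix
(equal in determinant to M σ for diagonal M).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import R_KCAL_PER_MOL_K, SCHLITTER_SCALE_PER_K
from .core import Topology, Trajectory
from .dynamics import assign_leaflets

log = logging.getLogger(__name__)


@dataclass
class CovarianceModel:
    sigma: np.ndarray          # (n, n), Å²
    n_realizations: int        # frames × 3
    n_atoms: int


@dataclass
class EntropyResult:
    times: np.ndarray                 # ns, cumulative-window right edges
    s_mean: np.ndarray                # kcal/(mol·K), averaged over molecules
    s_std: np.ndarray
    per_molecule: np.ndarray          # (n_times, n_molecules)
    molecule_ids: list
    temperature: float


def concatenated_series(segment: np.ndarray,
                        remove_center: bool = False) -> np.ndarray:
    """Zero-mean concatenated coordinate series, shape ``(n_atoms, 3F)``.

    ``segment`` is ``(F, n_atoms, 3)``.  Means are removed per atom and per
    Cartesian coordinate before concatenation.  With ``remove_center`` the
    molecule's per-frame geometric center is subtracted first (optional;
    translation inflates the covariance otherwise).
    """
    seg = np.asarray(segment, dtype=float)
    if seg.ndim != 3 or seg.shape[2] != 3:
        raise ValueError("segment must have shape (F, n_atoms, 3)")
    if seg.shape[0] < 2:
        raise ValueError("covariance needs at least two frames")
    if remove_center:
        seg = seg - seg.mean(axis=1, keepdims=True)
    centered = seg - seg.mean(axis=0, keepdims=True)
    return centered.transpose(1, 0, 2).reshape(seg.shape[1], -1)


def covariance_matrix(segment: np.ndarray,
                      remove_center: bool = False) -> CovarianceModel:
    """Atom-level covariance from a molecule trajectory segment ``(F, n, 3)``."""
    series = concatenated_series(segment, remove_center)
    n, reals = series.shape
    sigma = (series @ series.T) / reals
    return CovarianceModel(sigma=sigma, n_realizations=reals, n_atoms=n)


def schlitter_entropy(cov: CovarianceModel | np.ndarray, masses: np.ndarray,
                      temperature: float,
                      half_prefactor: bool = False) -> dict:
    """Entropy of one molecule; returns ``{"S_kB", "S_kcal_per_molK"}``.

    ``masses`` in amu, covariance in Å², ``temperature`` in K.  Negative
    covariance eigenvalues beyond numerical tolerance are clamped to zero
    with a warning; S is therefore always ≥ 0.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    sigma = cov.sigma if isinstance(cov, CovarianceModel) else np.asarray(cov)
    masses = np.asarray(masses, dtype=float)
    if sigma.shape != (len(masses), len(masses)):
        raise ValueError("covariance dimension must equal the atom count")
    root_m = np.sqrt(masses)
    weighted = sigma * np.outer(root_m, root_m)
    scale = SCHLITTER_SCALE_PER_K * temperature
    eigvals = np.linalg.eigvalsh(0.5 * (weighted + weighted.T))
    tol = 1e-10 * max(1.0, float(np.abs(eigvals).max()))
    if eigvals.min() < -tol:
        log.warning("covariance has negative eigenvalue %.3g; clamping",
                    eigvals.min())
    eigvals = np.clip(eigvals, 0.0, None)
    s_kb = float(np.sum(np.log1p(scale * eigvals)))
    if half_prefactor:
        s_kb *= 0.5
    return {"S_kB": s_kb, "S_kcal_per_molK": s_kb * R_KCAL_PER_MOL_K}


def entropy_time_curve(trajectory: Trajectory, topology: Topology,
                       temperature: float, molecule_ids=None,
                       eval_frames=None, half_prefactor: bool = False,
                       remove_center: bool = False) -> EntropyResult:
    """Cumulative-window entropy vs time, averaged over lipids.

    At each evaluation time t the covariance uses all frames in [0, t].  By
    default the average runs over the lipids of the contact leaflet (the
    bilayer side facing the protein); pass ``molecule_ids`` to override.
    """
    if molecule_ids is None:
        if topology.molecules("protein"):
            leaflets = assign_leaflets(topology, trajectory)
            molecule_ids = sorted(m for m, l in leaflets.items()
                                  if l == "contact")
        else:
            molecule_ids = topology.molecules("lipid")
    if not molecule_ids:
        raise ValueError("no molecules to analyze")
    if eval_frames is None:
        eval_frames = range(2, trajectory.n_frames + 1)
    eval_frames = [int(f) for f in eval_frames]
    if any(f < 2 or f > trajectory.n_frames for f in eval_frames):
        raise ValueError("evaluation frames must lie in [2, n_frames]")
    per = np.empty((len(eval_frames), len(molecule_ids)))
    for j, mol in enumerate(molecule_ids):
        idx = topology.molecule_atoms(mol)
        masses = topology.masses[idx]
        xyz = trajectory.coords[:, idx, :]
        for i, f in enumerate(eval_frames):
            cov = covariance_matrix(xyz[:f], remove_center=remove_center)
            per[i, j] = schlitter_entropy(cov, masses, temperature,
                                          half_prefactor)["S_kcal_per_molK"]
    times = trajectory.times[np.array(eval_frames) - 1]
    return EntropyResult(times=times, s_mean=per.mean(axis=1),
                         s_std=per.std(axis=1), per_molecule=per,
                         molecule_ids=list(molecule_ids),
                         temperature=temperature)


def gaussianity_diagnostics(segment: np.ndarray, n_bins: int = 30) -> dict:
    """Correlation structure and marginals of the concatenated series.

    Returns the Pearson correlation matrix of the per-atom concatenated
    coordinate series plus per-atom histogram tables, for eyeballing how
    far the fluctuations are from the Gaussian assumption behind the
    covariance-based entropy.
    """
    seg = np.asarray(segment, dtype=float)
    if seg.shape[0] < 30:
        raise ValueError("diagnostics need at least 30 frames")
    series = concatenated_series(seg)
    sd = series.std(axis=1)
    safe = np.where(sd > 0, sd, 1.0)
    norm = series / safe[:, None]
    corr = (norm @ norm.T) / series.shape[1]
    corr[sd == 0, :] = 0.0
    corr[:, sd == 0] = 0.0
    np.fill_diagonal(corr, 1.0)
    hists = []
    for i in range(series.shape[0]):
        counts, edges = np.histogram(series[i], bins=n_bins)
        hists.append(pd.DataFrame({
            "atom": i, "bin_left": edges[:-1], "bin_right": edges[1:],
            "count": counts}))
    return {"correlation": corr,
            "histograms": pd.concat(hists, ignore_index=True),
            "n_realizations": series.shape[1]}
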