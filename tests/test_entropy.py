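"""Schlitter entropy: bookkeeping, closed forms, sampling convergence."""

import math

import numpy as np
import pytest

from memdyn.constants import (AMU_KG, ANGSTROM_M, HBAR_J_S, KB_J_PER_K,
                              R_KCAL_PER_MOL_K)
from memdyn.entropy import (covariance_matrix, entropy_time_curve,
                            gaussianity_diagnostics, schlitter_entropy)
from memdyn.synthetic import (SyntheticSpec, generate_topology,
                              generate_trajectory)


def scalar_entropy_oracle(masses_amu, variances_A2, temperature):
    """Independent per-atom evaluation for diagonal covariances (k_B units)."""
    total = 0.0
    for m, v in zip(masses_amu, variances_A2):
        lam = (KB_J_PER_K * temperature * math.e ** 2 / HBAR_J_S ** 2
               * (m * AMU_KG) * (v * ANGSTROM_M ** 2))
        total += math.log(1.0 + lam)
    return total


class TestCovarianceBookkeeping:
    def test_dppc_dimensions_and_realizations(self):
        spec = SyntheticSpec(
            n_lipids_per_leaflet=1, lipid_template="DPPC", n_frames=1000,
            include_protein=False, n_waters=0, n_cations=0, n_anions=0,
            box=(40.0, 40.0, 120.0))
        top = generate_topology(spec)
        traj = generate_trajectory(top, spec)
        idx = top.molecule_atoms(0)
        assert len(idx) == 130
        cov = covariance_matrix(traj.coords[:, idx, :])
        assert cov.sigma.shape == (130, 130)
        assert cov.n_realizations == 3000

    def test_frozen_molecule_zero_matrix(self):
        seg = np.ones((10, 4, 3)) * 2.5
        cov = covariance_matrix(seg)
        assert np.all(cov.sigma == 0)

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            covariance_matrix(np.zeros((1, 4, 3)))

    def test_known_sample_covariance(self):
        # two atoms moving identically in x only: hand-computable entries
        seg = np.zeros((4, 2, 3))
        seg[:, 0, 0] = [0.0, 1.0, 2.0, 3.0]
        seg[:, 1, 0] = [0.0, 1.0, 2.0, 3.0]
        cov = covariance_matrix(seg)
        # per-coordinate variance of [0,1,2,3] is 1.25, spread over 3 axes
        assert cov.sigma[0, 0] == pytest.approx(1.25 / 3)
        assert cov.sigma[0, 1] == pytest.approx(1.25 / 3)


class TestSchlitterFormula:
    def test_zero_covariance_zero_entropy(self):
        out = schlitter_entropy(np.zeros((5, 5)), np.full(5, 12.011), 310.0)
        assert out["S_kB"] == 0.0
        assert out["S_kcal_per_molK"] == 0.0

    def test_single_atom_scalar_formula(self):
        m, v, temp = 15.999, 0.42, 310.0
        out = schlitter_entropy(np.array([[v]]), np.array([m]), temp)
        expect = scalar_entropy_oracle([m], [v], temp)
        assert out["S_kB"] == pytest.approx(expect, rel=1e-12)

    def test_diagonal_closed_form(self):
        rng = np.random.default_rng(21)
        n = 12
        masses = rng.uniform(1.0, 31.0, n)
        variances = rng.uniform(0.01, 1.0, n)
        out = schlitter_entropy(np.diag(variances), masses, 310.0)
        expect = scalar_entropy_oracle(masses, variances, 310.0)
        assert out["S_kB"] == pytest.approx(expect, rel=1e-12)
        assert out["S_kcal_per_molK"] == pytest.approx(
            expect * R_KCAL_PER_MOL_K, rel=1e-12)

    def test_half_prefactor_convention(self):
        cov = np.diag([0.3, 0.2])
        masses = np.array([12.011, 15.999])
        full = schlitter_entropy(cov, masses, 310.0)
        half = schlitter_entropy(cov, masses, 310.0, half_prefactor=True)
        assert half["S_kB"] == pytest.approx(0.5 * full["S_kB"], rel=1e-14)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(8, 8))
        cov = a @ a.T / 8
        masses = rng.uniform(1, 30, 8)
        perm = rng.permutation(8)
        s1 = schlitter_entropy(cov, masses, 310.0)["S_kB"]
        s2 = schlitter_entropy(cov[np.ix_(perm, perm)], masses[perm],
                               310.0)["S_kB"]
        assert s2 == pytest.approx(s1, rel=1e-10)

    def test_monotone_in_variance_scale(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(6, 6))
        cov = a @ a.T / 6
        masses = rng.uniform(1, 30, 6)
        values = [schlitter_entropy(c * cov, masses, 310.0)["S_kB"]
                  for c in (0.0, 0.1, 0.5, 1.0, 2.0)]
        assert values[0] == 0.0
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_negative_eigenvalue_clamped(self, caplog):
        cov = np.diag([0.5, -0.1])
        out = schlitter_entropy(cov, np.array([12.0, 12.0]), 310.0)
        assert out["S_kB"] >= 0


class TestSamplingConvergence:
    def test_sampled_gaussian_close_to_closed_form(self):
        # 1000 frames x 3 axes = 3000 realizations of a 20-atom Gaussian
        rng = np.random.default_rng(8)
        n = 20
        a = rng.normal(size=(n, n)) / np.sqrt(n)
        cov_true = 0.25 * (a @ a.T + 0.5 * np.eye(n))
        masses = rng.uniform(1.0, 31.0, n)
        chol = np.linalg.cholesky(cov_true)
        draws = (chol @ rng.standard_normal((n, 3000)))
        seg = draws.reshape(n, 1000, 3).transpose(1, 0, 2)
        est = covariance_matrix(seg)
        assert est.n_realizations == 3000
        s_est = schlitter_entropy(est, masses, 310.0)["S_kB"]
        s_true = schlitter_entropy(cov_true, masses, 310.0)["S_kB"]
        assert abs(s_est - s_true) / s_true < 0.05

    def test_estimate_converges_with_frames(self):
        rng = np.random.default_rng(15)
        n = 10
        a = rng.normal(size=(n, n)) / np.sqrt(n)
        cov_true = 0.3 * (a @ a.T + 0.3 * np.eye(n))
        masses = rng.uniform(1.0, 31.0, n)
        chol = np.linalg.cholesky(cov_true)
        s_true = schlitter_entropy(cov_true, masses, 310.0)["S_kB"]
        errors = []
        for frames in (100, 1000, 5000):
            draws = chol @ rng.standard_normal((n, 3 * frames))
            seg = draws.reshape(n, frames, 3).transpose(1, 0, 2)
            s = schlitter_entropy(covariance_matrix(seg), masses,
                                  310.0)["S_kB"]
            errors.append(abs(s - s_true) / s_true)
        assert errors[2] < errors[0]
        assert errors[2] < 0.02


class TestEntropyCurve:
    def test_rises_then_plateaus(self, sparse_spec):
        import dataclasses
        spec = dataclasses.replace(
            sparse_spec, n_frames=240,
            internal_covariance=0.3 * np.eye(10))
        top = generate_topology(spec)
        traj = generate_trajectory(top, spec)
        res = entropy_time_curve(traj, top, 310.0,
                                 eval_frames=[5, 20, 80, 160, 240])
        assert np.all(np.diff(res.s_mean) > -1e-6)      # non-decreasing
        early_rise = res.s_mean[1] - res.s_mean[0]
        late_rise = res.s_mean[-1] - res.s_mean[-2]
        assert late_rise < 0.2 * early_rise             # flattening
        # plateau near the closed form at the true covariance
        idx = top.molecule_atoms(res.molecule_ids[0])
        expect = scalar_entropy_oracle(
            top.masses[idx], [0.3] * 10, 310.0) * R_KCAL_PER_MOL_K
        assert res.s_mean[-1] == pytest.approx(expect, rel=0.05)

    def test_identical_lipids_spread_shrinks(self, sparse_spec):
        import dataclasses
        spec = dataclasses.replace(
            sparse_spec, n_frames=200, internal_covariance=0.3 * np.eye(10))
        top = generate_topology(spec)
        traj = generate_trajectory(top, spec)
        res = entropy_time_curve(traj, top, 310.0, eval_frames=[10, 200])
        rel_spread = res.s_std / res.s_mean
        assert rel_spread[-1] < rel_spread[0]

    def test_default_averages_contact_leaflet(self, sparse_spec):
        top = generate_topology(sparse_spec)
        traj = generate_trajectory(top, sparse_spec)
        res = entropy_time_curve(traj, top, 310.0, eval_frames=[3])
        from memdyn.dynamics import assign_leaflets
        leaf = assign_leaflets(top, traj)
        assert set(res.molecule_ids) == {m for m, l in leaf.items()
                                         if l == "contact"}


class TestDiagnostics:
    def test_independent_noise_uncorrelated(self):
        rng = np.random.default_rng(30)
        seg = rng.normal(size=(400, 6, 3))
        out = gaussianity_diagnostics(seg)
        corr = out["correlation"]
        off = corr[~np.eye(6, dtype=bool)]
        assert np.all(np.abs(off) < 3 / np.sqrt(out["n_realizations"]) * 3)

    def test_comoving_atoms_fully_correlated(self):
        rng = np.random.default_rng(31)
        base = rng.normal(size=(200, 1, 3))
        seg = np.repeat(base, 4, axis=1)
        corr = gaussianity_diagnostics(seg)["correlation"]
        assert np.allclose(corr, 1.0)

    def test_planted_block_structure_recovered(self):
        rng = np.random.default_rng(32)
        n, frames = 8, 2000
        cov = np.eye(n)
        cov[:4, :4] = 0.2 * np.eye(4) + 0.8
        cov[4:, 4:] = 0.2 * np.eye(4) + 0.8
        chol = np.linalg.cholesky(cov)
        draws = chol @ rng.standard_normal((n, 3 * frames))
        seg = draws.reshape(n, frames, 3).transpose(1, 0, 2)
        corr = gaussianity_diagnostics(seg)["correlation"]
        assert corr[:4, :4].min() > 0.6
        assert corr[4:, 4:].min() > 0.6
        assert np.abs(corr[:4, 4:]).max() < 0.2
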