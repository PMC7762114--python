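"""Synthetic-system generator: counts, statistics, determinism, planting."""

import numpy as np
import pytest

from memdyn.dynamics import compute_msd, fit_power_law
from memdyn.fbm import sample_fbm_paths
from memdyn.interactions import detect_frame
from memdyn.synthetic import (PlantedContact, SyntheticSpec,
                              default_internal_covariance, generate_topology,
                              generate_trajectory, plant_contacts)


def small_spec(**kw):
    base = dict(n_lipids_per_leaflet=4, lipid_template="minimal",
                minimal_atoms=10, n_frames=5, n_waters=5, n_cations=2,
                n_anions=2, box=(60.0, 60.0, 150.0), rng_seed=11)
    base.update(kw)
    return SyntheticSpec(**base)


class TestTopologyGeneration:
    @pytest.mark.parametrize("template,atoms", [("DPPC", 130), ("POPE", 125)])
    def test_lipid_atom_counts(self, template, atoms):
        spec = small_spec(lipid_template=template, n_lipids_per_leaflet=2)
        top = generate_topology(spec)
        for mol in top.molecules("lipid"):
            assert len(top.molecule_atoms(mol)) == atoms

    def test_lipid_population(self):
        spec = small_spec(n_lipids_per_leaflet=6)
        top = generate_topology(spec)
        assert len(top.molecules("lipid")) == 12
        leaf = top.leaflet_ground_truth
        assert sum(v == "upper" for v in leaf.values()) == 6

    def test_full_bilayer_molecule_count(self):
        # study-scale bookkeeping without generating frames
        spec = SyntheticSpec(n_frames=2, n_waters=0, n_cations=0, n_anions=0,
                             include_protein=False)
        top = generate_topology(spec)
        assert len(top.molecules("lipid")) == 288

    def test_head_atom_names_present(self):
        spec = small_spec(lipid_template="DPPC", n_lipids_per_leaflet=1)
        top = generate_topology(spec)
        names = set(top.names[top.molecule_atoms(0)])
        assert {"P", "N", "O13", "O14", "O22", "C11", "C12"} <= names

    def test_typing_flags(self):
        spec = small_spec(lipid_template="DPPC", n_lipids_per_leaflet=1)
        top = generate_topology(spec)
        idx = top.molecule_atoms(0)
        by_name = {top.names[i]: i for i in idx}
        assert top.is_acceptor[by_name["O13"]]
        assert top.is_acceptor[by_name["O14"]]
        assert not top.is_donor[by_name["N"]]        # quaternary choline N
        assert top.is_hydrophobic[by_name["C216"]]
        assert top.charge_class[by_name["N"]] == 1

    def test_invalid_template_rejected(self):
        with pytest.raises(ValueError):
            generate_topology(small_spec(lipid_template="DOPC"))

    def test_protein_and_solvent_present(self):
        top = generate_topology(small_spec())
        assert len(top.molecules("protein")) == 1
        assert len(top.molecules("water")) == 5
        assert len(top.molecules("ion")) == 4


class TestTrajectoryGeneration:
    def test_frozen_system_is_static(self):
        spec = small_spec(leaflet_D={"contact": 0.0, "noncontact": 0.0},
                          internal_covariance=np.zeros((10, 10)))
        top = generate_topology(spec)
        traj = generate_trajectory(top, spec)
        assert np.all(traj.coords == traj.coords[0])

    def test_same_seed_bit_identical(self):
        spec = small_spec(n_frames=8)
        top = generate_topology(spec)
        a = generate_trajectory(top, spec)
        b = generate_trajectory(top, spec)
        assert np.array_equal(a.coords, b.coords)

    def test_different_seed_differs(self):
        spec_a = small_spec(n_frames=8)
        spec_b = small_spec(n_frames=8, rng_seed=99)
        top = generate_topology(spec_a)
        assert not np.array_equal(generate_trajectory(top, spec_a).coords,
                                  generate_trajectory(top, spec_b).coords)

    def test_non_psd_covariance_rejected(self):
        cov = np.diag([1.0] * 9 + [-1.0])
        spec = small_spec(internal_covariance=cov)
        top = generate_topology(spec)
        with pytest.raises(np.linalg.LinAlgError):
            generate_trajectory(top, spec)


class TestFbmStatistics:
    def test_normal_diffusion_msd(self):
        # alpha=1, D=1: sample MSD within sampling error of 6t
        rng = np.random.default_rng(0)
        n_mol, n_steps, dt = 600, 50, 0.1
        paths = sample_fbm_paths(3 * n_mol, n_steps, 1.0, 1.0, dt, rng)
        centers = paths.reshape(n_steps + 1, n_mol, 3)
        t = np.arange(n_steps + 1) * dt
        msd = compute_msd(centers, t)
        expect = 6.0 * t[1:]
        rel = np.abs(msd.msd[1:] - expect) / expect
        assert np.median(rel) < 0.15

    def test_subdiffusive_alpha_recovery(self):
        # oracle: the fit itself is exact on the analytic curve ...
        t = np.linspace(0, 50, 1001)
        exact = compute_msd.__wrapped__ if hasattr(compute_msd, "__wrapped__") \
            else None
        from memdyn.dynamics import MSDSeries
        analytic = MSDSeries(t=t, msd=6 * 0.5 * np.where(t > 0, t, 0) ** 0.3,
                             n_molecules=1)
        assert fit_power_law(analytic).alpha == pytest.approx(0.3, abs=1e-10)
        # ... so any recovery bias is attributable to the generator
        rng = np.random.default_rng(42)
        paths = sample_fbm_paths(3 * 288, 999, 0.3, 0.5, 0.05, rng)
        centers = paths.reshape(1000, 288, 3)
        msd = compute_msd(centers, np.arange(1000) * 0.05)
        fit = fit_power_law(msd)
        assert fit.alpha == pytest.approx(0.3, abs=0.05)

    def test_internal_covariance_recovered(self):
        # 1000 frames x 3 axes = 3000 realizations; Frobenius error <= 10%
        spec = small_spec(n_lipids_per_leaflet=1, n_frames=1000,
                          include_protein=False, n_waters=0, n_cations=0,
                          n_anions=0,
                          leaflet_D={"contact": 0.0, "noncontact": 0.0})
        top = generate_topology(spec)
        traj = generate_trajectory(top, spec)
        from memdyn.entropy import covariance_matrix
        target = default_internal_covariance(spec.template())
        idx = top.molecule_atoms(0)
        est = covariance_matrix(traj.coords[:, idx, :]).sigma
        err = np.linalg.norm(est - target) / np.linalg.norm(target)
        assert err <= 0.10


class TestPlantedContacts:
    def test_planted_hbonds_detected_exactly(self, sparse_spec):
        top = generate_topology(sparse_spec)
        traj = generate_trajectory(top, sparse_spec)
        prot = top.molecules("protein")[0]
        waters = top.molecules("water")
        contacts = [
            PlantedContact("hbond", (waters[0], "O"), (0, "O13")),
            PlantedContact("hbond", (waters[1], "O"), (1, "O13")),
            PlantedContact("hbond", (prot, "OG"), (2, "O14")),
            PlantedContact("hbond", (prot, "OG1"), (3, "O14")),
            PlantedContact("hbond", (prot, "NZ"), (4, "O13")),
            PlantedContact("hbond", (prot, "OH"), (5, "O22"),
                           geometry={"d_ha": 5.0}, expected_detected=False),
        ]
        planted, truth = plant_contacts(traj, top, contacts)
        assert truth["hbond"] == 5
        assert not truth["skipped"]
        records = detect_frame(planted.coords[0], top, box=planted.box,
                               kinds=("hbond",))
        lipidward = [r for r in records if "lipid" in r.scope]
        assert len(lipidward) == 5

    def test_planted_bridge_and_pairs(self, sparse_spec):
        top = generate_topology(sparse_spec)
        traj = generate_trajectory(top, sparse_spec)
        waters = top.molecules("water")
        ion = top.molecules("ion")[0]
        contacts = [
            PlantedContact("water_bridge", (0, "O22"), (1, "O22"),
                           water=waters[2]),
            PlantedContact("hp", (2, "C22"), (3, "C22"),
                           geometry={"distance": 4.0}),
            PlantedContact("hp", (4, "C23"), (5, "C23"),
                           geometry={"distance": 6.0},
                           expected_detected=False),
            PlantedContact("ionic", (ion, "NA"), (6, "O13"),
                           geometry={"distance": 3.0}),
        ]
        planted, truth = plant_contacts(traj, top, contacts)
        assert (truth["water_bridge"], truth["hp"], truth["ionic"]) == (1, 1, 1)
        assert not truth["skipped"]
        records = detect_frame(planted.coords[0], top, box=planted.box)
        bridges = [r for r in records if r.kind == "water_bridge"]
        assert len(bridges) == 1
        w, i, j = bridges[0].atoms
        assert {top.names[i], top.names[j]} == {"O22"}
        hp = [r for r in records if r.kind == "hp"
              and r.scope == "lipid-lipid"]
        assert len(hp) == 1
        ionic = [r for r in records if r.kind == "ionic"]
        assert len(ionic) == 1 and ionic[0].solvent_ion

    def test_bridge_within_one_molecule_not_counted(self, sparse_spec):
        top = generate_topology(sparse_spec)
        traj = generate_trajectory(top, sparse_spec)
        waters = top.molecules("water")
        contacts = [PlantedContact("water_bridge", (0, "O13"), (0, "O14"),
                                   water=waters[3])]
        planted, _ = plant_contacts(traj, top, contacts)
        records = detect_frame(planted.coords[0], top, box=planted.box,
                               kinds=("water_bridge",))
        assert records == []
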