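"""Contact detectors against brute-force oracles and closed-form energies."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from memdyn.interactions import (InteractionParams, build_interaction_map,
                                 detect_hbonds, detect_hp_contacts,
                                 detect_ionic, detect_water_bridges,
                                 hbond_energy, interaction_time_series)

from conftest import (brute_hbonds, brute_ionic, brute_pairs, make_topology,
                      random_typed_topology)


class TestHbondEnergy:
    @pytest.mark.parametrize("d,theta,expected", [
        (2.1, 180.0, 25.0),        # optimum geometry
        (2.35, 180.0, 12.5),       # distance ramp halfway
        (2.6, 180.0, 0.0),         # distance zero point
        (3.5, 180.0, 0.0),         # beyond zero point
        (2.1, 100.0, 0.0),         # angle floor
        (2.1, 140.0, 12.5),        # angle ramp halfway
        (1.5, 180.0, 25.0),        # inside plateau
    ])
    def test_closed_form_values(self, d, theta, expected):
        assert hbond_energy(d, theta) == pytest.approx(expected, abs=1e-12)

    def test_default_threshold_is_quarter_of_optimum(self):
        params = InteractionParams()
        assert params.hb_threshold == 6.25
        assert params.hb_threshold == 0.25 * params.hb_optimal_energy

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.floats(1.0, 4.0), st.floats(1.0, 4.0),
           st.floats(90.0, 180.0), st.floats(90.0, 180.0))
    def test_monotone_in_distance_and_angle(self, d1, d2, t1, t2):
        d_lo, d_hi = sorted((d1, d2))
        t_lo, t_hi = sorted((t1, t2))
        assert hbond_energy(d_lo, t_lo) >= hbond_energy(d_hi, t_lo)
        assert hbond_energy(d_hi, t_lo) <= hbond_energy(d_hi, t_hi)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.floats(1.0, 4.0), st.floats(90.0, 180.0))
    def test_continuity(self, d, theta):
        eps = 1e-7
        assert hbond_energy(d + eps, theta) == pytest.approx(
            hbond_energy(d, theta), abs=1e-4)
        assert hbond_energy(d, min(theta + eps, 180.0)) == pytest.approx(
            hbond_energy(d, theta), abs=1e-4)

    def test_bounded_by_optimum(self):
        grid_d = np.linspace(0.5, 4.0, 40)
        grid_t = np.linspace(0.0, 180.0, 40)
        e = hbond_energy(grid_d[:, None], grid_t[None, :])
        assert np.all((0 <= e) & (e <= 25.0))


def _hbond_fixture():
    """Water donating to a lone acceptor at tunable geometry."""
    top = make_topology(
        ["O", "H", "H", "O"], mol_ids=[0, 0, 0, 1],
        kinds={0: "water", 1: "lipid"},
        donors=[0], acceptors=[0, 3], h_parent=[-1, 0, 0, -1])
    coords = np.array([[0.0, 0, 0], [1.0, 0, 0], [-0.3, -0.9, 0],
                       [3.1, 0, 0]])
    return top, coords


class TestHbondDetection:
    def test_ideal_geometry_detected(self):
        top, coords = _hbond_fixture()
        recs = detect_hbonds(coords, top)
        assert len(recs) == 1
        assert recs[0].atoms == (0, 1, 3)
        assert recs[0].energy == pytest.approx(25.0)
        assert recs[0].scope == "lipid-water"

    def test_exact_threshold_excluded(self):
        # angle ramp gives exactly 6.25 kJ/mol at theta = 120 deg: the
        # criterion is strict, so the bond must NOT be reported
        top, coords = _hbond_fixture()
        theta = np.radians(120.0)
        coords[3] = coords[1] + 2.1 * np.array(
            [-np.cos(theta), np.sin(theta), 0.0])
        assert hbond_energy(2.1, 120.0) == 6.25
        assert detect_hbonds(coords, top) == []

    def test_apolar_frame_empty(self):
        top = make_topology(["C", "C"], hydrophobic=[0, 1])
        assert detect_hbonds(np.zeros((2, 3)), top) == []

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    @pytest.mark.parametrize("use_box", [False, True])
    def test_matches_brute_force(self, seed, use_box):
        rng = np.random.default_rng(seed)
        box = (20.0, 18.0, 22.0)
        top, coords = random_typed_topology(rng, n_atoms=80, box=box)
        b = box if use_box else None
        got = sorted(r.atoms for r in detect_hbonds(coords, top, box=b))
        assert got == brute_hbonds(coords, top, box=b)


class TestPairDetectors:
    def test_hp_within_cutoff(self):
        top = make_topology(["C", "C"], mol_ids=[0, 1],
                            kinds={0: "lipid", 1: "lipid"},
                            hydrophobic=[0, 1])
        coords = np.array([[0.0, 0, 0], [4.0, 0, 0]])
        assert len(detect_hp_contacts(coords, top)) == 1
        coords[1, 0] = 6.0
        assert detect_hp_contacts(coords, top) == []

    def test_same_residue_excluded(self):
        top = make_topology(["C", "C"], hydrophobic=[0, 1])
        coords = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        assert detect_hp_contacts(coords, top) == []

    def test_like_charges_not_ionic(self):
        top = make_topology(["NA", "NA"], mol_ids=[0, 1],
                            kinds={0: "ion", 1: "ion"},
                            charges={0: 1, 1: 1})
        coords = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        assert detect_ionic(coords, top) == []

    def test_cation_to_phosphate_oxygen(self):
        top = make_topology(["NA", "O"], mol_ids=[0, 1],
                            kinds={0: "ion", 1: "lipid"},
                            charges={0: 1, 1: -1}, names=["NA", "O13"])
        coords = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        recs = detect_ionic(coords, top)
        assert len(recs) == 1 and recs[0].solvent_ion

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("use_box", [False, True])
    def test_match_brute_force(self, seed, use_box):
        rng = np.random.default_rng(100 + seed)
        box = (15.0, 15.0, 15.0)
        top, coords = random_typed_topology(rng, n_atoms=120, box=box)
        b = box if use_box else None
        params = InteractionParams()
        got_hp = sorted(r.atoms for r in detect_hp_contacts(coords, top, box=b))
        assert got_hp == brute_pairs(coords, top, top.is_hydrophobic,
                                     params.hp_cutoff, b, True)
        got_ion = sorted(tuple(sorted(r.atoms))
                         for r in detect_ionic(coords, top, box=b))
        assert got_ion == sorted(tuple(sorted(p))
                                 for p in brute_ionic(coords, top, box=b))


class TestWaterBridges:
    def _bridge_system(self):
        # water 0 bonded to O22 of two lipids; water far away as control
        top = make_topology(
            ["O", "H", "H", "O", "O", "O", "H", "H"],
            names=["O", "H1", "H2", "O22", "O22", "O", "H1", "H2"],
            mol_ids=[0, 0, 0, 1, 2, 3, 3, 3],
            kinds={0: "water", 1: "lipid", 2: "lipid", 3: "water"},
            donors=[0, 5], acceptors=[0, 3, 4, 5],
            h_parent=[-1, 0, 0, -1, -1, -1, 5, 5])
        coords = np.array([
            [0.0, 0, 0], [1.0, 0, 0], [0.0, 1.0, 0],
            [3.1, 0, 0], [0.0, 3.1, 0],
            [40.0, 40, 40], [41.0, 40, 40], [40.0, 41, 40]])
        return top, coords

    def test_bridge_between_two_lipids(self):
        top, coords = self._bridge_system()
        recs = detect_water_bridges(coords, top)
        assert len(recs) == 1
        assert recs[0].atoms == (0, 3, 4)
        assert recs[0].scope == "lipid-lipid"

    def test_no_waters_empty(self):
        top = make_topology(["O", "O"], mol_ids=[0, 1],
                            kinds={0: "lipid", 1: "lipid"}, acceptors=[0, 1])
        assert detect_water_bridges(np.zeros((2, 3)), top) == []

    def test_same_molecule_not_bridged(self):
        top, coords = self._bridge_system()
        top.molecule_ids[4] = 1          # both acceptors now in one lipid
        top.resids[4] = top.resids[3]
        top.molecule_kind.pop(2)
        top._mol_atoms = None
        assert detect_water_bridges(coords, top) == []


class TestInvariances:
    def _counts(self, coords, top, box=None):
        params = InteractionParams()
        return (len(detect_hbonds(coords, top, params, box)),
                len(detect_hp_contacts(coords, top, params, box)),
                len(detect_ionic(coords, top, params, box)),
                len(detect_water_bridges(coords, top, params, box)))

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(7)
        top, coords = random_typed_topology(rng, n_atoms=90)
        base = self._counts(coords, top)
        shifted = coords + np.array([13.0, -4.0, 2.5])
        assert self._counts(shifted, top) == base
        # proper rotation about a random axis
        from scipy.spatial.transform import Rotation
        rot = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
        rotated = coords @ rot.T
        assert self._counts(rotated, top) == base


class TestAggregation:
    def test_empty_records_zero_map(self):
        top = make_topology(["C"], hydrophobic=[0])
        assert build_interaction_map([], top).empty

    def test_lysine_to_phosphate_cell(self):
        # three H-bonds from residue 246 Lys NZ to O13 of one lipid
        top = make_topology(
            ["N", "H", "H", "H", "O"],
            names=["NZ", "H1", "H2", "H3", "O13"],
            resnames=["LYS"] * 4 + ["DPPC"],
            resids=[246, 246, 246, 246, 1],
            mol_ids=[0, 0, 0, 0, 1],
            kinds={0: "protein", 1: "lipid"},
            donors=[0], acceptors=[4], h_parent=[-1, 0, 0, 0, -1])
        from memdyn.interactions import InteractionRecord
        recs = [InteractionRecord("hbond", f, (0, 1 + f, 4), "protein-lipid",
                                  energy=20.0) for f in range(3)]
        m = build_interaction_map(recs, top)
        assert m.loc["246 Lys", "O13"] == 3
        assert m.to_numpy().sum() == len(recs)

    def test_map_total_conserves_records(self):
        rng = np.random.default_rng(17)
        top, coords = random_typed_topology(rng, n_atoms=150)
        recs = detect_hp_contacts(coords, top)
        m = build_interaction_map(recs, top, rows=("lipid", "atom_name"),
                                  cols=("lipid", "atom_name"))
        assert int(m.to_numpy().sum()) == len(recs)

    def test_time_series_conservation(self, sparse_spec):
        from memdyn.synthetic import (PlantedContact, generate_topology,
                                      generate_trajectory, plant_contacts)
        top = generate_topology(sparse_spec)
        traj = generate_trajectory(top, sparse_spec)
        prot = top.molecules("protein")[0]
        contacts = [
            PlantedContact("hbond", (prot, "OG"), (0, "O13")),
            PlantedContact("hbond", (prot, "OG1"), (1, "O13")),
            PlantedContact("hbond", (prot, "NZ"), (2, "O14")),
        ]
        planted, truth = plant_contacts(traj, top, contacts)
        series = interaction_time_series(planted, top, scope="protein-lipid",
                                         kinds=("hbond",))
        hb = series[series["kind"] == "hbond"]
        assert (hb["count"] == truth["hbond"]).all()     # static trajectory
        assert (hb["n_lipids"] == 3).all()
        assert (hb["per_lipid_min"] == 1).all()
        assert (hb["per_lipid_max"] == 1).all()
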