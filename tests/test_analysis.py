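"""Observables: torsions, Rg, secondary structure, H-bonds, RMSD, binning."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from camtube import analysis as A
from camtube.geometry import generate_conformation, nerf_place
from camtube.topology import CGAtom, CGTopology, Conformation, build_topology


def ca_only_system(points):
    points = np.atleast_2d(np.asarray(points, dtype=float))
    atoms = [CGAtom(i, "CA") for i in range(points.shape[0])]
    topo = CGTopology(["G"] * points.shape[0], atoms, bonds=[], angles=[],
                      dihedrals=[], impropers=[])
    return topo, Conformation(points)


class TestBackboneDihedrals:
    def test_helix_round_trip(self):
        topo = build_topology("A" * 8)
        conf = generate_conformation(topo, "ideal_helix")
        dih = A.backbone_dihedrals(conf, topo)
        assert np.isnan(dih[0, 0]) and np.isnan(dih[-1, 1])
        assert np.nanmax(np.abs(dih[1:, 0] + 57.0)) < 0.1
        assert np.nanmax(np.abs(dih[:-1, 1] + 47.0)) < 0.1

    def test_extended_round_trip(self):
        topo = build_topology("V" * 6)
        conf = generate_conformation(topo, "extended")
        dih = A.backbone_dihedrals(conf, topo)
        assert np.nanmax(np.abs(dih[1:, 0] + 120.0)) < 0.1
        assert np.nanmax(np.abs(dih[:-1, 1] - 120.0)) < 0.1

    def test_constructed_90_degree_torsion(self):
        from camtube.geometry import dihedral_angle

        a, b, c = np.array([1.1, 0.2, -0.3]), np.zeros(3), np.array([0.1, 1.3, 0.0])
        d = nerf_place(a, b, c, 0.15, 109.0, 90.0)
        assert dihedral_angle(a, b, c, d) == pytest.approx(90.0, abs=1e-6)

    def test_single_residue_chain_empty(self):
        topo = build_topology("A")
        conf = generate_conformation(topo, "extended")
        assert A.backbone_dihedrals(conf, topo).shape == (0, 2)


class TestRadiusOfGyration:
    def test_single_point_is_zero(self):
        topo, conf = ca_only_system([[0.3, 0.4, 0.5]])
        assert A.radius_of_gyration(conf, topo) == 0.0

    def test_two_points_half_distance(self):
        topo, conf = ca_only_system([[0, 0, 0], [1.0, 0, 0]])
        assert A.radius_of_gyration(conf, topo) == pytest.approx(0.5, abs=1e-12)

    def test_unit_square_closed_form(self):
        topo, conf = ca_only_system([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]])
        assert A.radius_of_gyration(conf, topo) == pytest.approx(
            math.sqrt(0.5), abs=1e-12)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(12, 3))
        topo, conf = ca_only_system(pts)
        rot = Rotation.from_euler("xyz", [10, 20, 30], degrees=True)
        topo2, conf2 = ca_only_system(rot.apply(pts) + 5.0)
        assert abs(A.radius_of_gyration(conf, topo)
                   - A.radius_of_gyration(conf2, topo2)) < 1e-9


class TestSSFragments:
    def test_ideal_helix_windows(self):
        topo = build_topology("A" * 12)
        conf = generate_conformation(topo, "ideal_helix")
        dih = A.backbone_dihedrals(conf, topo)
        assert A.count_ss_fragments(dih, "alpha") == 7
        assert A.count_ss_fragments(dih, "beta") == 0

    def test_extended_chain_is_beta_not_alpha(self):
        topo = build_topology("V" * 12)
        conf = generate_conformation(topo, "extended")
        dih = A.backbone_dihedrals(conf, topo)
        assert A.count_ss_fragments(dih, "alpha") == 0
        assert A.count_ss_fragments(dih, "beta") == 7

    def test_short_chain_has_no_windows(self):
        topo = build_topology("A" * 5)
        conf = generate_conformation(topo, "ideal_helix")
        dih = A.backbone_dihedrals(conf, topo)
        assert A.count_ss_fragments(dih, "alpha") == 0
        assert A.count_ss_fragments(dih, "beta") == 0

    def test_window_count_monotone_in_length(self):
        # appending residues with the same classification never loses windows
        for n in range(6, 15):
            dih = np.tile([-57.0, -47.0], (n, 1))
            assert (A.count_ss_fragments(dih, "alpha")
                    == max(0, n - 5))


class TestHbondDetection:
    def test_ideal_helix_i_to_i_plus_4(self):
        topo = build_topology("A" * 12)
        conf = generate_conformation(topo, "ideal_helix")
        pairs = A.detect_hbonds(conf, topo)
        # donor H of residue i+4 bonded to acceptor O of residue i
        expected = {(i + 4, i) for i in range(0, 8)}
        assert expected <= set(pairs)

    def test_extended_chain_has_none(self):
        topo = build_topology("V" * 12)
        conf = generate_conformation(topo, "extended")
        assert A.detect_hbonds(conf, topo) == []

    def test_zero_threshold_finds_nothing(self):
        topo = build_topology("A" * 12)
        conf = generate_conformation(topo, "ideal_helix")
        crit = A.HBondCriteria(distance=0.0)
        assert A.detect_hbonds(conf, topo, crit) == []

    def test_detected_pairs_lie_in_hbond_window(self, params):
        # every detected bond is also an attractive 10-12 pair
        topo = build_topology("A" * 12)
        conf = generate_conformation(topo, "ideal_helix")
        for don, acc in A.detect_hbonds(conf, topo):
            assert abs(don - acc) >= 4
            o = conf.coordinates[topo.atom_id(acc, "O")]
            h = conf.coordinates[topo.atom_id(don, "H")]
            assert np.linalg.norm(o - h) < params.hbond_cutoff


class TestStericMap:
    def test_basins_and_clash_points(self):
        assert A.steric_energy("A", -57.0, -47.0) == 0.0
        assert A.steric_energy("A", -120.0, 120.0) == 0.0
        assert A.steric_energy("A", 0.0, 0.0) > 0.0

    def test_left_handed_helix_allowed(self):
        assert A.steric_energy("A", 57.0, 47.0) == 0.0

    def test_allowed_set_shared_across_residues(self):
        # the alpha and beta basins are sterically allowed for every residue
        for aa in "AVGLKPSW":
            assert A.steric_energy(aa, -57.0, -47.0) == 0.0
            assert A.steric_energy(aa, -120.0, 120.0) == 0.0

    def test_coarse_map_shape_and_nonempty(self):
        phis, psis, e = A.steric_map("A", grid_step=30.0)
        assert e.shape == (12, 12)
        assert (e == 0).any() and (e > 0).any()


class TestRMSD:
    def test_identical_is_zero(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(8, 3))
        c = Conformation(pts)
        assert A.rmsd(c, Conformation(pts.copy())) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_copy_is_zero(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(8, 3))
        rot = Rotation.from_euler("zxz", [11, 62, -40], degrees=True)
        moved = rot.apply(pts) + np.array([0.3, -0.8, 2.0])
        assert A.rmsd(Conformation(pts), Conformation(moved)) < 1e-9

    def test_against_rotation_grid_oracle(self):
        # brute-force oracle: dense rotation sampling + local polish
        rng = np.random.default_rng(7)
        a = rng.normal(size=(4, 3))
        b = a.copy()
        b[2, 0] += 0.37  # single-coordinate displacement
        got = A.rmsd(Conformation(a), Conformation(b))

        ac = a - a.mean(axis=0)
        bc = b - b.mean(axis=0)

        def objective(rotvec):
            r = Rotation.from_rotvec(rotvec)
            return np.sqrt(((ac - r.apply(bc)) ** 2).sum(axis=1).mean())

        quats = rng.normal(size=(5000, 4))
        quats /= np.linalg.norm(quats, axis=1, keepdims=True)
        sampled = [(objective(Rotation.from_quat(q).as_rotvec()), q)
                   for q in quats]
        best_val, best_q = min(sampled, key=lambda t: t[0])
        assert got <= best_val + 1e-12  # optimal beats every sampled rotation

        from scipy.optimize import minimize

        polished = minimize(objective, Rotation.from_quat(best_q).as_rotvec(),
                            method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-14}).fun
        assert got == pytest.approx(polished, abs=1e-7)

    def test_selection_by_atom_kind(self):
        topo = build_topology("VAV")
        c1 = generate_conformation(topo, "extended")
        c2 = generate_conformation(topo, "ideal_helix")
        r_ca = A.rmsd(c1, c2, topo, selection={"CA"})
        r_all = A.rmsd(c1, c2)
        assert 0 < r_ca != r_all

    def test_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            A.rmsd(Conformation(np.zeros((3, 3))), Conformation(np.zeros((4, 3))))


class TestMicrostateBinning:
    def test_identical_frames_one_cell(self):
        table = A.bin_microstates(np.tile([0.3, 0.7], (10, 1)), [0.1, 0.1])
        assert table.n_microstates == 1
        assert list(table.populations.values()) == [10]

    def test_half_open_edges(self):
        table = A.bin_microstates(np.array([[0.0], [0.05]]), [0.05])
        assert table.n_microstates == 2

    def test_uniform_stream_exact_cell_count(self):
        values = (np.arange(1000) / 1000.0).reshape(-1, 1)  # uniform on [0,1)
        table = A.bin_microstates(values, [0.1])
        assert table.n_microstates == 10
        assert sum(table.populations.values()) == 1000

    def test_nonfinite_frames_skipped_with_warning(self):
        data = np.array([[0.1], [np.nan], [0.2]])
        with pytest.warns(UserWarning, match="skipped"):
            table = A.bin_microstates(data, [0.1])
        assert table.skipped == 1
        assert sum(table.populations.values()) + table.skipped == 3

    def test_partition_property(self):
        rng = np.random.default_rng(5)
        data = rng.normal(size=(500, 4))
        table = A.bin_microstates(data, [0.3, 0.2, 0.5, 0.5])
        members = [f for cell in table.cells.values() for f in cell]
        assert sorted(members) == list(range(500))

    def test_record_input(self):
        recs = [A.CVRecord(0.0, 1.0, 0.5, 2, 0),
                A.CVRecord(1.0, 1.0, 0.5, 2, 0)]
        table = A.bin_microstates(recs, [0.1, 0.05, 0.5, 0.5])
        assert table.n_microstates == 1

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            A.bin_microstates(np.zeros((3, 1)), [0.0])
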