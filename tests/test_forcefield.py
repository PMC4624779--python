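"""Energy terms: frozen spec values, separation windows, force correctness."""

import math

import numpy as np
import pytest

from camtube import energy as E
from camtube.params import ForceFieldParams
from camtube.topology import CGAtom, CGTopology, Conformation
from camtube.fixtures import ToyDimer

from conftest import numerical_forces, squashed_random_chain


def two_atom_system(kind_a: str, kind_b: str, res_a: int, res_b: int, r: float):
    """Two free atoms of given kinds at given residue indices and separation."""
    n_res = max(res_a, res_b) + 1
    seq = ["G"] * n_res
    atoms = [CGAtom(res_a, kind_a), CGAtom(res_b, kind_b)]
    topo = CGTopology(seq, atoms, bonds=[], angles=[], dihedrals=[], impropers=[])
    conf = Conformation(np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]]))
    return topo, conf


class TestTubeEnergy:
    def test_hh_pair_overlap_energy(self, params):
        # H-H threshold 0.23 nm, kappa 1e5: 1e5 * (0.23 - 0.20)^2 = 90
        topo, conf = two_atom_system("H", "H", 0, 3, 0.20)
        assert E.tube_energy(conf, topo, params)[0] == pytest.approx(90.0, abs=1e-9)

    def test_zero_exactly_at_threshold(self, params):
        topo, conf = two_atom_system("H", "H", 0, 3, 0.23)
        assert E.tube_energy(conf, topo, params)[0] == 0.0

    def test_zero_beyond_threshold(self, params):
        topo, conf = two_atom_system("CA", "CA", 0, 3, 0.45)
        assert E.tube_energy(conf, topo, params)[0] == 0.0

    def test_nearest_neighbour_window(self, params):
        # only O-O and H-H interact at |i-j| = 1
        topo, conf = two_atom_system("H", "H", 0, 1, 0.1)
        assert E.tube_energy(conf, topo, params)[0] > 0
        topo, conf = two_atom_system("CA", "CA", 0, 1, 0.1)
        assert E.tube_energy(conf, topo, params)[0] == 0.0

    def test_threshold_table_must_be_complete(self):
        table = ForceFieldParams().sphere_thresholds.copy()
        table.pop(("H", "H"))
        with pytest.raises(ValueError, match="16"):
            ForceFieldParams(sphere_thresholds=table)


class TestHbondEnergy:
    def test_well_depth_at_ideal_length(self, params):
        dimer = ToyDimer(0.2)
        e, _ = E.hbond_energy(dimer.conformation, dimer.topology, params)
        assert e == pytest.approx(-21.0, abs=1e-3)  # cutoff shift ~1.2e-4

    def test_frozen_value_at_quarter_nm(self, params):
        # 21 * (5 * 0.8^12 - 6 * 0.8^10) = -6.3136
        dimer = ToyDimer(0.25)
        e, _ = E.hbond_energy(dimer.conformation, dimer.topology, params)
        assert e == pytest.approx(-6.3136, abs=2e-4)

    def test_below_minimum_separation_window(self, params):
        topo, conf = two_atom_system("O", "H", 0, 3, 0.2)
        assert E.hbond_energy(conf, topo, params)[0] == 0.0

    def test_zero_at_cutoff(self, params):
        dimer = ToyDimer(0.8)
        assert E.hbond_energy(dimer.conformation, dimer.topology, params)[0] == 0.0

    def test_minimum_location_and_monotone_tail(self, params):
        r = np.linspace(0.16, 0.79, 400)
        e = params.hbond_pair_energy(r)
        assert r[np.argmin(e)] == pytest.approx(0.2, abs=2e-3)
        tail = params.hbond_pair_energy(np.linspace(0.201, 0.79, 200))
        assert np.all(np.diff(tail) > 0)


class TestDirectionality:
    def _ch_geometry(self, angle_deg: float, params):
        """C'...H distance from the law of cosines at given C'-O-H angle."""
        b, c = 0.1229, 0.2
        ang = math.radians(angle_deg)
        return math.sqrt(b * b + c * c - 2 * b * c * math.cos(ang))

    def test_linear_bond_unpenalised(self, params):
        r_ch = self._ch_geometry(180.0, params)
        assert r_ch > params.d_CH  # 0.3229 > 0.3197
        topo, conf = two_atom_system("C", "H", 0, 4, r_ch)
        assert E.hbond_directionality_energy(conf, topo, params)[0] == 0.0

    def test_bent_bond_penalised(self, params):
        r_ch = self._ch_geometry(120.0, params)
        assert r_ch == pytest.approx(0.28228, abs=1e-5)
        topo, conf = two_atom_system("C", "H", 0, 4, r_ch)
        e, _ = E.hbond_directionality_energy(conf, topo, params)
        assert e == pytest.approx(1e5 * (0.3197 - r_ch) ** 2, rel=1e-9)
        assert e == pytest.approx(140.0, abs=0.5)

    def test_short_separation_excluded(self, params):
        topo, conf = two_atom_system("C", "H", 0, 2, 0.28)
        assert E.hbond_directionality_energy(conf, topo, params)[0] == 0.0

    def test_on_pair_threshold(self, params):
        topo, conf = two_atom_system("O", "N", 0, 4, 0.25)
        e, _ = E.hbond_directionality_energy(conf, topo, params)
        assert e == pytest.approx(1e5 * (0.2980 - 0.25) ** 2, rel=1e-9)


class TestHydrophobic:
    def test_sigmoid_half_value_at_midpoint(self):
        p = ForceFieldParams(eps_W=10.0, B={("V", "V"): -1.0})
        topo = CGTopology(list("VGGV"), [CGAtom(0, "CB"), CGAtom(3, "CB")],
                          bonds=[], angles=[], dihedrals=[], impropers=[])
        conf = Conformation(np.array([[0.0, 0.0, 0.0], [0.8, 0.0, 0.0]]))
        e, _ = E.hydrophobic_energy(conf, topo, p)
        assert e == pytest.approx(-5.0, abs=1e-12)

    def test_negligible_far_outside_contact(self):
        p = ForceFieldParams(eps_W=10.0, B={("V", "V"): -1.0})
        topo = CGTopology(list("VGGV"), [CGAtom(0, "CB"), CGAtom(3, "CB")],
                          bonds=[], angles=[], dihedrals=[], impropers=[])
        conf = Conformation(np.array([[0.0, 0, 0], [2.0, 0, 0]]))
        assert abs(E.hydrophobic_energy(conf, topo, p)[0]) < 1e-12

    def test_polar_residue_contributes_nothing(self, params):
        # Ser is polar: the V-S pair is absent from the contact matrix
        topo = CGTopology(list("VGGS"), [CGAtom(0, "CB"), CGAtom(3, "CB")],
                          bonds=[], angles=[], dihedrals=[], impropers=[])
        for r in (0.3, 0.8, 1.0):
            conf = Conformation(np.array([[0.0, 0, 0], [r, 0, 0]]))
            assert E.hydrophobic_energy(conf, topo, params)[0] == 0.0

    def test_contact_matrix_symmetric_and_hydrophobic_only(self, params):
        from camtube.params import contact_matrix_array

        M, idx = contact_matrix_array(params.B)
        assert np.array_equal(M, M.T)
        assert M[idx["V"], idx["V"]] == pytest.approx(-1.0)
        for polar in "SDEKRNQHTGP":
            assert np.all(M[idx[polar]] == 0.0)

    def test_monotone_for_attractive_contact(self, params):
        r = np.linspace(0.05, 1.19, 300)
        e = params.hydrophobic_pair_energy(r, -1.0)
        assert np.all(np.diff(e) >= 0)


class TestCurvature:
    def test_frozen_example(self):
        p = ForceFieldParams(kappa_c=2000.0)
        topo, conf = two_atom_system("C", "H", 0, 2, 0.28)
        e, _ = E.curvature_energy(conf, topo, p)
        assert e == pytest.approx(2000 * (0.3197 - 0.28) ** 2, rel=1e-12)
        assert e == pytest.approx(3.1524, abs=1e-3)

    def test_zero_beyond_threshold(self, params):
        topo, conf = two_atom_system("C", "H", 0, 3, 0.35)
        assert E.curvature_energy(conf, topo, params)[0] == 0.0

    def test_window_excludes_long_separations(self, params):
        topo, conf = two_atom_system("C", "H", 0, 4, 0.28)
        assert E.curvature_energy(conf, topo, params)[0] == 0.0


class TestDihedrals:
    def _quad_at_angle(self, phi_deg: float):
        """Four points with torsion exactly phi_deg around the y-axis bond."""
        phi = math.radians(phi_deg)
        return np.array([
            [1.0, 0.0, 0.0],
            [0.0, 0.0, 0.0],
            [0.0, 1.0, 0.0],
            [math.cos(phi), 1.0, -math.sin(phi)],
        ])

    @pytest.mark.parametrize("phi,expected", [(180.0, 20.0), (0.0, 64.0)])
    def test_helical_group_frozen_values(self, phi, expected):
        # (V1, V2, V3) = (20, 10, 2), gamma = 0
        from camtube import _kernels as K

        pos = self._quad_at_angle(phi)
        F = np.zeros_like(pos)
        idx = np.array([0]), np.array([1]), np.array([2]), np.array([3])
        e = 0.0
        for v, mult in [(20.0, 1.0), (10.0, 2.0), (2.0, 3.0)]:
            e += K.dihedral_terms(pos, F, *idx, np.array([v]),
                                  np.array([0.0]), np.array([mult]), 1)
        assert e == pytest.approx(expected, abs=1e-9)

    def test_beta_group_v1_is_inactive(self, params):
        # the Val psi-like row has V1 = 0: no 1-periodic contribution
        terms = params.dihedral_table["psi_beta"]
        assert [t[0] for t in terms] == [0.0, 2.5, 2.5]

    def test_glycine_contributes_no_cb_terms(self, params):
        from camtube.topology import build_topology

        topo = build_topology("GGG")
        assert topo.dihedrals == []


class TestTotalEnergy:
    def test_extended_val5_no_tube_no_hbond(self, params):
        from camtube.topology import build_topology
        from camtube.geometry import generate_conformation

        topo = build_topology("V" * 5)
        conf = generate_conformation(topo, "extended")
        eb = E.total_energy(conf, topo, params)
        assert eb.tube == 0.0
        assert eb.hbond == 0.0

    def test_total_is_sum_of_terms(self, params):
        topo, conf = squashed_random_chain("VAVAV", seed=3)
        eb = E.total_energy(conf, topo, params)
        parts = (eb.tube + eb.hbond + eb.hbond_direction + eb.hydrophobic
                 + eb.curvature + eb.dihedral + eb.improper + eb.angle)
        assert eb.total == pytest.approx(parts, abs=1e-12)

    def test_rigid_motion_invariance(self, params):
        from scipy.spatial.transform import Rotation

        topo, conf = squashed_random_chain("VAVAV", seed=5)
        rot = Rotation.from_euler("zyx", [31.0, -57.0, 112.0], degrees=True)
        moved = Conformation(rot.apply(conf.coordinates) + np.array([1.0, -2.0, 0.5]))
        a = E.total_energy(conf, topo, params)
        b = E.total_energy(moved, topo, params)
        for key in a.as_dict():
            assert abs(a.as_dict()[key] - b.as_dict()[key]) < 1e-9

    def test_net_force_vanishes(self, params):
        topo, conf = squashed_random_chain("VAVAV", seed=8)
        eb = E.total_energy(conf, topo, params)
        assert np.abs(eb.forces.sum(axis=0)).max() < 1e-8

    def test_net_torque_vanishes(self, params):
        topo, conf = squashed_random_chain("VAVAV", seed=9)
        eb = E.total_energy(conf, topo, params)
        com = conf.coordinates.mean(axis=0)
        torque = np.cross(conf.coordinates - com, eb.forces).sum(axis=0)
        assert np.abs(torque).max() < 1e-8

    def test_shape_mismatch_rejected(self, params):
        from camtube.topology import build_topology

        topo = build_topology("VA")
        with pytest.raises(ValueError, match="atoms"):
            E.total_energy(Conformation(np.zeros((5, 3))), topo, params)


class TestPairList:
    def test_dipeptide_has_no_hbond_pairs(self, params):
        from camtube.topology import build_topology
        from camtube.geometry import generate_conformation

        topo = build_topology("VA")
        conf = generate_conformation(topo, "extended")
        assert E.pair_list(conf, topo, params)["hbond"] == []

    def test_oo_nearest_neighbours_in_tube_list(self, params):
        from camtube.topology import build_topology
        from camtube.geometry import generate_conformation

        topo = build_topology("V" * 8)
        conf = generate_conformation(topo, "extended")
        pl = E.pair_list(conf, topo, params)
        oo_nn = [(i, j, s) for i, j, s in pl["tube"]
                 if s == 1 and topo.atoms[i].kind == "O" and topo.atoms[j].kind == "O"]
        assert len(oo_nn) == 7

    def test_list_superset_of_contributing_pairs(self, params):
        topo, conf = squashed_random_chain("VAVAVA", seed=2)
        pl = E.pair_list(conf, topo, params)
        # every pair within any term's cutoff appears in that term's list
        pos = conf.coordinates
        listed = {(min(i, j), max(i, j)) for i, j, _ in pl["hbond"]}
        from camtube.energy import build_pair_tables

        t = build_pair_tables(topo, params)
        for o, h in zip(t.hb_o, t.hb_h):
            if np.linalg.norm(pos[o] - pos[h]) < params.hbond_cutoff:
                assert (min(o, h), max(o, h)) in listed


class TestGradients:
    @pytest.mark.parametrize("term", ["tube", "hbond", "dir", "phob", "curv",
                                      "dih", "impr", "ang"])
    def test_analytic_matches_central_difference(self, term, params):
        fns = {"tube": E.tube_energy, "hbond": E.hbond_energy,
               "dir": E.hbond_directionality_energy,
               "phob": E.hydrophobic_energy, "curv": E.curvature_energy,
               "dih": E.dihedral_energy, "impr": E.improper_energy,
               "ang": E.angle_energy}
        topo, conf = squashed_random_chain("VAVAV", seed=1)
        _, analytic = fns[term](conf, topo, params)
        numeric = numerical_forces(fns[term], conf, topo, params)
        err = np.abs(analytic - numeric) / np.maximum(np.abs(numeric), 1.0)
        assert err.max() < 1e-5


class TestParamValidation:
    def test_exponent_order_enforced(self):
        with pytest.raises(ValueError):
            ForceFieldParams(m=10, n=12)

    def test_negative_constants_rejected(self):
        with pytest.raises(ValueError):
            ForceFieldParams(eps_H=-1.0)

    def test_nonzero_polar_contact_rejected(self):
        with pytest.raises(ValueError):
            ForceFieldParams(B={("S", "V"): -1.0})

    def test_override_roundtrip(self, tmp_path):
        p = ForceFieldParams(eps_W=30.0, kappa_c=8000.0)
        path = tmp_path / "params.yaml"
        p.save(path)
        q = ForceFieldParams.from_file(path)
        assert q.eps_W == 30.0 and q.kappa_c == 8000.0

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "params.yaml"
        path.write_text("epsilon_HH: 3\n")
        with pytest.raises(ValueError, match="unknown"):
            ForceFieldParams.from_file(path)
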