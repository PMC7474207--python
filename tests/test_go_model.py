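import json

import numpy as np
import pytest

import gopull as gp
from gopull.go_model import (
    ContactMap,
    GoModelParams,
    GoTopology,
    SIGMA_FACTOR,
    build_contact_map_calpha,
)
from conftest import make_calpha_structure


def brute_force_contacts(structure, enlargement=1.24, min_sep=3):
    """Independent oracle: plain double loop over all heavy-atom pairs."""
    pairs = set()
    n = structure.n_residues
    for i in range(n):
        for j in range(i + min_sep, n):
            for a in structure.residues[i].heavy_atoms:
                for b in structure.residues[j].heavy_atoms:
                    d = np.linalg.norm(a.position - b.position)
                    if d < enlargement * (a.vdw_radius + b.vdw_radius):
                        pairs.add((i, j))
    return pairs


class TestContactMap:
    def test_three_residue_chain_empty(self):
        s = make_calpha_structure(np.arange(9.0).reshape(3, 3))
        assert len(gp.build_contact_map(s)) == 0

    def test_boundary_strictly_less(self):
        # heavy atoms of residues 0 and 4 at exactly the enlarged-radii sum
        cutoff = 1.24 * (1.70 + 1.70)
        ca = np.column_stack([np.arange(5) * 20.0, np.zeros(5), np.zeros(5)])
        extra = {
            0: [("CB", "C", (0.0, 10.0, 0.0))],
            4: [("CB", "C", (cutoff, 10.0, 0.0))],
        }
        s = make_calpha_structure(ca, extra)
        assert (0, 4) not in gp.build_contact_map(s)

        extra[4] = [("CB", "C", (cutoff - 0.01, 10.0, 0.0))]
        s = make_calpha_structure(ca, extra)
        cmap = gp.build_contact_map(s)
        assert (0, 4) in cmap
        # native distance is the Cα–Cα distance, not the heavy-atom one
        k = cmap.pairs.index((0, 4))
        assert cmap.native_distance[k] == pytest.approx(80.0)

    def test_matches_brute_force_oracle(self, bundle2):
        s, cmap, _ = bundle2
        assert set(map(tuple, cmap.pairs)) == brute_force_contacts(s)

    def test_matches_brute_force_on_four_bundle(self, bundle4):
        s, cmap, _ = bundle4
        assert set(map(tuple, cmap.pairs)) == brute_force_contacts(s)

    @pytest.mark.parametrize("pair", [(1.0, 1.24), (1.24, 1.5)])
    def test_monotone_in_enlargement(self, bundle2, pair):
        s, _, _ = bundle2
        lo = gp.build_contact_map(s, enlargement=pair[0])
        hi = gp.build_contact_map(s, enlargement=pair[1])
        assert set(map(tuple, lo.pairs)) <= set(map(tuple, hi.pairs))

    def test_min_sep_respected(self, bundle4):
        _, cmap, _ = bundle4
        assert all(j - i >= 3 for i, j in cmap.pairs)

    def test_no_heavy_atoms_error_mentions_fallback(self):
        s = make_calpha_structure(np.zeros((5, 3)))
        for r in s.residues:
            r.heavy_atoms = []
        with pytest.raises(ValueError, match="fallback"):
            gp.build_contact_map(s)

    def test_calpha_fallback(self):
        ca = np.array(
            [[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0], [7.6, 5.0, 0], [0.0, 5.0, 0]],
            dtype=float,
        )
        s = make_calpha_structure(ca)
        cmap = build_contact_map_calpha(s, cutoff=7.5)
        assert (0, 3) not in cmap  # d ≈ 9.4
        assert (0, 4) in cmap  # d = 5.0
        assert (1, 4) in cmap  # d ≈ 6.3

    def test_tsv_roundtrip(self, tmp_path, bundle2):
        _, cmap, _ = bundle2
        path = tmp_path / "map.tsv"
        cmap.to_tsv(str(path))
        back = ContactMap.from_tsv(str(path), cmap.n_residues)
        assert back.pairs == cmap.pairs
        np.testing.assert_allclose(back.native_distance, cmap.native_distance, atol=1e-6)


class TestTopology:
    def test_sigma_identity(self):
        ca = np.zeros((9, 3))
        ca[:, 0] = np.arange(9) * 3.8
        s = make_calpha_structure(ca)
        cmap = ContactMap([(0, 5)], np.array([6.0]), 9)
        topo = gp.build_topology(s, cmap)
        assert topo.nat_sigma[0] == pytest.approx(6.0 / SIGMA_FACTOR)
        assert topo.nat_sigma[0] == pytest.approx(5.346, abs=1e-3)

    def test_two_residue_chain(self):
        s = make_calpha_structure([[0, 0, 0], [3.8, 0, 0]])
        topo = gp.build_topology(s, ContactMap([], np.zeros(0), 2))
        assert len(topo.bond_i) == 1
        assert len(topo.chir_first) == 0
        assert topo.n_native_contacts == 0
        assert topo.bond_r0[0] == pytest.approx(3.8)

    def test_rebuild_identical(self, bundle2):
        s, cmap, topo = bundle2
        topo2 = gp.build_topology(s, cmap)
        for name in ("bond_r0", "chir_c0", "nat_sigma"):
            np.testing.assert_array_equal(getattr(topo, name), getattr(topo2, name))

    def test_contact_beyond_structure_raises(self):
        s = make_calpha_structure(np.zeros((4, 3)) + np.arange(4)[:, None])
        cmap = ContactMap([(0, 9)], np.array([5.0]), 10)
        with pytest.raises(ValueError, match="absent|inconsistent"):
            gp.build_topology(s, cmap)

    def test_repulsive_pairs_exclude_native_and_near(self, bundle2):
        _, cmap, topo = bundle2
        native = set(map(tuple, cmap.pairs))
        rep = set(zip(topo.rep_i.tolist(), topo.rep_j.tolist()))
        assert not (native & rep)
        assert all(j - i >= 3 for i, j in rep)
        n = topo.n_residues
        assert len(rep) + len(native) == sum(
            1 for i in range(n) for j in range(i + 3, n)
        )

    def test_json_roundtrip(self, tmp_path, bundle2):
        _, _, topo = bundle2
        path = tmp_path / "topo.json"
        topo.to_json(str(path))
        back = GoTopology.from_json(str(path))
        assert back.n_residues == topo.n_residues
        np.testing.assert_allclose(back.nat_sigma, topo.nat_sigma)
        np.testing.assert_allclose(back.native_positions, topo.native_positions)


def numerical_gradient(topology, positions, h=1e-6):
    """Central-difference oracle for −∇E."""
    grad = np.zeros_like(positions)
    for i in range(len(positions)):
        for d in range(3):
            p = positions.copy()
            p[i, d] += h
            ep = gp.energy_forces(topology, p)[0].total
            p[i, d] -= 2 * h
            em = gp.energy_forces(topology, p)[0].total
            grad[i, d] = -(ep - em) / (2 * h)
    return grad


class TestEnergyForces:
    def test_native_pair_minimum(self, two_bead_topology):
        pos = np.array([[0.0, 0, 0], [5.0, 0, 0]])
        e, f = gp.energy_forces(two_bead_topology, pos)
        assert e.native_lj == pytest.approx(-1.0, abs=1e-12)
        np.testing.assert_allclose(f, 0.0, atol=1e-9)

    def test_native_pair_zero_at_sigma(self, two_bead_topology):
        pos = np.array([[0.0, 0, 0], [5.0 / SIGMA_FACTOR, 0, 0]])
        e, _ = gp.energy_forces(two_bead_topology, pos)
        assert e.native_lj == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize(
        "r,expect_positive", [(4.0, False), (4.5, False), (3.5, True)]
    )
    def test_repulsive_truncation(self, r, expect_positive):
        topo = GoTopology(
            n_residues=2,
            bond_i=[], bond_j=[], bond_r0=[], bond_k=100.0,
            chir_first=[], chir_c0=[], chir_inv_norm=[], chirality_k=1.0,
            nat_i=[], nat_j=[], nat_sigma=[], epsilon=1.0,
            rep_i=[0], rep_j=[1], repulsive_cutoff=4.0,
        )
        pos = np.array([[0.0, 0, 0], [r, 0, 0]])
        e, _ = gp.energy_forces(topo, pos)
        if expect_positive:
            assert e.repulsive > 0
        else:
            assert e.repulsive == pytest.approx(0.0, abs=1e-12)

    def test_total_is_sum_of_terms(self, bundle2):
        s, _, topo = bundle2
        rng = np.random.default_rng(1)
        e, _ = gp.energy_forces(topo, s.ca_coords + rng.normal(0, 0.2, (topo.n_residues, 3)))
        assert e.total == pytest.approx(
            e.bonds + e.chirality + e.native_lj + e.repulsive + e.pulling_springs,
            abs=1e-10,
        )

    def test_forces_match_numerical_gradient(self, bundle2):
        s, _, topo = bundle2
        rng = np.random.default_rng(7)
        pos = s.ca_coords + rng.normal(0, 0.3, (topo.n_residues, 3))
        _, f = gp.energy_forces(topo, pos)
        num = numerical_gradient(topo, pos)
        scale = np.abs(f).max()
        assert np.abs(f - num).max() / scale < 1e-6

    @pytest.mark.parametrize("term", ["bonds", "chirality", "native", "repulsive"])
    def test_each_term_gradient(self, term, bundle2):
        s, cmap, full = bundle2
        # topology with a single active term
        empty = dict(
            bond_i=[], bond_j=[], bond_r0=[], bond_k=0.0,
            chir_first=[], chir_c0=[], chir_inv_norm=[], chirality_k=0.0,
            nat_i=[], nat_j=[], nat_sigma=[], epsilon=1.0,
            rep_i=[], rep_j=[], repulsive_cutoff=4.0,
        )
        parts = dict(empty)
        if term == "bonds":
            parts.update(bond_i=full.bond_i, bond_j=full.bond_j,
                         bond_r0=full.bond_r0, bond_k=full.bond_k)
        elif term == "chirality":
            parts.update(chir_first=full.chir_first, chir_c0=full.chir_c0,
                         chir_inv_norm=full.chir_inv_norm, chirality_k=1.0)
        elif term == "native":
            parts.update(nat_i=full.nat_i, nat_j=full.nat_j, nat_sigma=full.nat_sigma)
        else:
            parts.update(rep_i=full.rep_i, rep_j=full.rep_j)
        topo = GoTopology(n_residues=full.n_residues, **parts)
        rng = np.random.default_rng(11)
        pos = s.ca_coords + rng.normal(0, 0.3, (full.n_residues, 3))
        _, f = gp.energy_forces(topo, pos)
        num = numerical_gradient(topo, pos)
        scale = max(np.abs(f).max(), 1e-6)
        assert np.abs(f - num).max() / scale < 1e-5

    def test_translation_rotation_invariance(self, bundle2):
        s, _, topo = bundle2
        rng = np.random.default_rng(3)
        pos = s.ca_coords + rng.normal(0, 0.2, (topo.n_residues, 3))
        e0 = gp.energy_forces(topo, pos)[0].total
        # translation
        e1 = gp.energy_forces(topo, pos + np.array([13.0, -4.0, 2.0]))[0].total
        # proper rotation
        from scipy.spatial.transform import Rotation

        R = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
        e2 = gp.energy_forces(topo, pos @ R.T)[0].total
        assert abs(e1 - e0) < 1e-8
        assert abs(e2 - e0) < 1e-8

    def test_coincident_beads_raise(self, two_bead_topology):
        pos = np.zeros((2, 3))
        with pytest.raises(ValueError, match="coincident"):
            gp.energy_forces(two_bead_topology, pos)

    def test_native_state_energy(self, bundle4):
        s, cmap, topo = bundle4
        e, _ = gp.energy_forces(topo, s.ca_coords)
        assert e.native_lj == pytest.approx(-len(cmap), abs=1e-9)
        assert e.bonds == pytest.approx(0.0, abs=1e-9)
        assert e.chirality == pytest.approx(0.0, abs=1e-9)
        assert e.repulsive == pytest.approx(0.0, abs=1e-9)

    def test_shape_mismatch_raises(self, bundle2):
        _, _, topo = bundle2
        with pytest.raises(ValueError, match="shape"):
            gp.energy_forces(topo, np.zeros((3, 3)))


class TestParams:
    def test_custom_bond_k(self, bundle2):
        s, cmap, _ = bundle2
        topo = gp.build_topology(s, cmap, GoModelParams(bond_k=50.0))
        assert topo.bond_k == 50.0

    def test_uniform_well_depth_default(self, bundle2):
        _, _, topo = bundle2
        assert topo.epsilon == 1.0
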