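"""Featurization: scheme values, canonical sorting, metric properties."""

import itertools

import networkx as nx
import numpy as np
import pytest

from graph2struct import InputError, MolecularGraph, parse_smiles
from graph2struct.representations import (
    BagSpec,
    OutOfVocabularyError,
    bond_hop_matrix,
    bond_length_matrix,
    bond_order_rep,
    canonical_sort,
    distance_targets,
    fit_bag_spec,
    flla_rep,
    graph_bob_rep,
    graph_cm_matrix,
    represent,
)
from graph2struct.graphs import CrystalRecord


def _ring_graph(n_c: int) -> MolecularGraph:
    """Plain carbocycle with explicit hydrogens."""
    n = 3 * n_c
    z = np.array([6] * n_c + [1] * 2 * n_c)
    bom = np.zeros((n, n), dtype=int)
    for i in range(n_c):
        j = (i + 1) % n_c
        bom[i, j] = bom[j, i] = 1
    h = n_c
    for i in range(n_c):
        for _ in range(2):
            bom[i, h] = bom[h, i] = 1
            h += 1
    return MolecularGraph(z, bom)


class TestSchemeValues:
    def test_ethane_bond_order_single_entry(self):
        v = bond_order_rep(parse_smiles("CC"), n_max=3)
        assert sorted(v.values) == [0.0, 0.0, 1.0]

    def test_formaldehyde_double_bond_entry(self):
        v = bond_order_rep(parse_smiles("C=O"), n_max=2)
        assert list(v.values) == [2.0]

    def test_propane_hop_two(self):
        m = bond_hop_matrix(parse_smiles("CCC"))
        assert m.max() == 2

    def test_cyclohexane_max_hop_is_three(self):
        """Brute-force BFS on the 6-cycle gives an eccentricity of 3."""
        g = _ring_graph(6)
        m = bond_hop_matrix(g)
        gx = nx.from_numpy_array((g.heavy_bond_orders > 0).astype(float))
        brute = dict(nx.all_pairs_shortest_path_length(gx))
        for i in range(6):
            for j in range(6):
                assert m[i, j] == brute[i][j]
        assert m.max() == 3

    def test_bonded_cc_path_length(self, radii):
        m = bond_length_matrix(parse_smiles("CC"), radii)
        assert m[0, 1] == pytest.approx(2 * radii[6])

    def test_linear_ccc_path_length(self, radii):
        m = bond_length_matrix(parse_smiles("CCC"), radii)
        assert m.max() == pytest.approx(4 * radii[6])

    def test_graph_cm_entries(self, radii):
        m = graph_cm_matrix(parse_smiles("CC"), radii)
        assert m[0, 0] == pytest.approx(0.5 * 6**2.4)
        assert m[0, 1] == pytest.approx(36.0 / (2 * radii[6]))

    def test_graph_cm_decreasing_along_paths(self, radii, family_small):
        for g, _ in family_small[:8]:
            m = graph_cm_matrix(g, radii)
            hops = bond_hop_matrix(g)
            z = g.heavy_charges
            for i in range(g.n_heavy):
                same_z = [j for j in range(g.n_heavy) if j != i and z[j] == z[0]]
                # off-diagonals with equal charges shrink as hops grow
                pairs = sorted(same_z, key=lambda j: hops[i, j])
                for a, b in zip(pairs, pairs[1:]):
                    if hops[i, a] < hops[i, b] and z[a] == z[b]:
                        assert m[i, a] > m[i, b]

    def test_disconnected_graph_raises(self):
        z = np.array([6, 6])
        bom = np.zeros((2, 2), dtype=int)
        g = MolecularGraph(z, bom)
        with pytest.raises(InputError, match="disconnected"):
            bond_hop_matrix(g)


class TestPathOracle:
    """Shortest weighted/unweighted paths equal exhaustive enumeration."""

    @staticmethod
    def _brute_force(g, weight):
        n = g.n_heavy
        adj = g.heavy_bond_orders > 0
        gx = nx.from_numpy_array(adj.astype(float))
        out = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                best = np.inf
                for path in nx.all_simple_paths(gx, i, j):
                    cost = sum(
                        weight(a, b) for a, b in zip(path, path[1:])
                    )
                    best = min(best, cost)
                out[i, j] = out[j, i] = best
        return out

    def test_hop_matrix_matches_enumeration(self, family_small):
        for g, _ in family_small[:6]:
            brute = self._brute_force(g, lambda a, b: 1)
            assert np.allclose(bond_hop_matrix(g), brute)

    def test_length_matrix_matches_enumeration(self, family_small, radii):
        z = None
        for g, _ in family_small[:6]:
            z = g.heavy_charges
            brute = self._brute_force(
                g, lambda a, b: radii[int(z[a])] + radii[int(z[b])]
            )
            assert np.allclose(bond_length_matrix(g, radii), brute, atol=1e-9)

    def test_length_matrix_on_ring(self, radii):
        g = _ring_graph(5)
        brute = self._brute_force(g, lambda a, b: 2 * radii[6])
        assert np.allclose(bond_length_matrix(g, radii), brute, atol=1e-9)


class TestMetricProperties:
    @pytest.mark.parametrize("builder", ["hop", "length"])
    def test_symmetry_zero_diag_triangle(self, builder, family_small, radii):
        for g, _ in family_small[:10]:
            m = (
                bond_hop_matrix(g)
                if builder == "hop"
                else bond_length_matrix(g, radii)
            )
            assert np.allclose(m, m.T)
            assert np.all(np.diag(m) == 0)
            n = m.shape[0]
            for i, j, k in itertools.permutations(range(n), 3):
                assert m[i, j] <= m[i, k] + m[k, j] + 1e-9


class TestCanonicalSort:
    def test_already_sorted_identity(self):
        m = np.array([[0.0, 1.0], [1.0, 5.0]])
        _, _, perm = canonical_sort(m)
        assert list(perm) == [0, 1]

    def test_same_permutation_applied_to_distances(self, family_small, radii):
        g, geom = family_small[0]
        m = bond_length_matrix(g, radii)
        idx = list(g.heavy_indices)
        d = geom.distance_matrix()[np.ix_(idx, idx)]
        sm, sd, perm = canonical_sort(m, d, charges=g.heavy_charges)
        assert np.allclose(sm, m[np.ix_(perm, perm)])
        assert np.allclose(sd, d[np.ix_(perm, perm)])

    def test_tie_case_exhaustive_permutations(self, radii):
        """Isobutane has three equivalent methyl carbons; the sorted
        output must not depend on which input order they arrive in."""
        g = parse_smiles("CC(C)C")
        rng = np.random.default_rng(1)
        base = represent(g, "bond_length", 4, radii).values
        for _ in range(30):
            p = rng.permutation(g.n_atoms)
            v = represent(g.permuted(p), "bond_length", 4, radii).values
            assert np.array_equal(base, v)

    def test_norm_ordering_non_decreasing(self, family_small, radii):
        for g, _ in family_small[:10]:
            m = bond_length_matrix(g, radii)
            sm, _, _ = canonical_sort(m, charges=g.heavy_charges)
            norms = np.linalg.norm(sm, axis=1)
            assert np.all(np.diff(norms) >= -1e-9)


class TestPaddingAndTargets:
    def test_padding_neutrality(self, family_small, radii):
        for g, _ in family_small[:5]:
            small = represent(g, "bond_length", g.n_heavy, radii)
            big = represent(g, "bond_length", g.n_heavy + 2, radii)
            n, nb = g.n_heavy, g.n_heavy + 2
            iu_s = np.triu_indices(n, k=1)
            mat_b = np.zeros((nb, nb))
            mat_b[np.triu_indices(nb, k=1)] = big.values
            assert np.allclose(
                small.values, mat_b[: n, : n][iu_s]
            )
            # padded slots are exactly zero
            mask = np.ones((nb, nb), bool)
            mask[:n, :n] = False
            assert np.all(mat_b[np.triu_indices(nb, k=1)][mask[np.triu_indices(nb, k=1)]] == 0)

    def test_oversized_molecule_rejected(self, family_small, radii):
        g, _ = family_small[0]
        with pytest.raises(InputError, match="exceeds"):
            represent(g, "bond_length", g.n_heavy - 1, radii)

    def test_distance_targets_contract(self, family_small):
        g, geom = family_small[0]
        perm = tuple(range(g.n_heavy))
        t = distance_targets(geom, g.heavy_indices, perm, n_max=9)
        nz = t.values[t.values > 0]
        assert np.all(nz > 0.5)
        assert len(t.values) == 36

    def test_distance_targets_padding_zero_enforced(self):
        with pytest.raises(InputError):
            from graph2struct.representations import DistanceTargets

            DistanceTargets(values=np.ones(3), n_max=3, permutation=(0, 1))


class TestGraphBob:
    def test_ethane_bags(self, radii):
        g = parse_smiles("CC")
        bags = fit_bag_spec([g], radii)
        v = graph_bob_rep(g, radii, bags)
        spec = dict(bags.sizes)
        assert spec[("C",)] == 2
        assert spec[("C", "C")] == 1
        diag = 0.5 * 6**2.4
        assert sorted(v.values)[-2:] == pytest.approx([diag, diag])

    def test_bag_values_permute_cm_entries(self, family_small, radii):
        graphs = [g for g, _ in family_small[:6]]
        bags = fit_bag_spec(graphs, radii)
        for g in graphs:
            v = graph_bob_rep(g, radii, bags)
            m = graph_cm_matrix(g, radii)
            cm_entries = sorted(
                list(np.diag(m)) + list(m[np.triu_indices(g.n_heavy, k=1)])
            )
            bob_nonzero = sorted(x for x in v.values if x != 0)
            assert np.allclose(bob_nonzero, cm_entries)

    def test_out_of_vocabulary_error(self, radii):
        bags = fit_bag_spec([parse_smiles("CC")], radii)
        with pytest.raises(OutOfVocabularyError):
            graph_bob_rep(parse_smiles("CO"), radii, bags)

    def test_overflow_truncates_with_warning(self, radii, caplog):
        bags = fit_bag_spec([parse_smiles("CC")], radii)
        import logging

        with caplog.at_level(logging.WARNING):
            v = graph_bob_rep(parse_smiles("CCC"), radii, bags)
        assert "truncating" in caplog.text
        assert len(v.values) == bags.length

    def test_bagspec_roundtrip(self, family_small, radii):
        bags = fit_bag_spec([g for g, _ in family_small[:4]], radii)
        assert BagSpec.from_dict(bags.to_dict()) == bags


class TestFlla:
    def test_reference_crystal(self):
        c = CrystalRecord(("Al", "Na", "K", "F"), 8.0, np.zeros((1, 3)))
        assert list(flla_rep(c).values) == [3, 3, 3, 1, 4, 1, 2, 7]

    def test_d_site_changes_last_tuple_only(self):
        a = flla_rep(CrystalRecord(("Al", "Na", "K", "F"), 8.0, np.zeros((1, 3))))
        b = flla_rep(CrystalRecord(("Al", "Na", "K", "Cl"), 8.0, np.zeros((1, 3))))
        assert np.array_equal(a.values[:6], b.values[:6])
        assert not np.array_equal(a.values[6:], b.values[6:])

    def test_length_always_eight(self, crystals):
        assert all(len(flla_rep(c).values) == 8 for c in crystals[:20])

    def test_non_main_group_rejected(self):
        c = CrystalRecord(("Fe", "Na", "K", "F"), 8.0, np.zeros((1, 3)))
        with pytest.raises(ValueError, match="main-group"):
            flla_rep(c)
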