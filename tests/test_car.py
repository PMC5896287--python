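"""Graph handling, structure matrices, CAR conditionals and exact sampling."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import spacecohort as sc
from spacecohort.car import rw1_structure_matrix

from conftest import random_connected_graph


class TestAdjacencyGraph:
    def test_asymmetric_neighbors_rejected(self):
        with pytest.raises(sc.ValidationError, match="asymmetric"):
            sc.graph_from_neighbors(["a", "b"], [{1}, set()])

    def test_self_neighbor_rejected(self):
        with pytest.raises(sc.ValidationError, match="itself"):
            sc.graph_from_neighbors(["a"], [{0}])

    def test_n_i_matches_neighbor_sets(self, path3):
        assert list(path3.n_i) == [1, 2, 1]

    def test_components_of_disconnected_graph(self):
        g = sc.graph_from_edges(["a", "b", "c", "d"], [("a", "b"), ("c", "d")])
        comps = g.connected_components()
        assert [sorted(c) for c in comps] == [[0, 1], [2, 3]]

    def test_gal_round_trip(self, tmp_path, lattice5):
        path = tmp_path / "g.gal"
        sc.write_gal(lattice5, path)
        g2 = sc.read_gal(path)
        assert g2.area_ids == lattice5.area_ids
        assert g2.neighbors == lattice5.neighbors

    def test_gal_with_island(self, tmp_path):
        (tmp_path / "g.gal").write_text("3\na 1\nb\nb 1\na\nc 0\n")
        g = sc.read_gal(tmp_path / "g.gal")
        assert list(g.n_i) == [1, 1, 0]

    def test_edge_csv_reader(self, tmp_path):
        from spacecohort.car import read_edge_csv

        (tmp_path / "e.csv").write_text("a,b\nb,c\n")
        g = read_edge_csv(tmp_path / "e.csv")
        assert list(g.n_i) == [1, 2, 1]


class TestStructureMatrix:
    def test_path_graph_laplacian(self, path3):
        k = sc.build_structure_matrix(path3).dense()
        np.testing.assert_array_equal(k, [[1, -1, 0], [-1, 2, -1], [0, -1, 1]])

    def test_isolated_area_is_zero(self):
        g = sc.graph_from_neighbors(["a"], [set()])
        np.testing.assert_array_equal(sc.build_structure_matrix(g).dense(), [[0.0]])

    def test_equals_degree_minus_adjacency_on_random_graphs(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(2, 30))
            g = random_connected_graph(rng, n)
            k = sc.build_structure_matrix(g).dense()
            nxg = g.to_networkx()
            adj = nx.to_numpy_array(nxg)
            deg = np.diag(adj.sum(axis=1))
            np.testing.assert_array_equal(k, deg - adj)

    def test_psd_and_nullspace_dimension(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(2, 20))
            g1 = random_connected_graph(rng, n)
            g2 = random_connected_graph(rng, int(rng.integers(2, 10)))
            # disjoint union: two components
            ids = [f"x{a}" for a in g1.area_ids] + [f"y{a}" for a in g2.area_ids]
            off = g1.n_areas
            nb = [set(s) for s in g1.neighbors] + [{j + off for j in s} for s in g2.neighbors]
            g = sc.graph_from_neighbors(ids, nb)
            k = sc.build_structure_matrix(g).dense()
            evals = np.linalg.eigvalsh(k)
            assert evals.min() > -1e-10
            assert np.sum(np.abs(evals) < 1e-9) == 2
            assert sc.car_rank(g) == g.n_areas - 2

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(2, 12), st.integers(0, 2**31 - 1))
    def test_row_sums_zero_property(self, n, seed):
        g = random_connected_graph(np.random.default_rng(seed), n)
        k = sc.build_structure_matrix(g).dense()
        np.testing.assert_allclose(k.sum(axis=1), 0.0, atol=1e-12)
        np.testing.assert_array_equal(k, k.T)

    def test_coo_csv_writer(self, tmp_path, path3):
        k = sc.build_structure_matrix(path3)
        k.write_coo_csv(tmp_path / "k.csv")
        lines = (tmp_path / "k.csv").read_text().splitlines()
        assert lines[0] == "row,col,value"
        assert len(lines) == 1 + k.matrix.nnz


class TestFullConditional:
    def test_path_midpoint(self, path3):
        mean, prec = sc.car_full_conditional(np.array([0.2, 9.9, 0.4]), 1, 5.0, path3)
        assert mean == pytest.approx(0.3)
        assert prec == pytest.approx(10.0)

    def test_constant_field(self, lattice5):
        field = np.full(25, 1.7)
        for i in range(25):
            mean, _ = sc.car_full_conditional(field, i, 1.0, lattice5)
            assert mean == pytest.approx(1.7)

    def test_island_raises(self):
        g = sc.graph_from_neighbors(["a", "b", "c"], [{1}, {0}, set()])
        with pytest.raises(sc.ValidationError, match="island"):
            sc.car_full_conditional(np.zeros(3), 2, 1.0, g)

    @pytest.mark.parametrize("tau", [0.5, 2.0])
    def test_matches_numeric_conditionalization(self, tau):
        """Grid-integration oracle on every connected graph with <= 4 areas."""
        for n in (2, 3, 4):
            all_edges = list(itertools.combinations(range(n), 2))
            for r in range(n - 1, len(all_edges) + 1):
                for edge_set in itertools.combinations(all_edges, r):
                    ids = [str(i) for i in range(n)]
                    try:
                        g = sc.graph_from_edges(ids, [(str(a), str(b)) for a, b in edge_set])
                    except sc.ValidationError:
                        continue
                    if len(g.connected_components()) != 1:
                        continue
                    k = sc.build_structure_matrix(g).dense()
                    rng = np.random.default_rng(n * 100 + r)
                    field = rng.normal(size=n)
                    i = int(rng.integers(0, n))
                    grid = np.linspace(-12, 12, 4001)
                    f = np.tile(field, (grid.size, 1))
                    f[:, i] = grid
                    logw = -0.5 * tau * np.einsum("gi,ij,gj->g", f, k, f)
                    w = np.exp(logw - logw.max())
                    w /= w.sum()
                    mean_num = float(w @ grid)
                    var_num = float(w @ (grid - mean_num) ** 2)
                    mean, prec = sc.car_full_conditional(field, i, tau, g)
                    assert mean == pytest.approx(mean_num, abs=1e-6)
                    assert 1.0 / prec == pytest.approx(var_num, abs=1e-6)


class TestInteractionStructure:
    def test_identity_time_small_path(self):
        g = sc.graph_from_edges(["a", "b"], [("a", "b")])
        k_u = sc.build_structure_matrix(g)
        k = sc.build_interaction_structure(k_u, 2, "identity-time").dense()
        np.testing.assert_array_equal(np.diag(k), [1, 1, 1, 1])

    def test_isolated_area_gives_zero_matrix(self):
        g = sc.graph_from_neighbors(["a"], [set()])
        k_u = sc.build_structure_matrix(g)
        for variant in ("identity-time", "rw1-time"):
            k = sc.build_interaction_structure(k_u, 3, variant).dense()
            np.testing.assert_array_equal(k, np.zeros((3, 3)))

    def test_rw1_diagonal_doubles_inside(self, path3):
        """Conditional precisions are n_i at boundary cohorts, 2 n_i inside."""
        k_u = sc.build_structure_matrix(path3)
        k = sc.build_interaction_structure(k_u, 3, "rw1-time").dense()
        # area 'b' (index 1) has n_i = 2; its block occupies rows 3..5
        np.testing.assert_array_equal(np.diag(k)[3:6], [2, 4, 2])
        np.testing.assert_array_equal(np.diag(k)[0:3], [1, 2, 1])

    def test_matches_kronecker_oracle(self, lattice5):
        k_u = sc.build_structure_matrix(lattice5)
        t = 4
        k = sc.build_interaction_structure(k_u, t, "rw1-time").dense()
        np.testing.assert_array_equal(k, np.kron(k_u.dense(), rw1_structure_matrix(t).toarray()))

    def test_rejects_t_below_two(self, path3):
        with pytest.raises(sc.ValidationError):
            sc.build_interaction_structure(sc.build_structure_matrix(path3), 1)


class TestOmegaCovariance:
    def test_t2_matrix(self):
        cov = sc.build_omega_covariance(2, 1.0)
        np.testing.assert_array_equal(cov.matrix, [[1, -1], [-1, 1]])

    @pytest.mark.parametrize("t,s2", [(2, 1.0), (3, 0.5), (6, 2.0)])
    def test_row_sums_zero(self, t, s2):
        cov = sc.build_omega_covariance(t, s2)
        np.testing.assert_allclose(cov.matrix.sum(axis=1), 0.0, atol=1e-12)

    def test_t4_eigenvalues_and_rank(self):
        cov = sc.build_omega_covariance(4, 1.0)
        evals = np.sort(np.linalg.eigvalsh(cov.matrix))
        np.testing.assert_allclose(evals, [0.0, 4 / 3, 4 / 3, 4 / 3], atol=1e-12)

    def test_degenerate_t_raises(self):
        with pytest.raises(sc.ValidationError):
            sc.build_omega_covariance(1, 1.0)


class TestIntrinsicCarSampling:
    def test_component_sums_zero(self):
        g = sc.graph_from_edges(
            ["a", "b", "c", "d", "e"], [("a", "b"), ("b", "c"), ("d", "e")]
        )
        draw = sc.sample_intrinsic_car(g, 2.0, 123)
        assert abs(draw[:3].sum()) < 1e-10
        assert abs(draw[3:].sum()) < 1e-10

    def test_isolated_area_gets_zero(self):
        g = sc.graph_from_neighbors(["a", "b", "c"], [{1}, {0}, set()])
        draw = sc.sample_intrinsic_car(g, 1.0, 5)
        assert draw[2] == 0.0

    def test_seed_reproducibility(self, lattice5):
        d1 = sc.sample_intrinsic_car(lattice5, 3.0, 99)
        d2 = sc.sample_intrinsic_car(lattice5, 3.0, 99)
        np.testing.assert_array_equal(d1, d2)

    def test_covariance_matches_pseudoinverse(self):
        """Empirical covariance of 10,000 draws vs the Moore-Penrose oracle."""
        g = sc.graph_from_edges(["a", "b", "c", "d"], [("a", "b"), ("b", "c"), ("c", "d")])
        tau = 2.0
        rng = np.random.default_rng(2024)
        draws = np.array([sc.sample_intrinsic_car(g, tau, rng) for _ in range(10_000)])
        emp = np.cov(draws.T)
        oracle = np.linalg.pinv(sc.build_structure_matrix(g).dense()) / tau
        assert np.linalg.norm(emp - oracle) / np.linalg.norm(oracle) < 0.05

    def test_nonpositive_tau_rejected(self, path3):
        with pytest.raises(sc.ValidationError):
            sc.sample_intrinsic_car(path3, 0.0, 1)
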