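"""Adjacency construction, Laplacians, region averaging and CSV I/O."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fracbrain import (
    Connectome,
    ModelParameters,
    NetworkParameters,
    assemble_network_rhs,
    build_adjacency,
    build_laplacians,
    read_connectome,
    region_average,
    solve_rk4,
    write_connectome,
)


def make_connectome(edge_rows, n_nodes=3):
    ids = ["entorhinal", "fusiform", "precuneus", "cuneus", "brain-stem"]
    regions = ["limbic", "temporal", "parietal", "occipital", "brain stem"]
    nodes = pd.DataFrame(
        {
            "id": range(n_nodes),
            "x": np.zeros(n_nodes), "y": np.zeros(n_nodes), "z": np.zeros(n_nodes),
            "brain_id": ids[:n_nodes], "region": regions[:n_nodes],
        }
    )
    edges = pd.DataFrame(edge_rows, columns=["source", "target", "n_fibers", "length_mm"])
    return Connectome(nodes, edges)


class TestAdjacency:
    def test_single_edge_weight(self):
        conn = make_connectome([(0, 1, 4.0, 2.0)], n_nodes=2)
        A = build_adjacency(conn)
        assert A[0, 1] == A[1, 0] == 1.0
        assert np.all(np.diag(A) == 0)

    def test_no_edges_zero_matrix(self):
        conn = make_connectome([], n_nodes=2)
        assert np.all(build_adjacency(conn) == 0)

    def test_triangle_degree(self):
        conn = make_connectome([(0, 1, 1.0, 1.0), (0, 2, 2.0, 1.0), (1, 2, 3.0, 1.0)])
        A = build_adjacency(conn)
        assert A.sum(axis=1)[0] == pytest.approx(3.0)  # edges 1 and 2 meet at node 0


class TestLaplacians:
    def test_two_node_unit_laplacian(self):
        conn = make_connectome([(0, 1, 4.0, 2.0)], n_nodes=2)
        p = ModelParameters(rho_u=1.0)
        L = build_laplacians(build_adjacency(conn), p)
        np.testing.assert_allclose(L.u, [[1.0, -1.0], [-1.0, 1.0]])

    def test_zero_diffusivity_decouples(self):
        conn = make_connectome([(0, 1, 4.0, 2.0)], n_nodes=2)
        L = build_laplacians(build_adjacency(conn), ModelParameters(rho_v=0.0))
        assert np.all(L.v == 0)

    def test_structure_row_sums_symmetry_psd(self, default_params):
        rng = np.random.default_rng(0)
        n = 8
        A = rng.random((n, n)) * (rng.random((n, n)) < 0.4)
        A = np.triu(A, 1)
        A = A + A.T
        L = build_laplacians(A, default_params)
        for M in L.as_dict().values():
            np.testing.assert_allclose(M.sum(axis=1), 0.0, atol=1e-12)
            np.testing.assert_allclose(M, M.T, atol=1e-12)
            assert np.all(M - np.diag(np.diag(M)) <= 1e-12)
            eig = np.linalg.eigvalsh(M)
            assert eig[0] > -1e-10  # positive semidefinite
            # constant vector in the kernel
            np.testing.assert_allclose(M @ np.ones(n), 0.0, atol=1e-10)

    def test_negative_diffusivity_rejected(self):
        conn = make_connectome([(0, 1, 4.0, 2.0)], n_nodes=2)
        with pytest.raises(ValueError, match=">= 0"):
            build_laplacians(build_adjacency(conn), ModelParameters(rho_u=-1.0))


class TestRegionAverage:
    def test_uniform_vector(self):
        got = region_average(np.full(4, 3.3), ["a", "a", "b", "b"])
        assert np.all(got == 3.3)

    def test_simple_mean(self):
        got = region_average([0.1, 0.3], ["g", "g"])
        assert got["g"] == pytest.approx(0.2)

    def test_unequal_group_sizes(self):
        got = region_average([1.0, 0.0, 1.0], ["a", "b", "b"])
        assert got["a"] == 1.0 and got["b"] == 0.5

    def test_time_series_input(self):
        values = np.array([[1.0, 3.0, 5.0], [2.0, 4.0, 6.0]])  # (time, node)
        got = region_average(values, ["a", "a", "b"])
        np.testing.assert_allclose(got["a"], [2.0, 3.0])
        np.testing.assert_allclose(got["b"], [5.0, 6.0])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        values=st.lists(st.floats(-10, 10), min_size=4, max_size=12),
        labels=st.lists(st.sampled_from("abc"), min_size=4, max_size=12),
    )
    def test_group_mean_is_convex_combination(self, values, labels):
        n = min(len(values), len(labels))
        got = region_average(values[:n], labels[:n])
        assert np.all(got >= min(values[:n]) - 1e-12)
        assert np.all(got <= max(values[:n]) + 1e-12)


class TestValidationAndIO:
    def test_two_node_files_round_trip(self, tmp_path, fixtures):
        conn = fixtures["two_node"]
        nf, ef = tmp_path / "n.csv", tmp_path / "e.csv"
        write_connectome(conn, nf, ef)
        again = read_connectome(nf, ef)
        assert again.n_edges == 1
        pd.testing.assert_frame_equal(again.edges, conn.edges)
        assert set(again.seed_sets["tau"]) == set(conn.seed_sets["tau"])

    def test_self_loop_rejected_with_row(self):
        with pytest.raises(ValueError, match="self-loop.*\\[0\\]"):
            make_connectome([(0, 0, 1.0, 1.0)])

    def test_duplicate_edge_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            make_connectome([(0, 1, 1.0, 1.0), (1, 0, 2.0, 1.0)])

    def test_nonpositive_attributes_rejected(self):
        with pytest.raises(ValueError, match="n_fibers"):
            make_connectome([(0, 1, 0.0, 1.0)])
        with pytest.raises(ValueError, match="length_mm"):
            make_connectome([(0, 1, 1.0, 0.0)])

    def test_unknown_region_rejected(self):
        nodes = pd.DataFrame(
            {"id": [0], "x": [0.0], "y": [0.0], "z": [0.0],
             "brain_id": ["entorhinal"], "region": ["cerebellum"]}
        )
        with pytest.raises(ValueError, match="region"):
            Connectome(nodes, pd.DataFrame(columns=["source", "target", "n_fibers", "length_mm"]))

    def test_brain_id_region_mismatch_rejected(self):
        nodes = pd.DataFrame(
            {"id": [0], "x": [0.0], "y": [0.0], "z": [0.0],
             "brain_id": ["entorhinal"], "region": ["frontal"]}
        )
        with pytest.raises(ValueError, match="mismatch"):
            Connectome(nodes, pd.DataFrame(columns=["source", "target", "n_fibers", "length_mm"]))


class TestDiffusionConservation:
    def test_reaction_free_dynamics_conserve_species_totals(self, fixtures):
        """With all reaction rates zero the Laplacian coupling only moves
        mass between nodes: per-species totals are constant."""
        conn = fixtures["path3"]
        quiet = ModelParameters(
            a0=0, a1=0, a2=0, a1_tilde=0, b0=0, b1=0, b2=0, b1_tilde=0, b3=0,
            c0=0, c1=1.0, mu=0, k1=0, k2=0, k3=0, k4=0,
        )
        net = NetworkParameters(base=quiet)
        rhs = assemble_network_rhs(
            conn, build_laplacians(build_adjacency(conn), quiet), net
        )
        rng = np.random.default_rng(1)
        y0 = rng.random(6 * 3)
        y0[5 * 3 :] = 0.0  # damage block
        traj = solve_rk4(rhs, y0, 10.0, 0.01, store_every=100)
        for s in range(4):  # the four diffusing species
            totals = traj.states[:, s * 3 : (s + 1) * 3].sum(axis=1)
            np.testing.assert_allclose(totals, totals[0], atol=1e-10)
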