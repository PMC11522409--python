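"""Cross-correlation identities, matrices, graph metrics and Louvain."""

import networkx as nx
import numpy as np
import pytest

import meacircuit as mc
from meacircuit.connectivity import bin_trains, build_graph, correlation_matrices

from conftest import make_table


class TestBinTrains:
    def test_half_open_bin_edges(self, small_map):
        t = make_table({"C01": [0.049], "C02": [0.050]}, 0.2, small_map)
        b = mc.bin_trains(t, 0.050)
        i1 = b.electrode_ids.index("C01")
        i2 = b.electrode_ids.index("C02")
        assert b.counts[i1, 0] == 1 and b.counts[i1, 1] == 0
        assert b.counts[i2, 0] == 0 and b.counts[i2, 1] == 1

    def test_bin_count_and_conservation(self, small_map):
        rng = np.random.default_rng(0)
        t = make_table({"C01": np.sort(rng.uniform(0, 599.9, 500))}, 600.0, small_map)
        b = mc.bin_trains(t, 0.050)
        assert b.n_bins == 12000
        assert b.counts.sum() == 500


class TestMaxXcorr:
    def test_autocorrelation_unity_at_zero_lag(self):
        x = np.random.default_rng(1).poisson(2, 200).astype(float)
        r, lag = mc.max_xcorr(x, x)
        assert r == pytest.approx(1.0)
        assert lag == 0

    @pytest.mark.parametrize("shift", [1, 3, 7, 10])
    def test_exact_lag_recovery(self, shift):
        x = np.zeros(200)
        x[50] = 1.0
        y = np.roll(x, shift)
        r, lag = mc.max_xcorr(x, y)
        assert r == pytest.approx(1.0)
        assert abs(lag) == shift

    def test_shift_beyond_window_zero(self):
        x = np.zeros(200)
        x[50] = 1.0
        y = np.roll(x, 12)
        r, _ = mc.max_xcorr(x, y, max_lag=10)
        assert r == pytest.approx(0.0)

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        x = rng.poisson(1, 300).astype(float)
        y = rng.poisson(1, 300).astype(float)
        assert mc.max_xcorr(x, y)[0] == pytest.approx(mc.max_xcorr(y, x)[0])

    def test_all_zero_flagged(self):
        r, _ = mc.max_xcorr(np.zeros(100), np.ones(100))
        assert np.isnan(r)


class TestCorrelationMatrices:
    def test_identical_pooled_trains_internodal_unity(self):
        emap = mc.simulation_electrode_map(2)
        spikes = {e: np.arange(0.02, 10.0, 0.5) for e in emap.electrode_ids}
        t = mc.SpikeTable.from_arrays(spikes, 10.0, emap)
        s = correlation_matrices(bin_trains(t), emap)
        assert s.node_matrix[0, 1] == pytest.approx(1.0)
        assert s.node_matrix[0, 0] == pytest.approx(1.0)  # pairwise identical

    def test_independent_trains_low_internodal(self):
        # independent 10 Hz pooled node trains: without mean subtraction the
        # coefficient has a positive floor of lambda/(lambda+1) with lambda
        # counts per bin (= 1/3 at 0.5 counts / 50 ms), not zero
        rng = np.random.default_rng(3)
        emap = mc.simulation_electrode_map(2)
        spikes = {
            e: np.unique(np.sort(rng.uniform(0, 600.0, 3000)))  # 5 Hz each
            for e in emap.electrode_ids
        }
        t = mc.SpikeTable.from_arrays(spikes, 600.0, emap)
        s = correlation_matrices(bin_trains(t), emap)
        off = s.node_matrix[~np.eye(4, dtype=bool)]
        assert np.nanmax(off) < 0.35
        assert np.nanmin(off) > 0.2  # the floor is real and positive

    def test_single_electrode_node_intranodal_missing(self):
        emap = mc.ElectrodeMap([("c1", "C"), ("c2", "C"), ("h1", "H1")])
        t = mc.SpikeTable.from_arrays(
            {"c1": [0.1, 0.6], "c2": [0.1, 0.6], "h1": [0.3]}, 2.0, emap
        )
        s = correlation_matrices(bin_trains(t), emap)
        assert np.isnan(s.node_matrix[1, 1])
        assert s.node_matrix[0, 0] == pytest.approx(1.0)

    def test_tunnel_in_electrode_matrix_not_node_aggregates(self):
        emap = mc.ElectrodeMap([("c1", "C"), ("c2", "C"), ("t1", "TUNNEL")])
        t = mc.SpikeTable.from_arrays(
            {"c1": [0.1], "c2": [0.1], "t1": [0.1]}, 2.0, emap
        )
        s = correlation_matrices(bin_trains(t), emap)
        assert "t1" in s.electrode_ids
        i = s.electrode_ids.index("t1")
        assert np.isfinite(s.electrode_matrix[i, 0])


class TestGraph:
    def _summary(self, mat, ids):
        from meacircuit.connectivity import ConnectivitySummary

        return ConnectivitySummary(ids, np.asarray(mat, float),
                                   np.zeros_like(mat, dtype=int),
                                   np.full((4, 4), np.nan))

    def test_weak_edges_dropped_boundary_kept(self):
        ids = ["a", "b", "c"]
        mat = np.array([[1.0, 0.05, 0.1], [0.05, 1.0, 0.5], [0.1, 0.5, 1.0]])
        g = build_graph(self._summary(mat, ids), 0.1)
        assert not g.has_edge("a", "b")
        assert g.has_edge("a", "c")       # exactly at threshold: kept
        assert g.has_edge("b", "c")

    def test_all_weak_matrix_edgeless(self):
        ids = ["a", "b"]
        g = build_graph(self._summary([[1.0, 0.05], [0.05, 1.0]], ids), 0.1)
        assert g.number_of_edges() == 0
        comm, q = mc.louvain_modularity(g)
        assert np.isnan(q)

    def test_four_block_matrix_four_components(self):
        n = 8
        ids = [f"e{i}" for i in range(n)]
        mat = np.full((n, n), 0.05)
        for b in range(4):
            mat[2 * b : 2 * b + 2, 2 * b : 2 * b + 2] = 0.8
        np.fill_diagonal(mat, 1.0)
        g = build_graph(self._summary(mat, ids), 0.1)
        assert nx.number_connected_components(g) == 4


class TestLouvain:
    def test_two_triangles_modularity_half(self):
        g = nx.Graph()
        g.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)],
                         weight=1.0)
        comm, q = mc.louvain_modularity(g, n_restarts=10, seed=0)
        assert q == pytest.approx(0.5)
        assert len(set(comm.values())) == 2

    def test_planted_four_block_recovered(self):
        emap = mc.simulation_electrode_map(10)
        ids = emap.electrode_ids
        n = len(ids)
        mat = np.full((n, n), 0.05)
        for b in range(4):
            mat[10 * b : 10 * b + 10, 10 * b : 10 * b + 10] = 0.8
        np.fill_diagonal(mat, 1.0)
        from meacircuit.connectivity import ConnectivitySummary

        summary = ConnectivitySummary(ids, mat, np.zeros((n, n), int),
                                      np.full((4, 4), np.nan))
        g = build_graph(summary, 0.1, electrode_map=emap)
        comm, q = mc.louvain_modularity(g, n_restarts=20, seed=1)
        assert len(set(comm.values())) == 4
        assert q >= 0.3
        for node in mc.NODE_ORDER:
            labels = {comm[e] for e in emap.electrodes_in(node)}
            assert len(labels) == 1

    def test_uniform_complete_graph_no_structure(self):
        g = nx.complete_graph(12)
        nx.set_edge_attributes(g, 1.0, "weight")
        _, q = mc.louvain_modularity(g, n_restarts=20, seed=2)
        assert q <= 0.05

    def test_seeded_reproducibility(self):
        g = nx.les_miserables_graph()
        a = mc.louvain_modularity(g, n_restarts=5, seed=7)
        b = mc.louvain_modularity(g, n_restarts=5, seed=7)
        assert a == b


class TestPagerank:
    def test_two_nodes_symmetric(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=1.0)
        pr = mc.pagerank(g)
        assert pr["a"] == pytest.approx(0.5)
        assert sum(pr.values()) == pytest.approx(1.0, abs=1e-9)

    def test_star_centre_dominates(self):
        g = nx.star_graph(4)
        nx.set_edge_attributes(g, 1.0, "weight")
        pr = mc.pagerank(g)
        assert pr[0] > max(pr[i] for i in range(1, 5))
        assert sum(pr.values()) == pytest.approx(1.0, abs=1e-9)

    def test_isolated_vertex_against_power_iteration_oracle(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=1.0)
        g.add_node("c")
        pr = mc.pagerank(g, damping=0.85)
        # independent oracle: explicit power iteration with the dangling
        # convention of spreading an isolated node's mass uniformly
        v = np.full(3, 1 / 3)
        for _ in range(500):
            new = np.zeros(3)
            new[0] += 0.85 * v[1]          # b -> a
            new[1] += 0.85 * v[0]          # a -> b
            new += 0.85 * v[2] / 3         # dangling c spreads uniformly
            new += 0.15 / 3
            v = new
        expect = {"a": v[0], "b": v[1], "c": v[2]}
        for k in expect:
            assert pr[k] == pytest.approx(expect[k], abs=1e-6)
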