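"""Functional connectivity: binned lagged cross-correlation, correlation
matrices, thresholded graphs, Louvain communities and pagerank.

Spike trains are binned into 50 ms counts and compared with time-shifted
copies up to a maximum lag of 10 bins (500 ms); the coefficient is normalized
so that autocorrelations at zero lag equal 1 (no mean subtraction, which
leaves a positive floor for independent high-rate trains — documented and
tested rather than hidden).  The pairwise maximum over +-lags makes the
matrices symmetric and direction-free.

Intranodal connectivity is the average pairwise coefficient between a node's
electrodes; internodal connectivity correlates the nodes' summed trains, which
suppresses variability from unequal active-electrode counts.  Tunnel
electrodes appear in the electrode-level matrix and graphs but never in node
aggregates.  Graphs keep edges with coefficient >= 0.1, and community
structure is the best of ``n_restarts`` seeded Louvain runs scored by weighted
modularity Q.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .types import ConfigError, ElectrodeMap, NODE_ORDER, SpikeTable, TUNNEL


@dataclass
class BinnedTrains:
    bin_width: float
    counts: np.ndarray              # electrodes x bins, non-negative ints
    electrode_ids: list[str]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]


def bin_trains(table: SpikeTable, bin_width: float = 0.050) -> BinnedTrains:
    """Spike counts per electrode per half-open ``bin_width`` bin."""
    if bin_width <= 0:
        raise ConfigError("bin_width must be > 0")
    n_bins = math.ceil(table.duration / bin_width)
    ids = table.electrode_map.electrode_ids
    counts = np.zeros((len(ids), n_bins), dtype=np.int64)
    by = table.by_electrode()
    for i, eid in enumerate(ids):
        c, _ = np.histogram(by[eid], bins=n_bins, range=(0.0, n_bins * bin_width))
        counts[i] = c
    return BinnedTrains(bin_width, counts, list(ids))


def max_xcorr(x: np.ndarray, y: np.ndarray, max_lag: int = 10) -> tuple[float, int]:
    """Maximum normalized cross-correlation over lags in [-max_lag, max_lag].

    r(l) = sum_t x_t * y_{t+l} / sqrt(sum x^2 * sum y^2).  Ties between lags
    break toward the smallest |l|, then the negative lag.  Returns
    (NaN, 0) when either series is all-zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ConfigError("series must have equal length")
    if x.size < 2 * max_lag + 1:
        raise ConfigError("series shorter than the lag window")
    ex, ey = float(np.dot(x, x)), float(np.dot(y, y))
    if ex == 0.0 or ey == 0.0:
        return float("nan"), 0
    denom = math.sqrt(ex * ey)
    best_r, best_lag = -np.inf, 0
    for lag in sorted(range(-max_lag, max_lag + 1), key=lambda l: (abs(l), l)):
        # r(l) = sum_t x_t y_{t+l}
        if lag >= 0:
            r = float(np.dot(x[: x.size - lag], y[lag:])) / denom
        else:
            r = float(np.dot(x[-lag:], y[: y.size + lag])) / denom
        if r > best_r + 1e-15:
            best_r, best_lag = r, lag
    return best_r, best_lag


@dataclass
class ConnectivitySummary:
    electrode_ids: list[str]
    electrode_matrix: np.ndarray    # max-lagged coefficients, symmetric
    lag_matrix: np.ndarray          # best lag in bins (sign = shift direction)
    node_matrix: np.ndarray         # 4x4; diag = mean pairwise intranodal
    node_order: tuple[str, ...] = NODE_ORDER
    bin_width: float = 0.050
    max_lag_bins: int = 10


def correlation_matrices(
    binned: BinnedTrains,
    electrode_map: ElectrodeMap,
    max_lag: int = 10,
) -> ConnectivitySummary:
    """Electrode-level and node-level (4x4) max-lagged correlation matrices.

    Node diagonal = mean pairwise coefficient within the node (NaN with < 2
    contributing electrodes); off-diagonal = coefficient between the nodes'
    summed trains.  Tunnel electrodes stay out of the node aggregates.
    """
    ids = binned.electrode_ids
    n = len(ids)
    mat = np.full((n, n), np.nan)
    lags = np.zeros((n, n), dtype=int)
    nonzero = binned.counts.any(axis=1)
    for i in range(n):
        mat[i, i] = 1.0 if nonzero[i] else np.nan
        for j in range(i + 1, n):
            if not (nonzero[i] and nonzero[j]):
                continue
            r, lag = max_xcorr(binned.counts[i], binned.counts[j], max_lag)
            mat[i, j] = mat[j, i] = r
            lags[i, j] = lag
            lags[j, i] = -lag

    idx_of = {eid: i for i, eid in enumerate(ids)}
    node_mat = np.full((len(NODE_ORDER), len(NODE_ORDER)), np.nan)
    node_idx = {
        node: [idx_of[e] for e in electrode_map.electrodes_in(node) if e in idx_of]
        for node in NODE_ORDER
    }
    for a, node_a in enumerate(NODE_ORDER):
        members = [i for i in node_idx[node_a] if nonzero[i]]
        if len(members) >= 2:
            vals = [
                mat[i, j]
                for k, i in enumerate(members)
                for j in members[k + 1 :]
                if np.isfinite(mat[i, j])
            ]
            if vals:
                node_mat[a, a] = float(np.mean(vals))
        for b in range(a + 1, len(NODE_ORDER)):
            ia, ib = node_idx[node_a], node_idx[NODE_ORDER[b]]
            if not ia or not ib:
                continue
            xa = binned.counts[ia].sum(axis=0)
            xb = binned.counts[ib].sum(axis=0)
            if xa.any() and xb.any():
                r, _ = max_xcorr(xa, xb, max_lag)
                node_mat[a, b] = node_mat[b, a] = r
    return ConnectivitySummary(
        list(ids), mat, lags, node_mat, NODE_ORDER, binned.bin_width, max_lag
    )


@dataclass
class GraphSummary:
    graph: nx.Graph
    communities: dict[str, int]
    modularity: float
    pagerank: dict[str, float]
    edge_threshold: float

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.graph.number_of_nodes(),
            "n_edges": self.graph.number_of_edges(),
            "edge_threshold": self.edge_threshold,
            "modularity": self.modularity,
            "n_communities": len(set(self.communities.values())),
            "communities": dict(sorted(self.communities.items())),
            "pagerank": dict(sorted(self.pagerank.items())),
        }


def build_graph(
    summary: ConnectivitySummary,
    edge_threshold: float = 0.1,
    firing_rates: dict[str, float] | None = None,
    electrode_map: ElectrodeMap | None = None,
) -> nx.Graph:
    """Weighted undirected electrode graph; edges with coefficient < threshold
    are removed ("weaker than 0.1"), so exactly-threshold edges survive."""
    g = nx.Graph()
    for eid in summary.electrode_ids:
        attrs = {}
        if firing_rates is not None:
            attrs["firing_rate_hz"] = firing_rates.get(eid, 0.0)
        if electrode_map is not None:
            attrs["node_label"] = electrode_map.node_of(eid)
        g.add_node(eid, **attrs)
    n = len(summary.electrode_ids)
    for i in range(n):
        for j in range(i + 1, n):
            w = summary.electrode_matrix[i, j]
            if np.isfinite(w) and w >= edge_threshold:
                g.add_edge(
                    summary.electrode_ids[i],
                    summary.electrode_ids[j],
                    weight=float(w),
                )
    return g


def louvain_modularity(
    graph: nx.Graph,
    gamma: float = 1.0,
    n_restarts: int = 100,
    seed: int = 0,
) -> tuple[dict[str, int], float]:
    """Best-of-``n_restarts`` seeded Louvain partition and its weighted
    modularity Q.  Community ids are contiguous integers ordered by each
    community's smallest member for reproducibility.  Edgeless graph -> Q is
    NaN and every node its own community."""
    if graph.number_of_edges() == 0:
        return {v: i for i, v in enumerate(sorted(graph.nodes))}, float("nan")
    rng = np.random.default_rng(seed)
    best_q, best_parts = -np.inf, None
    for _ in range(max(int(n_restarts), 1)):
        parts = nx.community.louvain_communities(
            graph,
            weight="weight",
            resolution=gamma,
            seed=int(rng.integers(2**31 - 1)),
        )
        q = nx.community.modularity(graph, parts, weight="weight", resolution=gamma)
        if q > best_q:
            best_q, best_parts = q, parts
    ordered = sorted(best_parts, key=lambda c: min(c))
    assignment = {v: i for i, comm in enumerate(ordered) for v in sorted(comm)}
    return assignment, float(best_q)


def pagerank(graph: nx.Graph, damping: float = 0.85) -> dict[str, float]:
    """Weighted pagerank; scores sum to 1."""
    if graph.number_of_nodes() == 0:
        raise ConfigError("graph is empty")
    return nx.pagerank(graph, alpha=damping, weight="weight")
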