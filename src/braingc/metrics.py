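"""Graph statistics of a directed brain functional network.

Degrees and shortest-path statistics (characteristic path length L, global
efficiency E_global) are computed on the directed graph with unit hop
distances. L averages over *reachable* ordered pairs only (its count of
unreachable pairs is reported alongside); E_global assigns unreachable pairs
an efficiency of 0, its natural limit. The clustering coefficient uses the
undirected formula C_i = 2 E_i / (k_i (k_i - 1)) on the symmetrized graph,
with C_i = 0 for nodes of fewer than two neighbours, and the network-level C
is the mean over all N nodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .network import DirectedNetwork

__all__ = [
    "NetworkMetrics",
    "degrees",
    "characteristic_path_length",
    "clustering",
    "global_efficiency",
    "network_metrics",
]


@dataclass
class NetworkMetrics:
    """Per-node degrees and clustering plus whole-network summaries."""

    node_labels: tuple[str, ...]
    in_degree: np.ndarray
    out_degree: np.ndarray
    total_degree: np.ndarray
    node_clustering: np.ndarray
    mean_clustering: float
    char_path_length: float  # NaN when no ordered pair is reachable
    global_efficiency: float
    n_unreachable_pairs: int


def _digraph(net: DirectedNetwork) -> nx.DiGraph:
    g = nx.from_numpy_array(net.adjacency.astype(int), create_using=nx.DiGraph)
    return g


def degrees(net: DirectedNetwork) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(in, out, total) degree per node; in counts edges into the node."""
    adj = net.adjacency
    in_deg = adj.sum(axis=0).astype(int)
    out_deg = adj.sum(axis=1).astype(int)
    return in_deg, out_deg, in_deg + out_deg


def _pair_distances(net: DirectedNetwork) -> tuple[np.ndarray, int]:
    """Directed hop distances over reachable ordered pairs, and the number of
    unreachable ordered pairs."""
    n = net.n_nodes
    lengths = dict(nx.all_pairs_shortest_path_length(_digraph(net)))
    dists = [
        d
        for i, row in lengths.items()
        for j, d in row.items()
        if i != j
    ]
    n_pairs = n * (n - 1)
    return np.asarray(dists, dtype=float), n_pairs - len(dists)


def characteristic_path_length(net: DirectedNetwork) -> tuple[float, int]:
    """Mean directed shortest-path length over reachable ordered pairs.

    Returns (L, n_unreachable_pairs); L is NaN when no pair is reachable
    (the average is undefined on a fully disconnected digraph).
    """
    if net.n_nodes < 2:
        raise ValueError("path length requires >= 2 nodes")
    dists, n_unreachable = _pair_distances(net)
    if dists.size == 0:
        return float("nan"), n_unreachable
    return float(dists.mean()), n_unreachable


def clustering(net: DirectedNetwork) -> tuple[np.ndarray, float]:
    """Per-node and mean clustering on the symmetrized graph.

    An undirected edge joins i and j iff either direction is present; the
    directed-clustering alternative (fraction of realised directed triangles)
    is not what the unweighted 2E/k(k-1) formula describes and is not used.
    """
    sym = net.adjacency | net.adjacency.T
    g = nx.from_numpy_array(sym.astype(int))
    cdict = nx.clustering(g)
    ci = np.array([cdict[i] for i in range(net.n_nodes)], dtype=float)
    return ci, float(ci.mean())


def global_efficiency(net: DirectedNetwork) -> float:
    """Mean inverse directed shortest-path length over ordered pairs;
    unreachable pairs contribute 0."""
    if net.n_nodes < 2:
        raise ValueError("global efficiency requires >= 2 nodes")
    dists, _ = _pair_distances(net)
    n_pairs = net.n_nodes * (net.n_nodes - 1)
    if dists.size == 0:
        return 0.0
    return float(np.sum(1.0 / dists) / n_pairs)


def network_metrics(net: DirectedNetwork) -> NetworkMetrics:
    """All network statistics in one pass."""
    in_deg, out_deg, tot = degrees(net)
    ci, c_mean = clustering(net)
    length, n_unreach = characteristic_path_length(net)
    eff = global_efficiency(net)
    return NetworkMetrics(
        node_labels=net.node_labels,
        in_degree=in_deg,
        out_degree=out_deg,
        total_degree=tot,
        node_clustering=ci,
        mean_clustering=c_mean,
        char_path_length=length,
        global_efficiency=eff,
        n_unreachable_pairs=n_unreach,
    )
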