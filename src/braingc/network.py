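"""Directed binary network construction from a GCI matrix.

An edge i -> j exists iff GCI(i -> j) strictly exceeds the threshold. The
threshold is either fixed (the study's printed per-band values) or chosen by
the network-integrity rule: the largest candidate that leaves at most a given
fraction of nodes isolated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .granger import GCMatrix
from .recording import BandDefinition

__all__ = ["DirectedNetwork", "ThresholdSelection", "build_network", "select_threshold"]


@dataclass
class DirectedNetwork:
    """Boolean adjacency, entry (i, j) True iff edge i -> j, plus the
    threshold that produced it."""

    adjacency: np.ndarray
    node_labels: tuple[str, ...]
    threshold_used: float
    band: BandDefinition | None = None

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=bool)
        n = self.adjacency.shape[0]
        if self.adjacency.shape != (n, n) or n != len(self.node_labels):
            raise ValueError("adjacency must be square and match node_labels")
        if np.any(np.diag(self.adjacency)):
            raise ValueError("self-edges are not allowed")
        if self.threshold_used < 0:
            raise ValueError("threshold must be >= 0")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum())

    def edge_list(self) -> list[tuple[str, str]]:
        src, dst = np.nonzero(self.adjacency)
        return [(self.node_labels[s], self.node_labels[t]) for s, t in zip(src, dst)]


class ThresholdSelection(NamedTuple):
    """Result of the integrity rule; ``feasible`` is False when no candidate
    satisfied the isolated-node constraint and the smallest was returned."""

    threshold: float
    feasible: bool


def build_network(gc: GCMatrix, threshold: float) -> DirectedNetwork:
    """Edge i -> j iff gc.values[i, j] > threshold (strict); no self-edges."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    adj = gc.values > threshold
    np.fill_diagonal(adj, False)
    return DirectedNetwork(
        adjacency=adj,
        node_labels=gc.channel_labels,
        threshold_used=float(threshold),
        band=gc.band,
    )


def _isolated_fraction(gc: GCMatrix, threshold: float) -> float:
    adj = gc.values > threshold
    np.fill_diagonal(adj, False)
    total_degree = adj.sum(axis=0) + adj.sum(axis=1)
    return float(np.mean(total_degree == 0))


def default_grid(gc: GCMatrix, size: int = 100) -> np.ndarray:
    """Evenly spaced candidate thresholds between the off-diagonal extremes."""
    off = gc.offdiagonal()
    return np.linspace(float(off.min()), float(off.max()), size)


def select_threshold(
    gc: GCMatrix,
    max_isolated_fraction: float = 0.0,
    grid: np.ndarray | None = None,
) -> ThresholdSelection:
    """Network-integrity threshold rule.

    Returns the largest grid value whose induced network leaves at most
    ``max_isolated_fraction`` of nodes with total degree 0 (default: none),
    keeping the network as sparse as possible without breaking it apart. If
    no candidate qualifies, the smallest grid value is returned flagged
    infeasible.
    """
    if not 0 <= max_isolated_fraction < 1:
        raise ValueError("max_isolated_fraction must be in [0, 1)")
    if grid is None:
        grid = default_grid(gc)
    grid = np.sort(np.asarray(grid, dtype=float))
    if grid.size == 0:
        raise ValueError("threshold grid is empty")
    for thr in grid[::-1]:
        if _isolated_fraction(gc, thr) <= max_isolated_fraction:
            return ThresholdSelection(float(thr), True)
    return ThresholdSelection(float(grid[0]), False)
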