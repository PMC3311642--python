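"""Binary graph construction from association matrices.

A graph at cost c keeps exactly ``round(c * N(N-1)/2)`` edges: the maximum
spanning tree of the absolute-z matrix first (which guarantees a connected
network at every density), then the strongest remaining connections in
descending |z| order.  Ties are broken by lexicographic node-pair order so
construction is fully deterministic.
"""

from __future__ import annotations

import numpy as np

from .errors import InfeasibleCostError, TrivialGraphError
from .types import BinaryGraph, ConnectivityMatrix, DensityGrid

__all__ = [
    "max_spanning_tree",
    "binarize_at_cost",
    "density_sweep",
    "node_degree",
    "ranked_edges",
]


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _sorted_edge_list(z: np.ndarray) -> np.ndarray:
    """All upper-triangle edges sorted by descending weight, then (i, j)."""
    n = z.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = z[iu, ju]
    order = np.lexsort((ju, iu, -w))
    return np.column_stack([iu[order], ju[order]])


def max_spanning_tree(z: ConnectivityMatrix) -> list[tuple[int, int]]:
    """Maximum-|z| spanning tree by Kruskal with deterministic tie-breaks.

    Returns the N-1 tree edges as (i, j) pairs with i < j, in the order they
    were accepted.
    """
    n = z.n_regions
    if n < 2:
        raise TrivialGraphError("spanning tree needs at least 2 nodes")
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    tree: list[tuple[int, int]] = []
    for i, j in _sorted_edge_list(z.z_abs).tolist():
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            tree.append((i, j))
            if len(tree) == n - 1:
                break
    return tree


def ranked_edges(z: ConnectivityMatrix) -> tuple[np.ndarray, int]:
    """Deterministic edge priority for thresholding.

    Returns ``(edges, n_tree)``: an (M, 2) array whose first ``n_tree`` rows
    are the maximum-spanning-tree edges and whose remaining rows are the
    non-tree edges in descending |z| order (lexicographic tie-break).  Any
    graph formed by a prefix of length >= n_tree is connected, and prefixes
    are nested, which makes the whole density sweep a single ranking.
    """
    ordered = _sorted_edge_list(z.z_abs)
    n = z.n_regions
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    is_tree = np.zeros(len(ordered), dtype=bool)
    n_tree = 0
    for pos, (i, j) in enumerate(ordered.tolist()):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            is_tree[pos] = True
            n_tree += 1
            if n_tree == n - 1:
                break
    edges = np.concatenate([ordered[is_tree], ordered[~is_tree]])
    return edges, n_tree


def _graph_from_prefix(
    edges: np.ndarray, n_edges: int, cost: float, labels: list[str]
) -> BinaryGraph:
    n = len(labels)
    adj = np.zeros((n, n), dtype=bool)
    sel = edges[:n_edges]
    adj[sel[:, 0], sel[:, 1]] = True
    adj[sel[:, 1], sel[:, 0]] = True
    return BinaryGraph(adjacency=adj, cost=cost, region_labels=labels)


def binarize_at_cost(z: ConnectivityMatrix, cost: float) -> BinaryGraph:
    """Binary graph at a single connection density.

    Edge count is ``round(cost * N(N-1)/2)`` (round half up); densities too
    small to hold the spanning tree are rejected.
    """
    n = z.n_regions
    m_total = n * (n - 1) // 2
    m = _round_half_up(cost * m_total)
    if m < n - 1:
        raise InfeasibleCostError(
            f"cost {cost} gives {m} edges < N-1 = {n - 1}: cannot hold the spanning tree"
        )
    edges, _ = ranked_edges(z)
    return _graph_from_prefix(edges, m, cost, z.region_labels)


def density_sweep(z: ConnectivityMatrix, grid: DensityGrid) -> list[BinaryGraph]:
    """One binary graph per grid cost; edge sets are nested across costs."""
    n = z.n_regions
    m_total = n * (n - 1) // 2
    edges, _ = ranked_edges(z)
    graphs = []
    for cost in grid:
        m = _round_half_up(cost * m_total)
        if m < n - 1:
            raise InfeasibleCostError(
                f"cost {cost} gives {m} edges < N-1 = {n - 1}: cannot hold the spanning tree"
            )
        graphs.append(_graph_from_prefix(edges, m, cost, z.region_labels))
    return graphs


def node_degree(graph: BinaryGraph) -> np.ndarray:
    """Number of direct connections of each region."""
    return graph.degrees()
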