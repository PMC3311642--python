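"""Topological measures of binary brain graphs.

Global and nodal clustering coefficient (C_p), characteristic path length
(L_p), global efficiency (E_global) and local efficiency (E_local), plus
degree-preserving random nulls (Maslov–Sneppen double-edge swaps) and the
small-world ratios gamma = C_p/C_p^rand, lambda = L_p/L_p^rand and
sigma = gamma/lambda.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

from .errors import DisconnectedGraphError, UndefinedGammaError
from .types import BinaryGraph, ConnectivityMatrix, DensityGrid

__all__ = [
    "GraphMetricSet",
    "clustering_coefficient",
    "characteristic_path_length",
    "global_efficiency",
    "local_efficiency",
    "rewire_preserving_degree",
    "small_world_parameters",
    "compute_metrics",
    "metric_table",
    "GLOBAL_METRICS",
    "NODAL_METRICS",
    "SMALLWORLD_METRICS",
]

logger = logging.getLogger(__name__)

GLOBAL_METRICS = ("clustering", "path_length", "global_efficiency", "local_efficiency")
NODAL_METRICS = GLOBAL_METRICS
SMALLWORLD_METRICS = ("gamma", "lambda", "sigma")

#: Default null-ensemble settings.
DEFAULT_N_NULLS = 100
DEFAULT_SWAPS_PER_EDGE = 10


@dataclass
class GraphMetricSet:
    """All topological measures of one graph at one cost."""

    cost: float
    clustering_global: float
    path_length: float
    efficiency_global: float
    efficiency_local_global: float
    clustering_per_node: np.ndarray
    path_length_per_node: np.ndarray
    efficiency_per_node: np.ndarray
    local_efficiency_per_node: np.ndarray
    gamma: float | None = None
    lambda_ratio: float | None = None
    sigma: float | None = None
    null_clustering_mean: float | None = None
    null_path_length_mean: float | None = None
    n_nulls: int = 0
    region_labels: list[str] = field(default_factory=list)


def _distance_matrix(adj: np.ndarray) -> np.ndarray:
    return shortest_path(csr_matrix(adj), method="D", unweighted=True, directed=False)


def clustering_coefficient(graph: BinaryGraph) -> tuple[np.ndarray, float]:
    """Per-node clustering and its unweighted mean over all nodes.

    A node of degree k >= 2 scores ``2 * triangles / (k * (k - 1))``;
    degree-<2 nodes score 0 and are included in the mean.
    """
    a = graph.adjacency.astype(float)
    triangles = ((a @ a) * a).sum(axis=1) / 2.0
    k = graph.degrees().astype(float)
    denom = k * (k - 1)
    per_node = np.where(denom > 0, 2.0 * triangles / np.where(denom > 0, denom, 1.0), 0.0)
    return per_node, float(per_node.mean())


def characteristic_path_length(graph: BinaryGraph) -> tuple[np.ndarray, float]:
    """Mean shortest-path hop count: per node (mean distance to the others)
    and over all unordered pairs.  Requires a connected graph."""
    d = _distance_matrix(graph.adjacency)
    if np.isinf(d).any():
        raise DisconnectedGraphError("path length undefined for a disconnected graph")
    n = graph.n_nodes
    per_node = (d.sum(axis=1)) / (n - 1)
    mean = float(d[np.triu_indices(n, k=1)].mean())
    return per_node, mean


def _efficiency_from_distances(d: np.ndarray) -> tuple[np.ndarray, float]:
    n = d.shape[0]
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    per_node = inv.sum(axis=1) / (n - 1)
    scalar = float(inv[np.triu_indices(n, k=1)].mean())
    return per_node, scalar


def global_efficiency(graph: BinaryGraph) -> tuple[np.ndarray, float]:
    """Mean inverse shortest-path length (1/inf = 0 for unreachable pairs)."""
    return _efficiency_from_distances(_distance_matrix(graph.adjacency))


def local_efficiency(graph: BinaryGraph) -> tuple[np.ndarray, float]:
    """Per node: global efficiency of the subgraph induced by its neighbours
    (0 when degree < 2); network value is the mean over all nodes."""
    adj = graph.adjacency
    n = graph.n_nodes
    per_node = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(adj[i])
        if nb.size < 2:
            continue
        sub = adj[np.ix_(nb, nb)]
        _, eff = _efficiency_from_distances(_distance_matrix(sub))
        per_node[i] = eff
    return per_node, float(per_node.mean())


def _is_connected(adj: np.ndarray) -> bool:
    n_comp, _ = connected_components(csr_matrix(adj), directed=False)
    return n_comp == 1


def _rewire_one(
    adj: np.ndarray, edges: np.ndarray, n_swaps: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, int]:
    """Double-edge-swap randomization of one graph, in place on copies.

    Swaps never create self-loops or multi-edges; connectivity is enforced by
    an adaptive window — batches of swaps are committed only if the graph is
    still connected, otherwise reverted and the window shrunk.  Attempts are
    bounded, so swap-free graphs (e.g. a triangle) fall through unchanged.
    """
    n_edges = len(edges)
    max_tries = 100 * n_swaps + 100
    accepted_total = 0
    tries = 0
    window = 64
    # pre-drawn randomness consumed sequentially (much cheaper than per-call)
    block = 4096
    draws = np.empty((0, 3), dtype=np.int64)
    cursor = 0
    while accepted_total < n_swaps and tries < max_tries:
        undo: list[tuple[int, int, int, int, int, int]] = []
        target = min(window, n_swaps - accepted_total)
        while len(undo) < target and tries < max_tries:
            tries += 1
            if cursor >= len(draws):
                draws = np.column_stack(
                    [rng.integers(n_edges, size=block), rng.integers(n_edges, size=block),
                     rng.integers(2, size=block)]
                )
                cursor = 0
            e1, e2, flip = draws[cursor]
            cursor += 1
            e1, e2 = int(e1), int(e2)
            if e1 == e2:
                continue
            u, v = edges[e1]
            x, y = edges[e2]
            if flip:
                x, y = y, x
            # new edges: (u, x) and (v, y)
            if u == x or v == y or u == y or v == x:
                continue
            if adj[u, x] or adj[v, y]:
                continue
            adj[u, v] = adj[v, u] = False
            adj[x, y] = adj[y, x] = False
            adj[u, x] = adj[x, u] = True
            adj[v, y] = adj[y, v] = True
            edges[e1] = (u, x)
            edges[e2] = (v, y)
            undo.append((e1, e2, u, v, x, y))
        if not undo:
            break
        if _is_connected(adj):
            accepted_total += len(undo)
            window = min(window * 2, 1024)
        else:
            for e1, e2, u, v, x, y in reversed(undo):
                adj[u, x] = adj[x, u] = False
                adj[v, y] = adj[y, v] = False
                adj[u, v] = adj[v, u] = True
                adj[x, y] = adj[y, x] = True
                edges[e1] = (u, v)
                edges[e2] = (x, y)
            window = max(window // 2, 1)
    return adj, edges, accepted_total


def rewire_preserving_degree(
    graph: BinaryGraph,
    n_nulls: int = DEFAULT_N_NULLS,
    swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE,
    seed: int = 0,
) -> list[BinaryGraph]:
    """Degree-preserving, connectivity-preserving random null graphs.

    Each null starts from the input and applies ``swaps_per_edge * E`` double
    edge swaps.  If no valid swap exists (bounded attempts exhausted with no
    accepted swap) the input is returned unchanged with a logged warning.
    """
    if n_nulls < 1 or swaps_per_edge < 1:
        raise ValueError("n_nulls and swaps_per_edge must be >= 1")
    base_edges = np.column_stack(np.triu_indices(graph.n_nodes, k=1))
    mask = graph.adjacency[base_edges[:, 0], base_edges[:, 1]]
    base_edges = base_edges[mask]
    n_swaps = swaps_per_edge * len(base_edges)
    ss = np.random.SeedSequence(int(seed))
    nulls = []
    for child in ss.spawn(n_nulls):
        rng = np.random.default_rng(child)
        adj, _, accepted = _rewire_one(
            graph.adjacency.copy(), base_edges.copy(), n_swaps, rng
        )
        if accepted == 0:
            logger.warning(
                "no valid degree-preserving swap found; null equals input graph"
            )
        nulls.append(
            BinaryGraph(adjacency=adj, cost=graph.cost, region_labels=graph.region_labels)
        )
    return nulls


def small_world_parameters(
    graph: BinaryGraph, nulls: list[BinaryGraph]
) -> tuple[float, float, float, float, float]:
    """Small-world ratios against a null ensemble.

    Returns ``(gamma, lambda, sigma, null_clustering_mean,
    null_path_length_mean)`` where gamma = C_p/C_p^rand, lambda =
    L_p/L_p^rand and sigma = gamma/lambda.
    """
    if not nulls:
        raise ValueError("null ensemble must be nonempty")
    _, cp = clustering_coefficient(graph)
    _, lp = characteristic_path_length(graph)
    null_cp = float(np.mean([clustering_coefficient(g)[1] for g in nulls]))
    null_lp = float(np.mean([characteristic_path_length(g)[1] for g in nulls]))
    if null_cp == 0:
        raise UndefinedGammaError("null ensemble mean clustering is zero")
    gamma = cp / null_cp
    lam = lp / null_lp
    return gamma, lam, gamma / lam, null_cp, null_lp


def compute_metrics(
    graph: BinaryGraph,
    n_nulls: int = 0,
    swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE,
    seed: int = 0,
) -> GraphMetricSet:
    """All measures of one graph; small-world ratios when ``n_nulls`` > 0."""
    c_node, c_mean = clustering_coefficient(graph)
    l_node, l_mean = characteristic_path_length(graph)
    e_node, e_glob = global_efficiency(graph)
    le_node, le_mean = local_efficiency(graph)
    ms = GraphMetricSet(
        cost=graph.cost,
        clustering_global=c_mean,
        path_length=l_mean,
        efficiency_global=e_glob,
        efficiency_local_global=le_mean,
        clustering_per_node=c_node,
        path_length_per_node=l_node,
        efficiency_per_node=e_node,
        local_efficiency_per_node=le_node,
        region_labels=graph.region_labels,
    )
    if n_nulls > 0:
        nulls = rewire_preserving_degree(graph, n_nulls, swaps_per_edge, seed)
        gamma, lam, sigma, null_cp, null_lp = small_world_parameters(graph, nulls)
        ms.gamma, ms.lambda_ratio, ms.sigma = gamma, lam, sigma
        ms.null_clustering_mean, ms.null_path_length_mean = null_cp, null_lp
        ms.n_nulls = n_nulls
    return ms


def metric_table(
    subject_id: str,
    graphs: list[BinaryGraph],
    n_nulls: int = 0,
    swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE,
    seed: int = 0,
    smallworld_costs: list[float] | None = None,
    include_nodal: bool = True,
) -> pd.DataFrame:
    """Tidy per-subject metric table over a density sweep.

    Columns: subject_id, cost, metric, scope (global|node), region_label,
    value.  Small-world ratios are computed (with ``n_nulls`` nulls) at every
    cost when ``smallworld_costs`` is None, otherwise only at the listed
    costs.
    """
    rows = []
    for k, graph in enumerate(graphs):
        want_sw = n_nulls > 0 and (
            smallworld_costs is None or any(np.isclose(graph.cost, c) for c in smallworld_costs)
        )
        ms = compute_metrics(
            graph,
            n_nulls=n_nulls if want_sw else 0,
            swaps_per_edge=swaps_per_edge,
            seed=seed + k,
        )
        for name, value in (
            ("clustering", ms.clustering_global),
            ("path_length", ms.path_length),
            ("global_efficiency", ms.efficiency_global),
            ("local_efficiency", ms.efficiency_local_global),
        ):
            rows.append((subject_id, graph.cost, name, "global", "", value))
        if want_sw:
            for name, value in (
                ("gamma", ms.gamma),
                ("lambda", ms.lambda_ratio),
                ("sigma", ms.sigma),
            ):
                rows.append((subject_id, graph.cost, name, "global", "", value))
        if include_nodal:
            for name, vec in (
                ("clustering", ms.clustering_per_node),
                ("path_length", ms.path_length_per_node),
                ("global_efficiency", ms.efficiency_per_node),
                ("local_efficiency", ms.local_efficiency_per_node),
            ):
                for label, value in zip(graph.region_labels, vec):
                    rows.append((subject_id, graph.cost, name, "node", label, float(value)))
    return pd.DataFrame(
        rows, columns=["subject_id", "cost", "metric", "scope", "region_label", "value"]
    )
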