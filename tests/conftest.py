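"""Shared fixtures: tiny graphs, a brute-force metric oracle, random cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from restgraph.types import BinaryGraph


def graph_from_edges(n: int, edges, cost: float = 0.5) -> BinaryGraph:
    adj = np.zeros((n, n), dtype=bool)
    for i, j in edges:
        adj[i, j] = adj[j, i] = True
    labels = [f"R{k:03d}" for k in range(1, n + 1)]
    return BinaryGraph(adjacency=adj, cost=cost, region_labels=labels)


def complete_graph(n: int) -> BinaryGraph:
    return graph_from_edges(n, [(i, j) for i in range(n) for j in range(i + 1, n)])


def path_graph(n: int) -> BinaryGraph:
    return graph_from_edges(n, [(i, i + 1) for i in range(n - 1)])


def star_graph(n: int) -> BinaryGraph:
    return graph_from_edges(n, [(0, i) for i in range(1, n)])


# ---------------------------------------------------------------------------
# Independent brute-force oracle: Floyd–Warshall distances, exhaustive
# triangle enumeration, induced-subgraph efficiency by direct enumeration.
# Pure python, no shared code with the implementation under test.
# ---------------------------------------------------------------------------


def oracle_distances(adj) -> list[list[float]]:
    n = len(adj)
    inf = float("inf")
    d = [[0.0 if i == j else (1.0 if adj[i][j] else inf) for j in range(n)] for i in range(n)]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                via = d[i][k] + d[k][j]
                if via < d[i][j]:
                    d[i][j] = via
    return d


def oracle_clustering(adj) -> tuple[list[float], float]:
    n = len(adj)
    per_node = []
    for i in range(n):
        nb = [j for j in range(n) if adj[i][j]]
        k = len(nb)
        if k < 2:
            per_node.append(0.0)
            continue
        links = sum(1 for a in range(k) for b in range(a + 1, k) if adj[nb[a]][nb[b]])
        per_node.append(2.0 * links / (k * (k - 1)))
    return per_node, sum(per_node) / n


def oracle_path_length(adj) -> tuple[list[float], float]:
    d = oracle_distances(adj)
    n = len(adj)
    per_node = [sum(d[i][j] for j in range(n) if j != i) / (n - 1) for i in range(n)]
    pairs = [d[i][j] for i in range(n) for j in range(i + 1, n)]
    return per_node, sum(pairs) / len(pairs)


def oracle_global_efficiency(adj) -> tuple[list[float], float]:
    d = oracle_distances(adj)
    n = len(adj)
    inv = [[0.0 if (i == j or d[i][j] == float("inf")) else 1.0 / d[i][j] for j in range(n)] for i in range(n)]
    per_node = [sum(inv[i][j] for j in range(n) if j != i) / (n - 1) for i in range(n)]
    pairs = [inv[i][j] for i in range(n) for j in range(i + 1, n)]
    return per_node, sum(pairs) / len(pairs)


def oracle_local_efficiency(adj) -> tuple[list[float], float]:
    n = len(adj)
    per_node = []
    for i in range(n):
        nb = [j for j in range(n) if adj[i][j]]
        if len(nb) < 2:
            per_node.append(0.0)
            continue
        sub = [[adj[a][b] for b in nb] for a in nb]
        per_node.append(oracle_global_efficiency(sub)[1])
    return per_node, sum(per_node) / n


def random_connected_graph(n: int, p: float, rng: np.random.Generator) -> BinaryGraph:
    """Seeded Erdős–Rényi graph, resampled until connected."""
    for _ in range(1000):
        adj = rng.random((n, n)) < p
        adj = np.triu(adj, k=1)
        adj = adj | adj.T
        reach = {0}
        frontier = [0]
        while frontier:
            i = frontier.pop()
            for j in np.flatnonzero(adj[i]):
                if j not in reach:
                    reach.add(int(j))
                    frontier.append(int(j))
        if len(reach) == n:
            labels = [f"R{k:03d}" for k in range(1, n + 1)]
            return BinaryGraph(adjacency=adj, cost=0.5, region_labels=labels)
    raise RuntimeError("could not generate a connected graph")


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small two-group synthetic cohort reused by several test modules."""
    from restgraph import CohortSpec, GroupSpec, sample_cohort

    spec = CohortSpec(
        groups=[
            GroupSpec(name="AD", n_subjects=4, rewire_prob=0.05),
            GroupSpec(name="NC", n_subjects=4, rewire_prob=0.35),
        ],
        n_regions=30,
        n_timepoints=80,
        seed=7,
    )
    return spec, sample_cohort(spec)
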