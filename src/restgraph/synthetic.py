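"""Seeded synthetic cohorts with planted small-world correlation structure.

There is no public data release for the study design this pipeline targets,
so cohorts are simulated: each group carries a planted Watts-Strogatz graph,
the graph is turned into a positive-definite correlation-like covariance, and
each subject's ROI series is drawn as independent multivariate-normal volumes
from that covariance plus white measurement noise.  A group with a lower
rewiring probability therefore has a more lattice-like planted topology
(higher clustering, longer path length) — the direction of the patient/control
contrast the group-analysis stage is meant to recover.
"""

from __future__ import annotations

import numpy as np
import networkx as nx

from .errors import GenerationFailureError, InvalidSpecError
from .types import SEED_MOD, BinaryGraph, CohortSpec, GroupSpec, MotionTrace, RoiTimeSeries

__all__ = [
    "generate_planted_graph",
    "graph_to_covariance",
    "sample_cohort",
    "default_cohort_spec",
    "default_region_labels",
]


def default_region_labels(n_regions: int) -> list[str]:
    """Generic region labels R001..RNNN (stand-ins for an atlas naming)."""
    width = max(3, len(str(n_regions)))
    return [f"R{i + 1:0{width}d}" for i in range(n_regions)]


def generate_planted_graph(
    n_nodes: int, lattice_neighbors: int, rewire_prob: float, seed: int
) -> BinaryGraph:
    """Connected Watts–Strogatz graph: ring lattice with ``lattice_neighbors``
    neighbours on each side, each edge rewired with probability ``rewire_prob``.

    Rewiring preserves the edge count and never creates self-loops or
    multi-edges; generation is retried (fresh randomness, up to 100 times)
    until the result is connected.
    """
    if 2 * lattice_neighbors >= n_nodes:
        raise InvalidSpecError("2*lattice_neighbors must be < n_nodes")
    if not 0.0 <= rewire_prob <= 1.0:
        raise InvalidSpecError("rewire_prob outside [0, 1]")
    try:
        g = nx.connected_watts_strogatz_graph(
            n_nodes, 2 * lattice_neighbors, rewire_prob, tries=100, seed=int(seed) % SEED_MOD
        )
    except nx.NetworkXError as exc:
        raise GenerationFailureError(
            f"no connected graph after 100 retries (n={n_nodes}, "
            f"k={lattice_neighbors}, p={rewire_prob})"
        ) from exc
    adj = nx.to_numpy_array(g, nodelist=range(n_nodes), dtype=bool)
    return BinaryGraph(
        adjacency=adj,
        cost=g.number_of_edges() / (n_nodes * (n_nodes - 1) / 2),
        region_labels=default_region_labels(n_nodes),
    )


def graph_to_covariance(
    graph: BinaryGraph, edge_strength: float, seed: int = 0
) -> tuple[np.ndarray, float]:
    """Unit-diagonal covariance with ``edge_strength`` on planted edges.

    The raw matrix is ``I + s*A``.  If it is not positive definite it is
    repaired by a minimal uniform eigenvalue shift and rescaled back to unit
    diagonal, which preserves the edge/non-edge ordering of entries.

    Returns ``(covariance, shift)`` where ``shift`` is the eigenvalue shift
    applied (0.0 when the raw matrix was already positive definite).
    """
    if not 0.0 < edge_strength < 1.0:
        raise InvalidSpecError("edge_strength must lie in (0, 1)")
    a = graph.adjacency.astype(float)
    cov = np.eye(graph.n_nodes) + edge_strength * a
    lam_min = float(np.linalg.eigvalsh(cov)[0])
    shift = 0.0
    if lam_min <= 1e-10:
        shift = -lam_min + 1e-6
        cov = (cov + shift * np.eye(graph.n_nodes)) / (1.0 + shift)
    return cov, shift


def _subject_rng(master_seed: int, group_index: int, subject_index: int) -> np.random.Generator:
    # spawn-key derivation: adding subjects or groups never reshuffles the
    # streams of earlier subjects
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(group_index, subject_index))
    return np.random.default_rng(ss)


def _group_graph_seed(master_seed: int, group_index: int) -> int:
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(10_000 + group_index,))
    return int(ss.generate_state(1)[0] % SEED_MOD)


def sample_cohort(
    spec: CohortSpec,
) -> tuple[list[RoiTimeSeries], list[MotionTrace], "pandas.DataFrame"]:
    """Draw a full cohort from a :class:`CohortSpec`.

    Each subject's T x N matrix has independent rows drawn from the group's
    planted covariance, plus i.i.d. Gaussian noise of sd ``noise_sd``.  A
    zero-motion trace is attached to every subject (the generator does not
    emulate head movement).  Returns the series, the motion traces and a
    manifest DataFrame (subject_id, group, subgroup, seed).
    """
    import pandas as pd

    labels = default_region_labels(spec.n_regions)
    series: list[RoiTimeSeries] = []
    traces: list[MotionTrace] = []
    rows = []
    for gi, group in enumerate(spec.groups):
        graph_seed = group.graph_seed if group.graph_seed is not None else _group_graph_seed(
            spec.seed, gi
        )
        graph = generate_planted_graph(
            spec.n_regions, group.lattice_neighbors, group.rewire_prob, graph_seed
        )
        cov, _ = graph_to_covariance(graph, group.edge_strength)
        chol = np.linalg.cholesky(cov)
        for si in range(group.n_subjects):
            rng = _subject_rng(spec.seed, gi, si)
            z = rng.standard_normal((spec.n_timepoints, spec.n_regions))
            data = z @ chol.T
            if group.noise_sd > 0:
                data = data + group.noise_sd * rng.standard_normal(data.shape)
            sid = f"{group.name}_{si + 1:03d}"
            series.append(
                RoiTimeSeries(
                    subject_id=sid,
                    data=data,
                    sampling_interval_s=spec.sampling_interval_s,
                    region_labels=labels,
                )
            )
            traces.append(
                MotionTrace(
                    subject_id=sid,
                    translations=np.zeros((spec.n_timepoints, 3)),
                    rotations=np.zeros((spec.n_timepoints, 3)),
                )
            )
            rows.append(
                {
                    "subject_id": sid,
                    "group": group.name,
                    "subgroup": group.subgroup if group.subgroup is not None else "",
                    "seed": spec.seed,
                    "graph_seed": graph_seed,
                }
            )
    manifest = pd.DataFrame(rows)
    return series, traces, manifest


def default_cohort_spec(seed: int = 0) -> CohortSpec:
    """The two-group study-condition cohort: 33 patient-like subjects with a
    lattice-like planted topology (rewire 0.05) versus 20 control-like
    subjects with a more random topology (rewire 0.35), 90 regions, 155
    volumes at a 2-second sampling interval."""
    return CohortSpec(
        groups=[
            GroupSpec(name="AD", n_subjects=33, lattice_neighbors=3, rewire_prob=0.05),
            GroupSpec(name="NC", n_subjects=20, lattice_neighbors=3, rewire_prob=0.35),
        ],
        seed=seed,
    )
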