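"""Core domain containers shared by all pipeline stages.

The containers are thin dataclasses around numpy arrays; each validates its
own invariants at construction so downstream stages can rely on them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidSpecError

#: Half-open integer bound for seeds handed to numpy / networkx.
SEED_MOD = 2**31


def _as_2d_float(data) -> np.ndarray:
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 2:
        raise InvalidSpecError(f"expected a 2-D matrix, got shape {arr.shape}")
    return arr


@dataclass
class RoiTimeSeries:
    """One subject's T x N region-averaged signal matrix.

    Rows are volumes (timepoints), columns are regions; ``sampling_interval_s``
    is the repetition time in seconds.
    """

    subject_id: str
    data: np.ndarray
    sampling_interval_s: float
    region_labels: list[str]

    def __post_init__(self) -> None:
        self.data = _as_2d_float(self.data)
        t, n = self.data.shape
        if t < 10:
            raise InvalidSpecError(f"{self.subject_id}: need T >= 10 volumes, got {t}")
        if len(self.region_labels) != n:
            raise InvalidSpecError(
                f"{self.subject_id}: {len(self.region_labels)} labels for {n} regions"
            )
        if len(set(self.region_labels)) != n:
            raise InvalidSpecError(f"{self.subject_id}: region labels not unique")
        if not np.all(np.isfinite(self.data)):
            raise InvalidSpecError(f"{self.subject_id}: non-finite values in time series")
        if self.sampling_interval_s <= 0:
            raise InvalidSpecError("sampling interval must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]


@dataclass
class MotionTrace:
    """Per-volume rigid-body motion parameters: translations (mm), rotations (deg)."""

    subject_id: str
    translations: np.ndarray  # T x 3, millimetres
    rotations: np.ndarray  # T x 3, degrees

    def __post_init__(self) -> None:
        self.translations = _as_2d_float(self.translations)
        self.rotations = _as_2d_float(self.rotations)
        if self.translations.shape[1] != 3 or self.rotations.shape[1] != 3:
            raise InvalidSpecError("motion trace needs 3 translation and 3 rotation axes")
        if self.translations.shape[0] != self.rotations.shape[0]:
            raise InvalidSpecError("translation and rotation traces differ in length")


@dataclass
class MotionSummary:
    """Van Dijk-style motion summary for one subject."""

    subject_id: str
    max_abs_translation_mm: np.ndarray  # per axis
    max_abs_rotation_deg: np.ndarray  # per axis
    mean_relative_displacement_mm: float
    mean_relative_rotation_deg: float
    excluded: bool = False


@dataclass
class ConnectivityMatrix:
    """Symmetric N x N absolute Fisher-z association matrix, zero diagonal."""

    subject_id: str
    z_abs: np.ndarray
    region_labels: list[str]

    def __post_init__(self) -> None:
        self.z_abs = _as_2d_float(self.z_abs)
        n = self.z_abs.shape[0]
        if self.z_abs.shape != (n, n):
            raise InvalidSpecError("connectivity matrix must be square")
        if len(self.region_labels) != n:
            raise InvalidSpecError("label count does not match matrix size")
        if not np.all(np.isfinite(self.z_abs)):
            raise InvalidSpecError("non-finite connectivity values")
        if np.any(self.z_abs < 0):
            raise InvalidSpecError("absolute-z matrix must be non-negative")
        if not np.allclose(self.z_abs, self.z_abs.T):
            raise InvalidSpecError("connectivity matrix must be symmetric")
        if np.any(np.diagonal(self.z_abs) != 0):
            raise InvalidSpecError("connectivity diagonal must be exactly zero")

    @property
    def n_regions(self) -> int:
        return self.z_abs.shape[0]


@dataclass
class BinaryGraph:
    """Undirected unweighted simple graph on labelled nodes at a stated cost."""

    adjacency: np.ndarray  # N x N bool
    cost: float
    region_labels: list[str]

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency, dtype=bool)
        n = adj.shape[0]
        if adj.shape != (n, n):
            raise InvalidSpecError("adjacency must be square")
        if not np.array_equal(adj, adj.T):
            raise InvalidSpecError("adjacency must be symmetric")
        if np.any(np.diagonal(adj)):
            raise InvalidSpecError("self-edges are not allowed")
        if len(self.region_labels) != n:
            raise InvalidSpecError("label count does not match adjacency size")
        self.adjacency = adj

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)


@dataclass
class GroupSpec:
    """One synthetic group: a planted Watts-Strogatz topology plus noise level.

    ``lattice_neighbors`` is the number of ring-lattice neighbours on each
    side (node degree before rewiring is twice this), ``rewire_prob`` the
    Watts-Strogatz rewiring probability: lower values give higher clustering
    and longer path length, i.e. a more lattice-like (patient-like) topology.
    """

    name: str
    n_subjects: int
    lattice_neighbors: int = 3
    rewire_prob: float = 0.35
    edge_strength: float = 0.4
    noise_sd: float = 0.25
    graph_seed: int | None = None  # share between groups to share one topology
    subgroup: str | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise InvalidSpecError(f"group {self.name!r}: need at least 2 subjects")
        if not 0.0 <= self.rewire_prob <= 1.0:
            raise InvalidSpecError(f"group {self.name!r}: rewire_prob outside [0, 1]")
        if not 0.0 < self.edge_strength < 1.0:
            raise InvalidSpecError(f"group {self.name!r}: edge_strength outside (0, 1)")
        if self.noise_sd < 0:
            raise InvalidSpecError(f"group {self.name!r}: negative noise_sd")
        if self.lattice_neighbors < 1:
            raise InvalidSpecError(f"group {self.name!r}: lattice_neighbors must be >= 1")


@dataclass
class CohortSpec:
    """A synthetic cohort: groups of multivariate-normal ROI series.

    Defaults match a 90-region parcellation sampled for 155 volumes at a
    2-second repetition time.
    """

    groups: list[GroupSpec]
    n_regions: int = 90
    n_timepoints: int = 155
    sampling_interval_s: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 3:
            raise InvalidSpecError("need at least 3 regions")
        if self.n_timepoints < 10:
            raise InvalidSpecError("need at least 10 timepoints")
        if not self.groups:
            raise InvalidSpecError("cohort needs at least one group")
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise InvalidSpecError("group names must be unique")
        for g in self.groups:
            if 2 * g.lattice_neighbors >= self.n_regions:
                raise InvalidSpecError(
                    f"group {g.name!r}: 2*lattice_neighbors must be < n_regions"
                )


@dataclass
class DensityGrid:
    """Ordered list of connection densities (costs) for the threshold sweep."""

    costs: list[float] = field(
        default_factory=lambda: [round(c / 100, 2) for c in range(4, 41, 2)]
    )

    def __post_init__(self) -> None:
        costs = [float(c) for c in self.costs]
        if any(not 0 < c <= 1 for c in costs):
            raise InvalidSpecError("costs must lie in (0, 1]")
        if any(b <= a for a, b in zip(costs, costs[1:])):
            raise InvalidSpecError("costs must be strictly increasing")
        self.costs = costs

    def __iter__(self):
        return iter(self.costs)

    def __len__(self) -> int:
        return len(self.costs)
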