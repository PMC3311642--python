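"""Inter-regional association matrices.

Each subject's matrix is the absolute Fisher r-to-z transform of the Pearson
correlation between every pair of region time series; group-mean matrices
are entrywise averages over a group's subjects.
"""

from __future__ import annotations

import numpy as np

from .errors import CohortInconsistencyError, DegenerateRegionError
from .types import ConnectivityMatrix, RoiTimeSeries

__all__ = ["correlation_matrix", "fisher_z", "connectivity_matrix", "group_mean_matrix"]

#: Margin by which |r| is kept away from 1 before atanh (keeps z finite, ~8.0).
DEFAULT_CLAMP = 1e-7


def correlation_matrix(ts: RoiTimeSeries) -> np.ndarray:
    """Pairwise Pearson correlation of region time series (N x N, unit diagonal)."""
    sd = ts.data.std(axis=0)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = [ts.region_labels[i] for i in zero]
        raise DegenerateRegionError(
            f"{ts.subject_id}: zero-variance region(s): {', '.join(names)}"
        )
    r = np.corrcoef(ts.data, rowvar=False)
    # numerical guard: corrcoef can exceed |1| by eps
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    return r


def fisher_z(
    r_matrix: np.ndarray,
    region_labels: list[str],
    subject_id: str = "",
    clamp: float = DEFAULT_CLAMP,
) -> ConnectivityMatrix:
    """Absolute Fisher r-to-z transform of a correlation matrix.

    Off-diagonal entries become ``|atanh(r)|`` after clamping ``|r|`` at
    ``1 - clamp``; the diagonal is forced to zero.
    """
    r = np.asarray(r_matrix, dtype=float)
    r = np.clip(r, -1.0 + clamp, 1.0 - clamp)
    z = np.abs(np.arctanh(r))
    z = (z + z.T) / 2.0
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(subject_id=subject_id, z_abs=z, region_labels=list(region_labels))


def connectivity_matrix(ts: RoiTimeSeries, clamp: float = DEFAULT_CLAMP) -> ConnectivityMatrix:
    """Convenience composition: Pearson correlation then absolute Fisher z."""
    return fisher_z(correlation_matrix(ts), ts.region_labels, ts.subject_id, clamp=clamp)


def group_mean_matrix(matrices: list[ConnectivityMatrix]) -> np.ndarray:
    """Entrywise mean of a group's absolute connection matrices."""
    if not matrices:
        raise CohortInconsistencyError("cannot average an empty list of matrices")
    labels = matrices[0].region_labels
    for m in matrices[1:]:
        if m.region_labels != labels:
            raise CohortInconsistencyError(
                f"region labels of {m.subject_id!r} differ from {matrices[0].subject_id!r}"
            )
    return np.mean([m.z_abs for m in matrices], axis=0)
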