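"""Reading and writing the pipeline's delimited-text formats.

Time series are TSV matrices (rows = volumes, columns = regions, header row
of region labels); motion traces are 6-column TSV (tx, ty, tz in mm, rx, ry,
rz in degrees); connectivity matrices and graphs are dense CSV with region
labels as header row and index column.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .types import BinaryGraph, ConnectivityMatrix, MotionTrace, RoiTimeSeries

__all__ = [
    "write_timeseries",
    "read_timeseries",
    "write_motion_trace",
    "read_motion_trace",
    "write_matrix",
    "read_matrix",
    "write_graph_csv",
    "write_graph_edgelist",
]

_MOTION_COLUMNS = ["tx_mm", "ty_mm", "tz_mm", "rx_deg", "ry_deg", "rz_deg"]


def write_timeseries(ts: RoiTimeSeries, path: str | Path) -> None:
    df = pd.DataFrame(ts.data, columns=ts.region_labels)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_timeseries(
    path: str | Path, subject_id: str, sampling_interval_s: float
) -> RoiTimeSeries:
    df = pd.read_csv(path, sep="\t")
    return RoiTimeSeries(
        subject_id=subject_id,
        data=df.to_numpy(dtype=float),
        sampling_interval_s=sampling_interval_s,
        region_labels=[str(c) for c in df.columns],
    )


def write_motion_trace(trace: MotionTrace, path: str | Path) -> None:
    df = pd.DataFrame(
        np.column_stack([trace.translations, trace.rotations]), columns=_MOTION_COLUMNS
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_motion_trace(path: str | Path, subject_id: str) -> MotionTrace:
    df = pd.read_csv(path, sep="\t")
    arr = df.to_numpy(dtype=float)
    return MotionTrace(subject_id=subject_id, translations=arr[:, :3], rotations=arr[:, 3:6])


def write_matrix(matrix: np.ndarray, labels: list[str], path: str | Path) -> None:
    df = pd.DataFrame(matrix, index=labels, columns=labels)
    df.to_csv(path, float_format="%.10g")


def read_matrix(path: str | Path, subject_id: str = "") -> ConnectivityMatrix:
    df = pd.read_csv(path, index_col=0)
    return ConnectivityMatrix(
        subject_id=subject_id,
        z_abs=df.to_numpy(dtype=float),
        region_labels=[str(c) for c in df.columns],
    )


def write_graph_csv(graph: BinaryGraph, path: str | Path) -> None:
    df = pd.DataFrame(
        graph.adjacency.astype(int), index=graph.region_labels, columns=graph.region_labels
    )
    df.to_csv(path)


def write_graph_edgelist(graphs: list[BinaryGraph], path: str | Path) -> None:
    """Nested sweep as a 3-column edge list: each edge with the first cost at
    which it enters the network."""
    seen: dict[tuple[int, int], float] = {}
    labels = graphs[0].region_labels
    for g in sorted(graphs, key=lambda g: g.cost):
        i, j = np.nonzero(np.triu(g.adjacency, k=1))
        for a, b in zip(i, j):
            seen.setdefault((int(a), int(b)), g.cost)
    rows = [
        {"region_i": labels[a], "region_j": labels[b], "cost_introduced": c}
        for (a, b), c in sorted(seen.items())
    ]
    pd.DataFrame(rows, columns=["region_i", "region_j", "cost_introduced"]).to_csv(
        path, index=False
    )
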