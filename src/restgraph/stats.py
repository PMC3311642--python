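"""Group-level statistics on network metrics.

Per-density and per-node two-sample comparisons with Student's pooled t,
label-permutation p-values, nodal alteration-frequency profiling and
three-subgroup pairwise contrasts.  No multiple-comparison correction is
applied by default; Benjamini–Hochberg adjustment is available as a flag.
"""

from __future__ import annotations

import logging
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    DegenerateVarianceError,
    IncompleteCohortError,
    UnderpoweredSubgroupError,
)
from .types import DensityGrid

__all__ = [
    "two_sample_t",
    "permutation_p",
    "compare_global_metrics",
    "compare_nodal_metrics",
    "extract_fixed_cost",
    "nodal_alteration_frequency",
    "pairwise_subgroup_contrasts",
    "bh_adjust",
]

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
DEFAULT_N_PERM = 10_000
#: Exhaustive enumeration is auto-enabled below this many distinct splits.
EXHAUSTIVE_LIMIT = 20_000

COMPARISON_COLUMNS = [
    "metric",
    "cost",
    "scope",
    "region_label",
    "group_a",
    "group_b",
    "group_a_mean",
    "group_b_mean",
    "t_statistic",
    "df",
    "p_parametric",
    "p_permutation",
    "significant",
]


def two_sample_t(a, b, welch: bool = False) -> tuple[float, float, float]:
    """Two-sample two-tailed t-test.

    Student's pooled-variance t with df = n_a + n_b - 2 by default; Welch's
    unequal-variance variant when ``welch`` is True.  Returns (t, df, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if welch:
        res = sps.ttest_ind(a, b, equal_var=False)
        return float(res.statistic), float(res.df), float(res.pvalue)
    na, nb = a.size, b.size
    df = na + nb - 2
    pooled = (np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2)) / df
    if pooled == 0:
        raise DegenerateVarianceError("zero pooled variance: t undefined")
    t = (a.mean() - b.mean()) / np.sqrt(pooled * (1 / na + 1 / nb))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def _t_columns(v: np.ndarray, masks: np.ndarray, na: int, nb: int) -> np.ndarray:
    """Pooled t for every (split, column) pair.

    ``v`` is (n, m) values, ``masks`` (s, n) boolean group-A membership.
    Splits with zero pooled variance score t = 0 (logged by the caller).
    """
    m = masks.astype(float)
    tot = v.sum(axis=0)
    tot_sq = (v**2).sum(axis=0)
    a_sum = m @ v
    a_sq = m @ (v**2)
    b_sum = tot - a_sum
    b_sq = tot_sq - a_sq
    ssa = a_sq - a_sum**2 / na
    ssb = b_sq - b_sum**2 / nb
    df = na + nb - 2
    pooled = (ssa + ssb) / df
    # clip tiny negatives from cancellation
    pooled = np.maximum(pooled, 0.0)
    denom = np.sqrt(pooled * (1 / na + 1 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (a_sum / na - b_sum / nb) / denom
    t[~np.isfinite(t)] = 0.0
    return t


def _exhaustive_masks(n: int, na: int) -> np.ndarray:
    masks = np.zeros((comb(n, na), n), dtype=bool)
    for r, idx in enumerate(combinations(range(n), na)):
        masks[r, list(idx)] = True
    return masks


def _perm_pvalues_block(
    v: np.ndarray,
    mask_a: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
    method: str = "auto",
) -> np.ndarray:
    """Permutation p-value for each column of ``v`` (shared label shuffles).

    Statistic is |t| (pooled).  Monte-Carlo mode uses the add-one estimator
    ``(1 + #{|t*| >= |t|}) / (1 + n_perm)``; exhaustive mode enumerates every
    distinct split and returns the exact proportion.  ``method='auto'``
    enumerates when there are at most ``EXHAUSTIVE_LIMIT`` distinct splits.
    """
    n, m = v.shape
    na = int(mask_a.sum())
    nb = n - na
    t_obs = _t_columns(v, mask_a[None, :], na, nb)[0]
    n_splits = comb(n, na)
    if method == "auto":
        method = "exhaustive" if n_splits <= EXHAUSTIVE_LIMIT else "monte-carlo"
    if method == "exhaustive":
        masks = _exhaustive_masks(n, na)
        t_perm = _t_columns(v, masks, na, nb)
        degenerate = int(np.sum(np.all(t_perm == 0, axis=1)))
        ge = np.abs(t_perm) >= np.abs(t_obs)[None, :] - 1e-12
        p = ge.sum(axis=0) / n_splits
    elif method == "monte-carlo":
        # random na-subsets via uniform keys (vectorized label shuffles)
        keys = rng.random((n_perm, n))
        idx = np.argpartition(keys, na - 1, axis=1)[:, :na]
        masks = np.zeros((n_perm, n), dtype=bool)
        masks[np.repeat(np.arange(n_perm), na), idx.ravel()] = True
        t_perm = _t_columns(v, masks, na, nb)
        degenerate = int(np.sum(np.all(t_perm == 0, axis=1)))
        ge = np.abs(t_perm) >= np.abs(t_obs)[None, :] - 1e-12
        p = (1.0 + ge.sum(axis=0)) / (1.0 + n_perm)
    else:
        raise ValueError(f"unknown permutation method {method!r}")
    if degenerate:
        logger.info("%d permuted splits had zero pooled variance (t set to 0)", degenerate)
    return p


def permutation_p(
    a,
    b,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    method: str = "auto",
) -> float:
    """Two-sided label-permutation p-value for the |t| statistic."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size + b.size < 4:
        raise ValueError("need at least 4 observations in total")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    v = np.concatenate([a, b])[:, None]
    mask_a = np.zeros(v.shape[0], dtype=bool)
    mask_a[: a.size] = True
    rng = np.random.default_rng(seed)
    return float(_perm_pvalues_block(v, mask_a, n_perm, rng, method)[0])


def _pivot_complete(
    table: pd.DataFrame, subjects: list[str], grid: DensityGrid, metrics, scope: str
):
    """Pivot a tidy metric table to (subject x column) and check completeness."""
    sub = table[(table["scope"] == scope) & (table["metric"].isin(metrics))]
    if scope == "node":
        wide = sub.pivot_table(
            index="subject_id",
            columns=["metric", "cost", "region_label"],
            values="value",
            aggfunc="first",
        )
    else:
        wide = sub.pivot_table(
            index="subject_id", columns=["metric", "cost"], values="value", aggfunc="first"
        )
    missing_subjects = [s for s in subjects if s not in wide.index]
    gaps = []
    if missing_subjects:
        gaps.extend(f"subject {s}: no metrics" for s in missing_subjects)
    else:
        wide = wide.loc[subjects]
        if wide.isna().any().any():
            bad = wide.columns[wide.isna().any(axis=0)]
            gaps.extend(f"missing values for column {c}" for c in list(bad)[:20])
        for metric in metrics:
            have = set() if metric not in wide.columns.get_level_values(0) else set(
                wide[metric].columns.get_level_values(0)
            )
            for cost in grid:
                if not any(np.isclose(cost, h) for h in have):
                    gaps.append(f"metric {metric}: no values at cost {cost}")
    if gaps:
        raise IncompleteCohortError("incomplete cohort: " + "; ".join(gaps))
    return wide


def _available_metrics(table: pd.DataFrame, scope: str, requested=None) -> list[str]:
    present = list(dict.fromkeys(table.loc[table["scope"] == scope, "metric"]))
    if requested is None:
        return present
    return [m for m in requested if m in present]


def _compare(
    table: pd.DataFrame,
    groups: pd.DataFrame,
    grid: DensityGrid,
    scope: str,
    alpha: float,
    n_perm: int,
    seed: int,
    metrics=None,
    welch: bool = False,
    perm_method: str = "auto",
) -> pd.DataFrame:
    pair = list(dict.fromkeys(groups["group"]))
    if len(pair) != 2:
        raise ValueError(f"need exactly two groups, got {pair}")
    ga, gb = pair
    subjects = sorted(groups["subject_id"])
    group_of = dict(zip(groups["subject_id"], groups["group"]))
    mask_a = np.array([group_of[s] == ga for s in subjects])
    na, nb = int(mask_a.sum()), int((~mask_a).sum())
    if na < 2 or nb < 2:
        raise UnderpoweredSubgroupError(f"groups must have >= 2 subjects ({ga}={na}, {gb}={nb})")
    metrics = _available_metrics(table, scope, metrics)
    wide = _pivot_complete(table, subjects, grid, metrics, scope)
    rows = []
    ss = np.random.SeedSequence(int(seed))
    children = iter(ss.spawn(len(metrics) * len(grid)))
    for metric in metrics:
        block = wide[metric]
        for cost in grid:
            cost_vals = block.columns.get_level_values(0) if scope == "node" else block.columns
            sel = np.isclose(np.asarray(cost_vals, dtype=float), cost)
            v = block.loc[:, sel].to_numpy(dtype=float)
            labels = (
                list(block.columns.get_level_values(1)[sel]) if scope == "node" else [""]
            )
            rng = np.random.default_rng(next(children))
            p_perm = _perm_pvalues_block(v, mask_a, n_perm, rng, perm_method)
            for col in range(v.shape[1]):
                va, vb = v[mask_a, col], v[~mask_a, col]
                try:
                    t, df, p_par = two_sample_t(va, vb, welch=welch)
                except DegenerateVarianceError:
                    t, df, p_par = 0.0, float(na + nb - 2), 1.0
                rows.append(
                    {
                        "metric": metric,
                        "cost": cost,
                        "scope": scope,
                        "region_label": labels[col],
                        "group_a": ga,
                        "group_b": gb,
                        "group_a_mean": float(va.mean()),
                        "group_b_mean": float(vb.mean()),
                        "t_statistic": t,
                        "df": df,
                        "p_parametric": p_par,
                        "p_permutation": float(p_perm[col]),
                        "significant": bool(p_par < alpha),
                    }
                )
    return pd.DataFrame(rows, columns=COMPARISON_COLUMNS)


def compare_global_metrics(
    table: pd.DataFrame,
    groups: pd.DataFrame,
    grid: DensityGrid,
    alpha: float = DEFAULT_ALPHA,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    metrics=None,
    welch: bool = False,
    perm_method: str = "auto",
) -> pd.DataFrame:
    """Per-density comparison of global metrics between two groups.

    ``table`` is the concatenated tidy metric table; ``groups`` a DataFrame
    (subject_id, group) with exactly two group levels.  Every global metric
    found in the table (or the requested subset) is tested at every grid
    cost; both parametric and permutation p-values are reported, and the
    ``significant`` flag applies ``p_parametric < alpha``.
    """
    return _compare(table, groups, grid, "global", alpha, n_perm, seed, metrics, welch, perm_method)


def compare_nodal_metrics(
    table: pd.DataFrame,
    groups: pd.DataFrame,
    grid: DensityGrid,
    alpha: float = DEFAULT_ALPHA,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    metrics=None,
    welch: bool = False,
    perm_method: str = "auto",
) -> pd.DataFrame:
    """Per-(region, metric, cost) comparison between two groups.

    Within one (metric, cost) family a single stream of label shuffles is
    applied to all regions simultaneously, preserving the spatial
    correlation structure of the permutation null.
    """
    return _compare(table, groups, grid, "node", alpha, n_perm, seed, metrics, welch, perm_method)


def extract_fixed_cost(comparison: pd.DataFrame, cost: float) -> pd.DataFrame:
    """Rows of a comparison table at one connection density."""
    return comparison[np.isclose(comparison["cost"], cost)].reset_index(drop=True)


def nodal_alteration_frequency(
    nodal_table: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    retention_threshold: int = 10,
) -> pd.DataFrame:
    """How many densities each (region, metric) pair is altered at.

    Counts grid costs with ``p_parametric < alpha``; a pair is ``retained``
    when its count strictly exceeds ``retention_threshold``.
    """
    nodal = nodal_table[nodal_table["scope"] == "node"]
    grouped = (
        nodal.assign(altered=nodal["p_parametric"] < alpha)
        .groupby(["region_label", "metric"], sort=True)["altered"]
        .sum()
        .astype(int)
        .reset_index()
        .rename(columns={"altered": "alteration_count"})
    )
    grouped["retained"] = grouped["alteration_count"] > retention_threshold
    return grouped


def pairwise_subgroup_contrasts(
    table: pd.DataFrame,
    subgroups: pd.DataFrame,
    grid: DensityGrid,
    alpha: float = DEFAULT_ALPHA,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    scope: str = "global",
    metrics=None,
) -> dict[tuple[str, str], pd.DataFrame]:
    """All pairwise two-sample contrasts between (typically three) subgroups.

    ``subgroups`` is a DataFrame (subject_id, group) whose ``group`` column
    holds the subgroup labels.  Returns one comparison table per unordered
    pair, each built with the same machinery as the two-group comparisons.
    """
    levels = list(dict.fromkeys(subgroups["group"]))
    counts = subgroups["group"].value_counts()
    small = [g for g in levels if counts[g] < 2]
    if small:
        raise UnderpoweredSubgroupError(f"subgroup(s) with < 2 subjects: {small}")
    out: dict[tuple[str, str], pd.DataFrame] = {}
    compare = compare_global_metrics if scope == "global" else compare_nodal_metrics
    for k, (ga, gb) in enumerate(combinations(levels, 2)):
        sel = subgroups[subgroups["group"].isin([ga, gb])]
        sub_table = table[table["subject_id"].isin(set(sel["subject_id"]))]
        out[(ga, gb)] = compare(
            sub_table, sel, grid, alpha=alpha, n_perm=n_perm, seed=seed + k, metrics=metrics
        )
    return out


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (optional, off by default)."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out
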