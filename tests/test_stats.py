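"""Two-sample tests, permutation inference and group-comparison tables."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from restgraph import (
    bh_adjust,
    compare_global_metrics,
    compare_nodal_metrics,
    extract_fixed_cost,
    nodal_alteration_frequency,
    pairwise_subgroup_contrasts,
    permutation_p,
    two_sample_t,
)
from restgraph.errors import DegenerateVarianceError, IncompleteCohortError, UnderpoweredSubgroupError
from restgraph.types import DensityGrid


class TestTwoSampleT:
    def test_matches_scipy_pooled(self):
        rng = np.random.default_rng(0)
        a, b = rng.standard_normal(12), rng.standard_normal(8) + 0.5
        t, df, p = two_sample_t(a, b)
        ref = sps.ttest_ind(a, b, equal_var=True)
        assert t == pytest.approx(ref.statistic, abs=1e-12)
        assert df == 18
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_welch_matches_scipy(self):
        rng = np.random.default_rng(1)
        a, b = rng.standard_normal(10), 3 * rng.standard_normal(15)
        t, df, p = two_sample_t(a, b, welch=True)
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_symmetry_and_sign(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 7.0]
        t_ab, _, p_ab = two_sample_t(a, b)
        t_ba, _, p_ba = two_sample_t(b, a)
        assert t_ab < 0 and t_ba == pytest.approx(-t_ab)
        assert p_ab == pytest.approx(p_ba)

    def test_constant_samples_rejected(self):
        with pytest.raises(DegenerateVarianceError):
            two_sample_t([1.0, 1.0, 1.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            two_sample_t([1.0], [2.0, 3.0])


class TestPermutation:
    def test_exhaustive_exact_small_case(self):
        # 2+2: C(4,2) = 6 splits; observed split is the most extreme pair of
        # complementary splits -> exact p = 2/6
        a, b = [0.0, 1.0], [10.0, 11.0]
        p = permutation_p(a, b, method="exhaustive")
        assert p == pytest.approx(2.0 / 6.0)

    def test_monte_carlo_close_to_exact(self):
        rng = np.random.default_rng(2)
        a, b = rng.standard_normal(4), rng.standard_normal(4) + 1.0
        exact = permutation_p(a, b, method="exhaustive")
        mc = permutation_p(a, b, n_perm=20_000, seed=5, method="monte-carlo")
        assert abs(mc - exact) < 0.02

    def test_auto_picks_exhaustive_for_small_n(self):
        rng = np.random.default_rng(3)
        a, b = rng.standard_normal(5), rng.standard_normal(5)
        assert permutation_p(a, b, seed=1) == permutation_p(a, b, method="exhaustive")

    def test_identical_groups_p_is_one(self):
        assert permutation_p([1.0, 2.0], [1.0, 2.0], method="exhaustive") == pytest.approx(1.0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        a, b = rng.standard_normal(15), rng.standard_normal(15)
        p1 = permutation_p(a, b, n_perm=500, seed=7, method="monte-carlo")
        p2 = permutation_p(a, b, n_perm=500, seed=7, method="monte-carlo")
        assert p1 == p2

    def test_mc_p_never_zero(self):
        a, b = [0.0, 0.1, 0.2, 0.05] * 3, [50.0, 51.0, 52.0, 50.5] * 3
        p = permutation_p(a, b, n_perm=99, seed=0, method="monte-carlo")
        assert p >= 1.0 / 100.0


def _tidy_table(grid, groups, effect=0.0, noise_seed=0, nodal=False, regions=("R001", "R002")):
    """Build a synthetic tidy metric table with a known group effect."""
    rng = np.random.default_rng(noise_seed)
    rows = []
    for sid, grp in groups:
        for cost in grid:
            for metric in ("clustering", "path_length"):
                base = effect if (grp == "A" and metric == "clustering") else 0.0
                rows.append((sid, cost, metric, "global", "", base + rng.normal()))
                if nodal:
                    for lab in regions:
                        shift = effect if (grp == "A" and lab == "R001") else 0.0
                        rows.append((sid, cost, metric, "node", lab, shift + rng.normal()))
    return pd.DataFrame(
        rows, columns=["subject_id", "cost", "metric", "scope", "region_label", "value"]
    )


def _groups_df(groups):
    return pd.DataFrame(groups, columns=["subject_id", "group"])


class TestCompareGlobal:
    def setup_method(self):
        self.grid = DensityGrid(costs=[0.1, 0.2])
        self.groups = [(f"a{i}", "A") for i in range(6)] + [(f"b{i}", "B") for i in range(6)]

    def test_table_shape_and_agreement_with_direct_t(self):
        table = _tidy_table(self.grid, self.groups, effect=2.0, noise_seed=1)
        out = compare_global_metrics(table, _groups_df(self.groups), self.grid, n_perm=200, seed=0)
        assert len(out) == 2 * 2  # 2 metrics x 2 costs
        row = out[(out["metric"] == "clustering") & (out["cost"] == 0.1)].iloc[0]
        sel = table[(table["metric"] == "clustering") & (table["cost"] == 0.1) & (table["scope"] == "global")]
        va = sel[sel["subject_id"].str.startswith("a")].sort_values("subject_id")["value"]
        vb = sel[sel["subject_id"].str.startswith("b")].sort_values("subject_id")["value"]
        t, df, p = two_sample_t(va, vb)
        assert row["t_statistic"] == pytest.approx(t, abs=1e-10)
        assert row["p_parametric"] == pytest.approx(p, abs=1e-10)
        assert row["group_a_mean"] == pytest.approx(va.mean())
        assert row["significant"] == (p < 0.05)

    def test_large_effect_detected_null_not(self):
        table = _tidy_table(self.grid, self.groups, effect=5.0, noise_seed=2)
        out = compare_global_metrics(table, _groups_df(self.groups), self.grid, n_perm=500, seed=1)
        clu = out[out["metric"] == "clustering"]
        assert clu["significant"].all()
        assert (clu["p_permutation"] < 0.05).all()

    def test_incomplete_cohort_detected(self):
        table = _tidy_table(self.grid, self.groups)
        table = table[~((table["subject_id"] == "a0") & (table["cost"] == 0.2))]
        with pytest.raises(IncompleteCohortError):
            compare_global_metrics(table, _groups_df(self.groups), self.grid, n_perm=50)

    def test_deterministic(self):
        table = _tidy_table(self.grid, self.groups, effect=1.0, noise_seed=3)
        o1 = compare_global_metrics(table, _groups_df(self.groups), self.grid, n_perm=200, seed=5)
        o2 = compare_global_metrics(table, _groups_df(self.groups), self.grid, n_perm=200, seed=5)
        pd.testing.assert_frame_equal(o1, o2)


class TestCompareNodal:
    def test_per_region_rows_and_effect_localized(self):
        grid = DensityGrid(costs=[0.1])
        groups = [(f"a{i}", "A") for i in range(8)] + [(f"b{i}", "B") for i in range(8)]
        table = _tidy_table(grid, groups, effect=5.0, noise_seed=4, nodal=True)
        out = compare_nodal_metrics(table, _groups_df(groups), grid, n_perm=300, seed=2)
        assert set(out["region_label"]) == {"R001", "R002"}
        clu = out[out["metric"] == "clustering"].set_index("region_label")
        assert clu.loc["R001", "p_parametric"] < 0.01
        assert clu.loc["R002", "p_parametric"] > 0.05

    def test_alteration_frequency_and_retention(self):
        rows = []
        # R001/clustering significant at 12 of 19 costs, R002 at 2
        for k in range(19):
            rows.append(("clustering", 0.04 + 0.02 * k, "node", "R001", 0.01 if k < 12 else 0.5))
            rows.append(("clustering", 0.04 + 0.02 * k, "node", "R002", 0.01 if k < 2 else 0.5))
        tab = pd.DataFrame(rows, columns=["metric", "cost", "scope", "region_label", "p_parametric"])
        freq = nodal_alteration_frequency(tab, retention_threshold=10)
        freq = freq.set_index("region_label")
        assert freq.loc["R001", "alteration_count"] == 12
        assert bool(freq.loc["R001", "retained"])
        assert not bool(freq.loc["R002", "retained"])
        # exactly 10 must NOT be retained (strictly greater than rule)
        tab.loc[(tab["region_label"] == "R001") & (tab["p_parametric"] == 0.01), "p_parametric"] = 0.5
        tab.loc[tab.index[:20:2], "p_parametric"] = 0.01  # first 10 costs for R001
        freq10 = nodal_alteration_frequency(tab, retention_threshold=10).set_index("region_label")
        assert freq10.loc["R001", "alteration_count"] == 10
        assert not bool(freq10.loc["R001", "retained"])


class TestSubgroupsAndHelpers:
    def test_pairwise_contrasts(self):
        grid = DensityGrid(costs=[0.1])
        members = (
            [(f"x{i}", "ADe4") for i in range(3)]
            + [(f"y{i}", "ADe4neg") for i in range(3)]
            + [(f"z{i}", "NCe4neg") for i in range(3)]
        )
        rng = np.random.default_rng(6)
        rows = [
            (sid, 0.1, "clustering", "global", "", rng.normal()) for sid, _ in members
        ]
        table = pd.DataFrame(
            rows, columns=["subject_id", "cost", "metric", "scope", "region_label", "value"]
        )
        out = pairwise_subgroup_contrasts(table, _groups_df(members), grid, n_perm=50, seed=0)
        assert set(out) == {("ADe4", "ADe4neg"), ("ADe4", "NCe4neg"), ("ADe4neg", "NCe4neg")}
        for df in out.values():
            assert len(df) == 1

    def test_underpowered_subgroup_rejected(self):
        grid = DensityGrid(costs=[0.1])
        members = [("x0", "A"), ("x1", "A"), ("y0", "B")]
        table = pd.DataFrame(
            [(s, 0.1, "clustering", "global", "", 0.0) for s, _ in members],
            columns=["subject_id", "cost", "metric", "scope", "region_label", "value"],
        )
        with pytest.raises(UnderpoweredSubgroupError):
            pairwise_subgroup_contrasts(table, _groups_df(members), grid)

    def test_extract_fixed_cost(self):
        df = pd.DataFrame({"cost": [0.1, 0.22, 0.22], "metric": ["a", "a", "b"]})
        out = extract_fixed_cost(df, 0.22)
        assert len(out) == 2 and set(out["metric"]) == {"a", "b"}

    def test_bh_adjust_known_example(self):
        p = np.array([0.01, 0.02, 0.03, 0.04])
        adj = bh_adjust(p)
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])
        p2 = np.array([0.005, 0.5])
        np.testing.assert_allclose(bh_adjust(p2), [0.01, 0.5])
        assert np.all(bh_adjust(np.array([0.9, 0.95])) <= 1.0)
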