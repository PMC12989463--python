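import numpy as np
import pandas as pd
import pytest

from periphyton import (
    AssemblageClusterer,
    TreeChangepointRegressor,
    benchmark_report,
    bray_curtis,
    hierarchical_groups,
    tree_changepoints,
)
from periphyton.benchmarks import benchmark_metric_subset
from periphyton.metrics import metric_metadata


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        counts = pd.DataFrame({"a": [10, 20], "b": [10, 20]}, index=["t1", "t2"])
        d = bray_curtis(counts)
        assert d.loc["a", "b"] == pytest.approx(0.0)
        assert np.allclose(np.diag(d), 0.0)

    def test_disjoint_samples_one(self):
        counts = pd.DataFrame({"a": [10, 0], "b": [0, 30]}, index=["t1", "t2"])
        assert bray_curtis(counts).loc["a", "b"] == pytest.approx(1.0)

    def test_hand_computed_value(self):
        counts = pd.DataFrame({"a": [3, 7], "b": [7, 3]}, index=["t1", "t2"])
        # on proportions: sum|diff| / sum = 0.8 / 2
        assert bray_curtis(counts).loc["a", "b"] == pytest.approx(0.4)

    def test_symmetry_and_bounds(self, marsh):
        std, _, _ = marsh
        d = bray_curtis(std.iloc[:, :20])
        arr = d.to_numpy()
        np.testing.assert_allclose(arr, arr.T)
        assert ((arr >= 0) & (arr <= 1 + 1e-12)).all()


class TestClustering:
    @pytest.fixture
    def two_blobs(self):
        rng = np.random.default_rng(0)
        base1 = np.array([100, 80, 5, 0, 0], float)
        base2 = np.array([0, 0, 5, 90, 110], float)
        cols = {}
        for j in range(6):
            cols[f"low{j}"] = rng.poisson(base1)
            cols[f"high{j}"] = rng.poisson(base2)
        counts = pd.DataFrame(cols, index=[f"t{i}" for i in range(5)])
        mat_p = pd.Series(
            {c: (100.0 if c.startswith("low") else 900.0) for c in counts.columns}
        )
        return counts, mat_p

    def test_planted_partition_recovered(self, two_blobs):
        counts, mat_p = two_blobs
        clus = AssemblageClusterer(cut_height=0.75).fit(counts, mat_p)
        labels = clus.labels_
        assert labels.nunique() == 2
        low = labels[labels.index.str.startswith("low")]
        high = labels[labels.index.str.startswith("high")]
        assert low.nunique() == 1 and high.nunique() == 1
        assert low.iloc[0] != high.iloc[0]
        # groups numbered by increasing mat P; percentiles nondecreasing
        gs = clus.result_.group_summary.set_index("group")
        assert gs.loc[1, "mat_p_p50"] < gs.loc[2, "mat_p_p50"]
        assert (gs["mat_p_p50"] <= gs["mat_p_p75"]).all()
        assert (gs["mat_p_p75"] <= gs["mat_p_p90"]).all()

    def test_cut_extremes(self, two_blobs):
        counts, mat_p = two_blobs
        d = bray_curtis(counts)
        assert hierarchical_groups(d, 0.0).labels.nunique() == len(counts.columns)
        assert hierarchical_groups(d, d.to_numpy().max() + 0.5).labels.nunique() == 1

    def test_cut_out_of_range_rejected(self, two_blobs):
        counts, _ = two_blobs
        with pytest.raises(ValueError):
            hierarchical_groups(bray_curtis(counts), -0.1)


def brute_force_split(y, x, min_leaf):
    """Exhaustive single-split SSE scan (the oracle)."""
    order = np.argsort(x, kind="stable")
    xs, ys = np.asarray(x, float)[order], np.asarray(y, float)[order]
    n = len(xs)
    best = (None, -np.inf)
    sse_tot = ((ys - ys.mean()) ** 2).sum()
    for k in range(min_leaf, n - min_leaf + 1):
        if xs[k - 1] >= xs[k]:
            continue
        l, r = ys[:k], ys[k:]
        red = sse_tot - ((l - l.mean()) ** 2).sum() - ((r - r.mean()) ** 2).sum()
        if red > best[1]:
            best = ((xs[k - 1] + xs[k]) / 2, red)
    return best


class TestTreeChangepoints:
    def test_step_function_breakpoint_in_gap(self):
        rng = np.random.default_rng(1)
        x = np.sort(rng.uniform(100, 800, 60))
        y = np.where(x < 400, 5.0, 1.0) + rng.normal(0, 0.1, 60)
        res = tree_changepoints(y, x, n_perm=199, seed=0)
        lo = x[x < 400].max()
        hi = x[x >= 400].min()
        assert any(lo < bp < hi for bp in res.breakpoints)
        assert all(p <= 0.01 for p in res.p_values)

    def test_two_steps_ordered(self):
        rng = np.random.default_rng(2)
        x = np.sort(rng.uniform(50, 1200, 90))
        y = np.select([x < 300, x < 800], [8.0, 4.0], 0.5) + rng.normal(0, 0.1, 90)
        res = tree_changepoints(y, x, n_perm=199, seed=0)
        assert len(res.breakpoints) >= 2
        assert res.breakpoints == sorted(res.breakpoints)
        assert any(250 < bp < 350 for bp in res.breakpoints)
        assert any(750 < bp < 850 for bp in res.breakpoints)

    def test_constant_response_no_breakpoints(self):
        x = np.linspace(100, 800, 40)
        res = tree_changepoints(np.ones(40), x, seed=0)
        assert res.breakpoints == []

    def test_matches_exhaustive_oracle_single_split(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            n = int(rng.integers(12, 51))
            x = rng.uniform(50, 1200, n).round(-1)
            y = rng.normal(size=n) + (x > 400) * rng.uniform(1, 4)
            cp, red = brute_force_split(y, x, 5)
            if cp is None:
                continue
            res = tree_changepoints(
                y, x, min_leaf=5, max_depth=1, n_perm=99, alpha=1.0, seed=4
            )
            assert len(res.breakpoints) == 1
            assert res.breakpoints[0] == pytest.approx(cp)
            assert res.sse_reductions[0] == pytest.approx(red)

    def test_regressor_predicts_group_means(self):
        x = np.linspace(100, 800, 40)
        y = np.where(x < 400, 5.0, 1.0)
        reg = TreeChangepointRegressor(max_depth=1, n_perm=199, random_state=0).fit(x, y)
        assert len(reg.breakpoints_) == 1
        pred = reg.predict(np.array([150.0, 700.0]))
        np.testing.assert_allclose(pred, [5.0, 1.0])


class TestBenchmarkReport:
    def test_subset_is_thirteen_metrics(self):
        subset = benchmark_metric_subset(metric_metadata())
        assert len(subset) == 13
        assert sum(m.endswith("titan") for m in subset) == 8

    def test_reference_percentiles_linear_interpolation(self):
        values = pd.DataFrame(
            {"richness": [10.0, 12, 20, 25]}, index=list("abcd")
        )
        meta = pd.DataFrame(
            [{"metric": "richness", "type": "richness", "source": "-", "trait": "-"}]
        )
        with pytest.warns(UserWarning):
            report = benchmark_report(
                values,
                meta,
                [100.0, 200.0, 300.0, 400.0],
                minimally_disturbed=list("abcd"),
            )
        p75 = report.query("method == 'minimally_disturbed' and quantity == 'p75'")
        assert p75["mat_p"].iloc[0] == pytest.approx(325.0)

    def test_full_report_rows(self, marsh):
        std, samples, truth = marsh
        from periphyton import build_metric_matrix, wa_table
        from periphyton.titan import CommunityZProfile

        table = pd.concat(
            [
                pd.DataFrame(
                    {"taxon": std.index, "source": s, "trait": truth.trait.to_numpy()}
                )
                for s in ("literature", "regression", "titan")
            ]
        )
        wa = wa_table(std, samples["mat_p"])
        values, meta = build_metric_matrix(std, table, wa["optimum"], wa["tolerance"])
        clus = AssemblageClusterer().fit(std, samples["mat_p"])
        prof = CommunityZProfile(
            np.array([300.0]), np.array([5.0]), np.array([4.0]), 350.0, 480.0
        )
        low_regions = samples.sort_values("mat_p").index[:20]
        report = benchmark_report(
            values,
            meta,
            samples["mat_p"],
            titan_profile=prof,
            cluster_result=clus.result_,
            minimally_disturbed=low_regions,
            tree_kwargs={"n_perm": 99},
            seed=0,
        )
        methods = set(report["method"])
        assert {"titan_sum_z", "minimally_disturbed"} <= methods
        # TITAN row is a pass-through of the community changepoint
        titan_row = report.query("quantity == 'community_z_minus'")
        assert titan_row["mat_p"].iloc[0] == 350.0
        inside = report.query("method == 'tree_changepoint'")["mat_p"]
        assert inside.between(samples["mat_p"].min(), samples["mat_p"].max()).all()
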