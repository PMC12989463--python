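import numpy as np
import pandas as pd
import pytest

from periphyton import (
    WeightedAverageModel,
    build_metric_matrix,
    diversity_metrics,
    metric_metadata,
)
from periphyton.metrics import rloga_metric, simple_trait_metrics, wam_infer


def trait_rows(d):
    return pd.DataFrame(
        [{"taxon": k, "source": "titan", "trait": v} for k, v in d.items()]
    )


@pytest.fixture
def mixed_sample():
    counts = pd.Series({"A": 30, "B": 70, "C": 100})
    rows = trait_rows({"A": "lowP", "B": "highP", "C": "unassigned"})
    return counts, rows


class TestSimpleTraitMetrics:
    def test_unassigned_taxa_excluded_from_denominators(self, mixed_sample):
        counts, rows = mixed_sample
        out = simple_trait_metrics(counts, rows)
        assert out["PropValves_lowP"] == pytest.approx(0.3)
        assert out["PropTaxa_lowP"] == pytest.approx(0.5)
        assert out["noTaxa_lowP"] == 1

    def test_all_low_p(self):
        counts = pd.Series({"A": 10, "B": 5})
        out = simple_trait_metrics(counts, trait_rows({"A": "lowP", "B": "lowP"}))
        assert out["PropValves_lowP"] == 1.0 and out["PropValves_highP"] == 0.0

    def test_only_unassigned_taxa_warns_nan(self):
        counts = pd.Series({"C": 100})
        with pytest.warns(UserWarning, match="no trait-assigned"):
            out = simple_trait_metrics(counts, trait_rows({"C": "unassigned"}))
        assert np.isnan(out["PropValves_lowP"])
        assert out["noTaxa_lowP"] == 0

    def test_complementarity(self, mixed_sample):
        counts, rows = mixed_sample
        out = simple_trait_metrics(counts, rows)
        assert out["PropValves_lowP"] + out["PropValves_highP"] == pytest.approx(1.0)
        assert out["PropTaxa_lowP"] + out["PropTaxa_highP"] == pytest.approx(1.0)


class TestRlogA:
    def test_powers_of_two_give_exact_ratio(self):
        counts = pd.Series({"A": 8, "B": 2})
        out = rloga_metric(counts, trait_rows({"A": "lowP", "B": "highP"}))
        assert out["RlogA_lowP"] == pytest.approx(3 / 4)  # ln8/(ln8+ln2)

    def test_count_one_contributes_nothing(self):
        counts = pd.Series({"A": 1, "B": 8})
        out = rloga_metric(counts, trait_rows({"A": "lowP", "B": "highP"}))
        assert out["RlogA_lowP"] == 0.0

    def test_all_singletons_undefined(self):
        counts = pd.Series({"A": 1, "B": 1})
        with pytest.warns(UserWarning, match="RlogA undefined"):
            out = rloga_metric(counts, trait_rows({"A": "lowP", "B": "highP"}))
        assert np.isnan(out["RlogA_lowP"])

    def test_double_ratio_equals_log_sum_ratio(self):
        """The published per-taxon share formula reduces to Σln(A) ratios."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(3, 12)
            counts = pd.Series(rng.integers(1, 500, n), index=[f"t{i}" for i in range(n)])
            traits = {
                f"t{i}": ("lowP" if rng.random() < 0.4 else "highP") for i in range(n)
            }
            out = rloga_metric(counts, trait_rows(traits))
            logs = np.log(counts.astype(float))
            low = [t for t, tr in traits.items() if tr == "lowP"]
            expected = logs[low].sum() / logs.sum()
            assert out["RlogA_lowP"] == pytest.approx(expected, abs=1e-12)
            assert out["RlogA_lowP"] + out["RlogA_highP"] == pytest.approx(1, abs=1e-12)


class TestDiversity:
    def test_uniform_assemblage_maximal(self):
        out = diversity_metrics([25, 25, 25, 25])
        assert out["richness"] == 4
        assert out["shannon"] == pytest.approx(np.log(4))
        assert out["evenness"] == pytest.approx(1.0)

    def test_single_taxon_degenerate(self):
        out = diversity_metrics([600])
        assert out["richness"] == 1 and out["shannon"] == 0.0
        assert np.isnan(out["evenness"])

    def test_ninety_ten_closed_form(self):
        out = diversity_metrics([90, 10])
        assert out["shannon"] == pytest.approx(-0.9 * np.log(0.9) - 0.1 * np.log(0.1))

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            diversity_metrics([0, 0])


class TestWAM:
    def test_single_taxon_returns_its_optimum(self):
        counts = pd.Series({"Enceverg": 600})
        u = pd.Series({"Enceverg": 112.0})
        assert wam_infer(counts, u, None, "simple") == pytest.approx(112.0)

    def test_equal_tolerances_match_simple(self):
        counts = pd.Series({"A": 300, "B": 300})
        u = pd.Series({"A": 100.0, "B": 300.0})
        t = pd.Series({"A": 50.0, "B": 50.0})
        assert wam_infer(counts, u, t, "simple") == pytest.approx(200.0)
        assert wam_infer(counts, u, t, "tol") == pytest.approx(200.0)

    def test_tolerance_downweighting_pulls_toward_tight_taxon(self):
        counts = pd.Series({"A": 300, "B": 300})
        u = pd.Series({"A": 100.0, "B": 300.0})
        t1 = pd.Series({"A": 50.0, "B": 50.0})
        t2 = pd.Series({"A": 25.0, "B": 50.0})  # halve A's tolerance
        assert wam_infer(counts, u, t2, "tol") < wam_infer(counts, u, t1, "tol")

    def test_no_optima_gives_nan(self):
        counts = pd.Series({"A": 10})
        assert np.isnan(wam_infer(counts, pd.Series({"A": np.nan}), None, "simple"))

    def test_estimator_recovers_gradient(self, marsh):
        std, samples, _ = marsh
        model = WeightedAverageModel().fit(std, samples["mat_p"])
        pred = model.predict(std)
        assert pred.between(model.optima_.min(), model.optima_.max()).all()
        assert np.corrcoef(pred, samples["mat_p"])[0, 1] > 0.8


class TestMetricMatrix:
    @pytest.fixture
    def full_suite(self, marsh):
        std, samples, truth = marsh
        table = pd.concat(
            [
                pd.DataFrame(
                    {"taxon": std.index, "source": s, "trait": truth.trait.to_numpy()}
                )
                for s in ("literature", "regression", "titan")
            ]
        )
        from periphyton import wa_table

        wa = wa_table(std, samples["mat_p"])
        return build_metric_matrix(
            std, table, wa["optimum"], wa["tolerance"]
        )

    def test_twenty_nine_columns_and_factorial(self, full_suite):
        values, meta = full_suite
        assert values.shape[1] == 29
        trait_meta = meta[meta["trait"] != "-"]
        assert len(trait_meta) == 24
        assert trait_meta.groupby(["source", "trait"]).size().eq(4).all()
        assert (meta["source"] == "titan").sum() == 8

    def test_complementarity_across_suite(self, full_suite):
        values, _ = full_suite
        for s in ("literature", "regression", "titan"):
            for m in ("PropValves", "PropTaxa", "RlogA"):
                pair = values[f"{m}_lowP_{s}"] + values[f"{m}_highP_{s}"]
                assert np.allclose(pair.dropna(), 1.0, atol=1e-12)

    def test_order_invariance(self, marsh, full_suite):
        std, samples, truth = marsh
        values, _ = full_suite
        table = pd.concat(
            [
                pd.DataFrame(
                    {"taxon": std.index, "source": s, "trait": truth.trait.to_numpy()}
                )
                for s in ("literature", "regression", "titan")
            ]
        )
        from periphyton import wa_table

        wa = wa_table(std, samples["mat_p"])
        shuffled = std.sample(frac=1, axis=0, random_state=1).sample(
            frac=1, axis=1, random_state=2
        )
        values2, _ = build_metric_matrix(shuffled, table, wa["optimum"], wa["tolerance"])
        pd.testing.assert_frame_equal(values2.loc[values.index], values)

    def test_empty_source_flagged_as_missing(self, marsh):
        std, samples, truth = marsh
        table = pd.concat(
            [
                pd.DataFrame(
                    {"taxon": std.index, "source": s, "trait": truth.trait.to_numpy()}
                )
                for s in ("regression", "titan")
            ]
        )
        from periphyton import wa_table

        wa = wa_table(std, samples["mat_p"])
        values, meta = build_metric_matrix(std, table, wa["optimum"], wa["tolerance"])
        lit_cols = meta.loc[meta["source"] == "literature", "metric"]
        assert len(lit_cols) == 8
        assert values[lit_cols].isna().all().all()
        populated = meta.loc[meta["source"].isin(["regression", "titan"]), "metric"]
        assert len(populated) == 16
        assert values[populated].notna().any().all()

    def test_metadata_suite_is_canonical(self):
        meta = metric_metadata()
        assert len(meta) == 29
        assert meta["metric"].is_unique
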