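import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from regscore.evaluation import (
    GoldStandard,
    expressed_top_tf_check,
    feature_confounder_correlation,
    gold_standard_eval,
    overlap_fraction,
    pairwise_correlation,
)
from regscore.io import FeatureMatrix, Peak

from .oracles import brute_aupr


class TestPairwiseCorrelation:
    def test_rank_preserving_transform_gives_unit_correlation(self, rng):
        x = rng.uniform(0, 10, 30)
        df = pd.DataFrame({"a": x, "b": x**3})
        corr, median = pairwise_correlation(df, subset="all")
        assert corr.at["a", "b"] == pytest.approx(1.0)
        assert median == pytest.approx(1.0)

    def test_matches_rank_then_pearson_oracle(self, rng):
        df = pd.DataFrame(rng.uniform(0, 1, (5, 3)), columns=list("abc"))
        corr, median = pairwise_correlation(df, subset="all")
        ranks = np.column_stack([rankdata(df[c]) for c in df.columns])
        expect = np.corrcoef(ranks, rowvar=False)
        np.testing.assert_allclose(corr.to_numpy(), expect, atol=1e-12)
        iu = np.triu_indices(3, 1)
        assert median == pytest.approx(float(np.median(expect[iu])), abs=1e-12)

    def test_constant_column_excluded_with_warning(self, rng):
        df = pd.DataFrame({"a": rng.uniform(0, 1, 10), "b": rng.uniform(0, 1, 10), "c": 1.0})
        with pytest.warns(UserWarning, match="constant"):
            corr, median = pairwise_correlation(df, subset="all")
        assert np.isnan(corr.at["a", "c"])
        assert median == pytest.approx(corr.at["a", "b"])

    def test_tf_subset_skips_peak_features(self, rng):
        df = pd.DataFrame(
            rng.uniform(0, 1, (20, 3)), columns=["TFA", "TFB", "Peak_Count"]
        )
        corr, _ = pairwise_correlation(FeatureMatrix(values=df, variant="DN"))
        assert list(corr.columns) == ["TFA", "TFB"]


class TestConfounderCorrelation:
    def test_identical_column_fully_correlated(self, rng):
        v = rng.uniform(0, 100, 50)
        df = pd.DataFrame({"TFA": v, "Peak_Length": v, "Peak_Count": rng.uniform(0, 1, 50)})
        out = feature_confounder_correlation(df)
        assert out.at["TFA", "Peak_Length"] == pytest.approx(1.0)

    def test_independent_features_uncorrelated(self, rng):
        n = 1000
        df = pd.DataFrame(
            {"TFA": rng.standard_normal(n), "Peak_Length": rng.standard_normal(n)}
        )
        out = feature_confounder_correlation(df)
        assert abs(out.at["TFA", "Peak_Length"]) < 0.1

    def test_missing_confounders_rejected(self, rng):
        df = pd.DataFrame({"TFA": rng.uniform(0, 1, 10)})
        with pytest.raises(ValueError, match="peak-feature"):
            feature_confounder_correlation(df)


class TestGoldStandardEval:
    def test_all_ranked_in_gs(self):
        coef = pd.Series({"A": 3.0, "B": 2.0, "C": 1.0})
        pr = gold_standard_eval(coef, GoldStandard(frozenset("ABC")))
        assert pr.aupr == pytest.approx(1.0)
        assert (pr.precision == 1.0).all()
        assert (pr.tp, pr.fp, pr.fn) == (3, 0, 0)

    def test_no_ranked_in_gs(self):
        coef = pd.Series({"A": 3.0, "B": 2.0})
        with pytest.warns(UserWarning):
            pr = gold_standard_eval(coef, GoldStandard(frozenset({"Z"})))
        assert pr.aupr == 0.0 and pr.tp == 0

    def test_worked_example_pr_points(self):
        coef = pd.Series({"A": 3.0, "C": 2.0, "B": 1.0})
        pr = gold_standard_eval(coef, GoldStandard(frozenset("AB")))
        np.testing.assert_allclose(pr.precision, [1 / 1, 1 / 2, 2 / 3])
        np.testing.assert_allclose(pr.recall, [1 / 2, 1 / 2, 2 / 2])
        assert pr.aupr == pytest.approx(brute_aupr([True, False, True]), abs=1e-4)

    def test_monotone_transform_invariance(self, rng):
        coef = pd.Series(rng.uniform(0.1, 1.0, 8), index=[f"t{i}" for i in range(8)])
        gs = GoldStandard(frozenset({"t1", "t4", "t6"}))
        a = gold_standard_eval(coef, gs)
        b = gold_standard_eval(coef**3, gs)
        c = gold_standard_eval(np.log(coef), gs)
        assert a.aupr == pytest.approx(b.aupr, rel=1e-12)
        assert a.aupr == pytest.approx(c.aupr, rel=1e-12)

    def test_random_ranking_aupr_near_prevalence(self, rng):
        names = [f"t{i}" for i in range(40)]
        gs = GoldStandard(frozenset(names[:10]))  # prevalence 0.25
        auprs = []
        for _ in range(200):
            coef = pd.Series(rng.permutation(np.linspace(1, 2, 40)), index=names)
            auprs.append(gold_standard_eval(coef, gs).aupr)
        assert np.mean(auprs) == pytest.approx(0.25, abs=0.05)

    def test_absolute_ranking_flag(self):
        coef = pd.Series({"A": -5.0, "B": 1.0})
        gs = GoldStandard(frozenset({"A"}))
        signed = gold_standard_eval(coef, gs, absolute=False)
        absd = gold_standard_eval(coef, gs, absolute=True)
        assert absd.precision[0] == 1.0 and signed.precision[0] == 0.0

    def test_empty_gold_standard_rejected(self):
        with pytest.raises(ValueError):
            GoldStandard(frozenset())


class TestExpressedTopTfCheck:
    def test_identical_models_give_p_one(self):
        coef = pd.Series({"A": 1.0, "B": 0.5, "C": 0.0})
        expr = pd.Series({"A": 10.0, "B": 5.0})
        ex_o, ex_p, p = expressed_top_tf_check(coef, coef, expr, k=2)
        assert p == 1.0
        pd.testing.assert_series_equal(ex_o, ex_p)

    def test_fully_separated_samples_significant(self):
        names = [f"t{i}" for i in range(20)]
        co = pd.Series(np.linspace(1, 2, 20), index=names)
        cp = pd.Series(np.linspace(1, 2, 20), index=[f"u{i}" for i in range(20)])
        expr = pd.Series({**{n: 10.0 for n in names}, **{f"u{i}": 0.0 for i in range(20)}})
        _, _, p = expressed_top_tf_check(co, cp, expr, k=20)
        assert p < 0.001

    def test_unmappable_tf_counts_as_zero(self):
        co = pd.Series({"A": 2.0, "MYSTERY": 1.0})
        ex_o, _, _ = expressed_top_tf_check(co, co, pd.Series({"A": 7.0}), k=2)
        assert ex_o["MYSTERY"] == 0.0

    def test_reduced_k_from_original_selection(self):
        co = pd.Series({"A": 1.0, "B": 0.0, "C": 0.0})  # only one selected
        cp = pd.Series({"A": 1.0, "B": 2.0, "C": 3.0})
        expr = pd.Series({"A": 5.0, "B": 1.0, "C": 2.0})
        ex_o, ex_p, _ = expressed_top_tf_check(co, cp, expr, k=100)
        assert len(ex_o) == len(ex_p) == 1

    def test_all_zero_coefficients_rejected(self):
        z = pd.Series({"A": 0.0})
        with pytest.raises(ValueError):
            expressed_top_tf_check(z, z, pd.Series({"A": 1.0}))


class TestOverlapFraction:
    def test_identical_sets(self):
        peaks = [Peak("chr1", 0, 10), Peak("chr1", 50, 70)]
        assert overlap_fraction(peaks, list(peaks)) == 1.0

    def test_disjoint_sets(self):
        q = [Peak("chr1", 0, 10)]
        r = [Peak("chr1", 20, 30), Peak("chr2", 0, 10)]
        assert overlap_fraction(q, r) == 0.0

    def test_partial_overlap_hand_case(self):
        q = [
            Peak("chr1", 0, 100),
            Peak("chr1", 200, 300),
            Peak("chr1", 400, 500),
            Peak("chr2", 0, 50),
        ]
        r = [Peak("chr1", 90, 210), Peak("chr3", 0, 1000)]
        # first two query peaks hit the chr1 reference, others miss
        assert overlap_fraction(q, r) == pytest.approx(0.5)

    def test_matches_pairwise_interval_oracle(self, rng):
        from .conftest import random_peaks

        q = random_peaks(rng, 30, span=5000)
        r = random_peaks(rng, 10, span=5000)
        expect = np.mean(
            [any(p.start < x.end and p.end > x.start for x in r) for p in q]
        )
        assert overlap_fraction(q, r) == pytest.approx(expect)

    def test_window_restriction(self):
        q = [Peak("chr1", 0, 10), Peak("chr1", 1000, 1010)]
        r = [Peak("chr1", 0, 2000)]
        # only the first query peak lies in the window; it overlaps
        assert overlap_fraction(q, r, windows=[("chr1", 0, 100)]) == 1.0
        assert overlap_fraction(q, r, windows=[("chr1", 5000, 6000)]) == 0.0
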