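import math

import numpy as np
import pandas as pd
import pytest

from regscore.affinity import AffinityTable
from regscore.io import FeatureMatrix, GeneModel, Peak
from regscore.scoring import (
    DecayParams,
    assign_windows,
    build_design,
    chip_peak_features,
    chip_scores_C,
    chip_scores_CN,
    chip_scores_CPF,
    decay_weight,
    dnase_scores,
)

from .conftest import random_genes, random_peaks
from .oracles import brute_window

P = DecayParams()


def affinity_table_for(peaks, tf_values: dict[str, float], widths=None):
    """Constant-per-TF affinity table over the given peaks."""
    df = pd.DataFrame(
        {tf: [v] * len(peaks) for tf, v in tf_values.items()},
        index=pd.Index([p.key for p in peaks], name="peak"),
    )
    return AffinityTable(df, widths or {tf: 8 for tf in tf_values})


class TestDecayWeight:
    def test_zero_distance(self):
        assert decay_weight(0, P) == 1.0

    def test_one_scale_length(self):
        assert decay_weight(5000, P) == pytest.approx(math.exp(-1), rel=1e-12)
        assert decay_weight(5000, P) == pytest.approx(0.3678794, rel=1e-6)

    def test_default_scale_is_5kb(self):
        assert P.d0 == 5000.0 and P.window == 50000

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            decay_weight(-1, P)


class TestAssignWindows:
    def test_peak_midpoint_at_tss_distance_zero(self):
        g = GeneModel("g", "chr1", "+", tss=50001)  # tss0 = 50000
        pk = Peak("chr1", 49950, 50050)  # midpoint 50000
        (a,) = assign_windows([g], [pk], P)
        assert a.peak_indices.tolist() == [0]
        assert a.distances[0] == 0.0

    def test_boundary_overlap_admits_peak(self):
        g = GeneModel("g", "chr1", "+", tss=50001)
        pk = Peak("chr1", 50000 + 24990, 50000 + 25010)  # straddles window edge
        (a,) = assign_windows([g], [pk], P)
        assert a.peak_indices.tolist() == [0]

    def test_fully_outside_excluded(self):
        g = GeneModel("g", "chr1", "+", tss=50001)
        pk = Peak("chr1", 50000 + 25000, 50000 + 25100)  # starts exactly at edge
        (a,) = assign_windows([g], [pk], P)
        assert a.peak_indices.size == 0

    def test_matches_brute_force_pairwise_overlap(self, rng):
        genes = random_genes(rng, 3)
        peaks = random_peaks(rng, 5)
        for g, a in zip(genes, assign_windows(genes, peaks, P)):
            expect = brute_window(g, peaks, P.window, P.d0)
            got = {(peaks[i].start, peaks[i].end) for i in a.peak_indices}
            assert got == {(p.start, p.end) for p, _ in expect}
            weights = sorted(np.exp(-a.distances / P.d0))
            assert weights == pytest.approx(sorted(w for _, w in expect), rel=1e-12)


class TestChipScores:
    def g(self, tss=50001):
        return GeneModel("g", "chr1", "+", tss=tss)

    def test_single_peak_at_tss(self):
        fm = chip_scores_C([self.g()], {"TFA": [Peak("chr1", 49950, 50050, score=3.5)]}, P)
        assert fm.values.at["g", "TFA"] == pytest.approx(3.5)
        assert fm.variant == "C"

    def test_two_peak_hand_evaluation(self):
        peaks = [
            Peak("chr1", 54950, 55050, score=2.0),  # midpoint 55000, d=5000
            Peak("chr1", 49950, 50050, score=1.0),  # d=0
        ]
        fm = chip_scores_C([self.g()], {"TFA": peaks}, P)
        assert fm.values.at["g", "TFA"] == pytest.approx(2 * math.exp(-1) + 1, rel=1e-12)
        assert fm.values.at["g", "TFA"] == pytest.approx(1.735759, abs=1e-6)

    def test_no_peaks_in_window(self):
        fm = chip_scores_C([self.g()], {"TFA": [Peak("chr2", 0, 100, score=9)]}, P)
        assert fm.values.at["g", "TFA"] == 0.0

    def test_peak_features_single_peak(self):
        c, l = chip_peak_features([self.g()], {"TFA": [Peak("chr1", 49950, 50050, score=5)]}, P)
        assert c["g"] == pytest.approx(1.0)
        assert l["g"] == pytest.approx(100.0)

    def test_peak_features_score_blind(self):
        # presence indicator: a zero-score peak still counts
        c, _ = chip_peak_features([self.g()], {"TFA": [Peak("chr1", 49950, 50050, score=0)]}, P)
        assert c["g"] == pytest.approx(1.0)

    def test_peak_features_two_tfs_at_5kb(self):
        pk = [Peak("chr1", 54950, 55050, score=1.0)]
        c, _ = chip_peak_features([self.g()], {"TFA": pk, "TFB": list(pk)}, P)
        assert c["g"] == pytest.approx(2 * math.exp(-1), rel=1e-12)
        assert c["g"] == pytest.approx(0.735759, abs=1e-6)

    def test_cn_normalisation_and_worked_ratio(self):
        genes = [self.g()]
        chip = {
            "TFA": [
                Peak("chr1", 54950, 55050, score=2.0),
                Peak("chr1", 49950, 50050, score=1.0),
            ]
        }
        C = chip_scores_C(genes, chip, P)
        c, l = chip_peak_features(genes, chip, P)
        CN = chip_scores_CN(C, c, l)
        a = 2 * math.exp(-1) + 1
        cC = math.exp(-1) + 1
        assert CN.values.at["g", "TFA"] == pytest.approx(a / cC, rel=1e-12)
        assert list(CN.values.columns) == ["TFA", "Peak_Count", "Peak_Length"]

    def test_cn_zero_peak_gene_all_zero(self):
        genes = [self.g(), GeneModel("h", "chr9", "+", tss=1000)]
        chip = {"TFA": [Peak("chr1", 49950, 50050, score=1.0)]}
        C = chip_scores_C(genes, chip, P)
        c, l = chip_peak_features(genes, chip, P)
        CN = chip_scores_CN(C, c, l)
        assert (CN.values.loc["h"] == 0).all()

    def test_cn_times_count_reconstructs_c(self, rng):
        genes = random_genes(rng, 6)
        chip = {f"TF{i}": random_peaks(rng, 8) for i in range(4)}
        C = chip_scores_C(genes, chip, P)
        c, l = chip_peak_features(genes, chip, P)
        CN = chip_scores_CN(C, c, l)
        back = CN.values[C.values.columns].mul(c, axis=0)
        mask = c > 0
        np.testing.assert_allclose(
            back.loc[mask].to_numpy(), C.values.loc[mask].to_numpy(), rtol=1e-12, atol=0
        )

    def test_cpf_columns(self, rng):
        genes = random_genes(rng, 3)
        chip = {"TFA": random_peaks(rng, 5)}
        c, l = chip_peak_features(genes, chip, P)
        fm = chip_scores_CPF(c, l)
        assert list(fm.values.columns) == ["Peak_Count", "Peak_Length"]
        assert fm.variant == "CPF"


class TestDnaseScores:
    def setup_method(self):
        self.gene = GeneModel("g", "chr1", "+", tss=50001)
        self.peak = Peak("chr1", 49971, 50031, signal=2.0)  # midpoint 50001, |p|=60

    def run(self, variant, aff=0.5, width=11, peak=None):
        peak = peak or self.peak
        tab = affinity_table_for([peak], {"TFA": aff}, {"TFA": width})
        return dnase_scores([self.gene], [peak], tab, P, variant)

    def test_D_single_peak(self):
        peak = Peak("chr1", 49970, 50030, signal=2.0)  # midpoint 50000 = tss0, d=0
        fm = self.run("D", peak=peak)
        assert fm.values.at["g", "TFA"] == pytest.approx(0.5, rel=1e-12)

    def test_DS_scales_by_signal(self):
        peak = Peak("chr1", 49970, 50030, signal=2.0)
        fm = self.run("DS", peak=peak)
        assert fm.values.at["g", "TFA"] == pytest.approx(1.0, rel=1e-12)

    def test_DN_binding_site_normalisation(self):
        peak = Peak("chr1", 49970, 50030, signal=2.0)  # |p|=60, |m|=11 -> 50 sites
        fm = self.run("DN", peak=peak)
        assert fm.values.at["g", "TFA"] == pytest.approx(0.5 / 50, rel=1e-12)
        assert fm.values.at["g", "Peak_Count"] == pytest.approx(1.0)
        assert fm.values.at["g", "Peak_Length"] == pytest.approx(60.0)

    def test_short_peak_divisor_clamped(self):
        peak = Peak("chr1", 49997, 50003, signal=1.0)  # |p|=6 < |m|=11
        fm = self.run("DN", peak=peak)
        assert fm.values.at["g", "TFA"] == pytest.approx(0.5, rel=1e-12)

    @pytest.mark.parametrize(
        "variant,cols",
        [
            ("D", ["TFA", "TFB"]),
            ("DS", ["TFA", "TFB"]),
            ("DN", ["TFA", "TFB", "Peak_Count", "Peak_Length"]),
            ("DSN", ["TFA", "TFB", "Peak_Count", "Peak_Length", "Peak_Signal"]),
            ("DPF", ["Peak_Count", "Peak_Length"]),
            ("DPFS", ["Peak_Count", "Peak_Length", "Peak_Signal"]),
        ],
    )
    def test_column_contract_per_variant(self, rng, variant, cols):
        peaks = random_peaks(rng, 6)
        tab = affinity_table_for(peaks, {"TFA": 0.3, "TFB": 0.1})
        fm = dnase_scores([self.gene], peaks, tab, P, variant)
        assert list(fm.values.columns) == cols
        assert fm.variant == variant

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="unknown DNase variant"):
            self.run("DX")

    def test_missing_affinity_for_assigned_peak(self):
        other = Peak("chr9", 0, 50)
        tab = affinity_table_for([other], {"TFA": 0.5})
        with pytest.raises(ValueError, match="no affinities"):
            dnase_scores([self.gene], [self.peak], tab, P, "D")

    def test_peak_features_are_motif_blind(self, rng):
        peaks = random_peaks(rng, 10)
        t1 = affinity_table_for(peaks, {"TFA": 0.9, "TFB": 0.2}, {"TFA": 6, "TFB": 12})
        t2 = affinity_table_for(peaks, {"TFA": 0.1, "TFB": 0.7}, {"TFA": 9, "TFB": 4})
        g = [self.gene]
        for variant in ("DPF", "DPFS"):
            a = dnase_scores(g, peaks, t1, P, variant)
            b = dnase_scores(g, peaks, t2, P, variant)
            pd.testing.assert_frame_equal(a.values, b.values)


class TestDecayLimits:
    def test_d0_to_infinity_gives_unweighted_sum(self, rng):
        genes = random_genes(rng, 4)
        chip = {"TFA": random_peaks(rng, 10)}
        flat = DecayParams(d0=1e15, window=50000)
        fm = chip_scores_C(genes, chip, flat)
        for g, a in zip(genes, assign_windows(genes, chip["TFA"], flat)):
            expect = sum(chip["TFA"][i].score for i in a.peak_indices)
            assert fm.values.at[g.gene_id, "TFA"] == pytest.approx(expect, rel=1e-9)

    def test_tiny_window_zeroes_everything(self, rng):
        genes = random_genes(rng, 4)
        chip = {"TFA": random_peaks(rng, 10)}
        # a 2 bp window admits almost nothing; relocate peaks far away to be exact
        chip = {"TFA": [Peak("chr1", 90000, 90100, score=5)]}
        genes = [GeneModel("g", "chr1", "+", tss=10)]
        fm = chip_scores_C(genes, chip, DecayParams(d0=5000, window=2))
        assert (fm.values.to_numpy() == 0).all()


class TestBuildDesign:
    def test_log_transform_values(self):
        fm = FeatureMatrix(
            values=pd.DataFrame({"TFA": [0.0, 7.0]}, index=["g1", "g2"]), variant="D"
        )
        X, y = build_design(fm, pd.Series({"g1": 7.0, "g2": 0.0}))
        assert X.at["g1", "TFA"] == 0.0
        assert X.at["g2", "TFA"] == pytest.approx(3.0)
        assert y["g1"] == pytest.approx(3.0) and y["g2"] == 0.0

    def test_intersection_sorted(self):
        fm = FeatureMatrix(
            values=pd.DataFrame({"TFA": [1.0, 2.0, 3.0, 4.0, 5.0]},
                                index=["e", "d", "c", "b", "a"]),
            variant="D",
        )
        expr = pd.Series({"a": 1.0, "c": 2.0, "e": 3.0, "zz": 4.0})
        X, y = build_design(fm, expr)
        assert list(X.index) == ["a", "c", "e"] == list(y.index)

    def test_empty_intersection_errors(self):
        fm = FeatureMatrix(values=pd.DataFrame({"TFA": [1.0]}, index=["g1"]), variant="D")
        with pytest.raises(ValueError, match="at least 2 genes"):
            build_design(fm, pd.Series({"x": 1.0, "y": 2.0}))
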