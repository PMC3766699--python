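import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mircircuitnet import preprocess
from mircircuitnet.io_formats import ExpressionMatrix, SampleSheet

from conftest import random_matrix


def _sheet_ntm(n_per_class=26):
    rows = []
    for i in range(n_per_class):
        for cls in ("N", "T", "M"):
            rows.append({"sample_id": f"{cls}{i}", "patient_id": f"p{cls}{i}", "tissue": cls})
    return SampleSheet(pd.DataFrame(rows))


def _matrix_for(sheet, values):
    cols = sheet.sample_ids
    return ExpressionMatrix(
        pd.DataFrame(values, index=[f"f{i}" for i in range(len(values))], columns=cols),
        "miRNA",
    )


class TestDetectionFilter:
    def test_all_detected_is_identity(self):
        sheet = _sheet_ntm()
        m = _matrix_for(sheet, np.full((5, 78), 6.0))
        out = preprocess.filter_mirnas_by_detection(m, sheet, min_detected=20)
        assert out.feature_ids == m.feature_ids

    def test_threshold_and_class_exemption_rules(self):
        sheet = _sheet_ntm()
        n = 78
        values = np.full((3, n), 0.0)  # below the detection floor everywhere
        tissue = np.array([sheet.tissue_of()[s] for s in sheet.sample_ids])
        # f0: detected in 25 scattered samples -> retained by count
        values[0, :25] = 6.0
        # f1: detected in 10 samples spread over all classes -> dropped
        for cls, k in (("N", 4), ("T", 3), ("M", 3)):
            idx = np.where(tissue == cls)[0][:k]
            values[1, idx] = 6.0
        # f2: detected in only 15 samples, but every undetected sample is class M
        values[2, tissue != "M"] = 0.0
        idx_nt = np.where(tissue != "M")[0][:15]
        values[2, :] = 0.0
        values[2, idx_nt] = 6.0
        # make remaining undetected samples all M: detect everything not in M
        values[2, tissue != "M"] = 6.0
        values[2, tissue == "M"] = 0.0
        m = _matrix_for(sheet, values)
        out = preprocess.filter_mirnas_by_detection(m, sheet, min_detected=20)
        assert "f0" in out.feature_ids
        assert "f1" not in out.feature_ids
        assert "f2" in out.feature_ids  # class-exemption: undetected only in M

    def test_exemption_applies_even_below_count_threshold(self):
        sheet = _sheet_ntm()
        tissue = np.array([sheet.tissue_of()[s] for s in sheet.sample_ids])
        values = np.zeros((1, 78))
        idx_n = np.where(tissue == "N")[0][:10]
        values[0, idx_n] = 6.0  # 10 detections, all undetected are in T or M? no:
        m = _matrix_for(sheet, values)
        # undetected spread over N, T and M -> dropped
        out = preprocess.filter_mirnas_by_detection(m, sheet, min_detected=20)
        assert out.n_features == 0
        # now detected everywhere except class T -> exempt despite only 52 < 78
        values2 = np.full((1, 78), 6.0)
        values2[0, tissue == "T"] = 0.0
        m2 = _matrix_for(sheet, values2)
        out2 = preprocess.filter_mirnas_by_detection(m2, sheet, min_detected=60)
        assert out2.n_features == 1

    def test_shape_mismatched_detection_matrix_rejected(self, tiny_matrix, tiny_sheet):
        wrong = pd.DataFrame(True, index=["x"], columns=["s1"])
        with pytest.raises(ValueError, match="detection"):
            preprocess.filter_mirnas_by_detection(tiny_matrix, tiny_sheet, detection=wrong)

    def test_idempotent(self):
        sheet = _sheet_ntm()
        m = random_matrix(30, 78, seed=1, columns=sheet.sample_ids)
        once = preprocess.filter_mirnas_by_detection(m, sheet)
        twice = preprocess.filter_mirnas_by_detection(once, sheet)
        pd.testing.assert_frame_equal(once.data, twice.data)


class TestVariabilityFilter:
    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(n=st.integers(2, 200), f=st.floats(0.0, 0.99))
    def test_retained_count_follows_floor_rule(self, n, f):
        m = random_matrix(n, 4, seed=0)
        out = preprocess.filter_genes_by_variability(m, drop_fraction=f)
        assert out.n_features == int(np.floor((1 - f) * n))

    def test_ten_features_drop_thirty_percent_keeps_seven(self):
        m = random_matrix(10, 5, seed=2)
        assert preprocess.filter_genes_by_variability(m, 0.30).n_features == 7

    def test_keeps_most_variable_and_preserves_input_order(self):
        data = pd.DataFrame(
            {"s1": [0, 0, 0], "s2": [1.0, 3.0, 2.0]},
            index=["low", "high", "mid"],
        )
        out = preprocess.filter_genes_by_variability(ExpressionMatrix(data, "gene"), 0.30)
        assert out.feature_ids == ["high", "mid"]

    def test_all_equal_variances_tie_break_by_input_order(self):
        data = pd.DataFrame(
            np.tile([0.0, 1.0], (10, 1)), index=[f"f{i}" for i in range(10)],
            columns=["s1", "s2"],
        )
        out = preprocess.filter_genes_by_variability(ExpressionMatrix(data, "gene"), 0.30)
        assert out.feature_ids == [f"f{i}" for i in range(7)]

    def test_invalid_drop_fraction_rejected(self, tiny_matrix):
        with pytest.raises(ValueError):
            preprocess.filter_genes_by_variability(tiny_matrix, 1.0)

    def test_idempotent(self):
        m = random_matrix(50, 6, seed=3)
        once = preprocess.filter_genes_by_variability(m, 0.0)
        pd.testing.assert_frame_equal(
            preprocess.filter_genes_by_variability(once, 0.0).data, once.data
        )


class TestMeanSignalFilter:
    def test_threshold_is_strict(self):
        data = pd.DataFrame(
            {"s1": [5.1, 4.9], "s2": [5.1, 4.9]}, index=["keep", "drop"]
        )
        out = preprocess.filter_by_mean_signal(ExpressionMatrix(data, "miRNA"), floor=5.0)
        assert out.feature_ids == ["keep"]

    def test_empty_matrix_passes_through(self):
        empty = ExpressionMatrix(pd.DataFrame(columns=["s1"], dtype=float), "miRNA")
        assert preprocess.filter_by_mean_signal(empty).n_features == 0

    def test_hand_computed_means_fixture(self):
        values = np.array(
            [[4, 5, 6], [7, 7, 7], [1, 2, 3], [5, 5, 5.1], [9, 1, 6]], dtype=float
        )
        m = ExpressionMatrix(
            pd.DataFrame(values, index=list("abcde"), columns=["s1", "s2", "s3"]),
            "miRNA",
        )
        out = preprocess.filter_by_mean_signal(m, floor=5.0)
        # hand means: 5.0, 7.0, 2.0, 5.0333, 5.3333
        assert out.feature_ids == ["b", "d", "e"]


class TestTransitionPatterns:
    def test_all_constant_matrix_all_unchanged(self):
        sheet = _sheet_ntm()
        m = _matrix_for(sheet, np.zeros((4, 78)))
        counts = preprocess.transition_pattern_counts(m, sheet)
        assert (counts.counts["unchanged"] == 4).all()

    def test_two_log2_units_up_in_t(self):
        sheet = _sheet_ntm()
        tissue = np.array([sheet.tissue_of()[s] for s in sheet.sample_ids])
        values = np.full((1, 78), 6.0)
        values[0, tissue == "T"] = 8.0
        counts = preprocess.transition_pattern_counts(_matrix_for(sheet, values), sheet)
        assert counts.counts.loc["TvN", "up"] == 1
        assert counts.counts.loc["MvT", "down"] == 1  # M back at 6 vs T at 8

    def test_counts_conserve_feature_total(self):
        sheet = _sheet_ntm()
        m = random_matrix(40, 78, seed=4, scale=2.0, columns=sheet.sample_ids)
        counts = preprocess.transition_pattern_counts(m, sheet)
        assert counts.total("TvN") == 40
        assert counts.total("MvT") == 40

    def test_reversing_contrast_swaps_up_and_down(self):
        sheet = _sheet_ntm()
        m = random_matrix(40, 78, seed=5, scale=2.0, columns=sheet.sample_ids)
        fwd = preprocess.transition_pattern_counts(m, sheet, contrasts=(("T", "N"),))
        rev = preprocess.transition_pattern_counts(m, sheet, contrasts=(("N", "T"),))
        assert fwd.counts.loc["TvN", "up"] == rev.counts.loc["NvT", "down"]
        assert fwd.counts.loc["TvN", "down"] == rev.counts.loc["NvT", "up"]


class TestClustering:
    def test_two_separated_groups_recovered(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 0.3, (30, 10)) + np.linspace(0, 5, 30)[:, None]
        b = -a + rng.normal(0, 0.3, (30, 10))
        data = pd.DataFrame(
            np.hstack([a, b]), index=[f"f{i}" for i in range(30)],
            columns=[f"ga{i}" for i in range(10)] + [f"gb{i}" for i in range(10)],
        )
        res = preprocess.cluster_samples(ExpressionMatrix(data + 8, "gene"), n_clusters=2)
        labels_a = {res.flat_clusters[f"ga{i}"] for i in range(10)}
        labels_b = {res.flat_clusters[f"gb{i}"] for i in range(10)}
        assert len(labels_a) == 1 and len(labels_b) == 1 and labels_a != labels_b

    def test_identical_samples_merge_at_zero_height(self):
        data = pd.DataFrame(
            np.tile(np.arange(5.0), (3, 1)).T, index=[f"f{i}" for i in range(5)],
            columns=["s1", "s2", "s3"],
        )
        res = preprocess.cluster_samples(ExpressionMatrix(data, "gene"))
        assert np.allclose(res.merge_tree[:, 2], 0.0, atol=1e-10)

    def test_column_order_invariance(self):
        m = random_matrix(20, 8, seed=7)
        shuffled = ExpressionMatrix(m.data[m.data.columns[::-1]], "miRNA")
        r1 = preprocess.cluster_samples(m)
        r2 = preprocess.cluster_samples(shuffled)
        np.testing.assert_allclose(r1.merge_tree, r2.merge_tree)
        pd.testing.assert_frame_equal(r1.cophenetic, r2.cophenetic)


class TestPatientPairing:
    def test_duplicated_tm_profiles_score_one(self):
        rng = np.random.default_rng(8)
        rows = []
        cols, col_rows = [], []
        for p in range(6):
            profile = rng.normal(6, 1, 25)
            for cls in ("T", "M"):
                cols.append(f"p{p}{cls}")
                col_rows.append(profile + rng.normal(0, 0.01, 25))
                rows.append({"sample_id": f"p{p}{cls}", "patient_id": f"p{p}", "tissue": cls})
        sheet = SampleSheet(pd.DataFrame(rows))
        m = ExpressionMatrix(
            pd.DataFrame(np.array(col_rows).T, index=[f"f{i}" for i in range(25)], columns=cols),
            "miRNA",
        )
        res = preprocess.cluster_samples(m)
        assert preprocess.patient_pairing_score(res, sheet) == 1.0

    def test_shuffled_labels_score_near_chance(self):
        rng = np.random.default_rng(9)
        n_pat = 20
        cols = [f"p{p}{c}" for p in range(n_pat) for c in ("T", "M")]
        m = ExpressionMatrix(
            pd.DataFrame(rng.normal(6, 1, (30, 2 * n_pat)),
                         index=[f"f{i}" for i in range(30)], columns=cols),
            "miRNA",
        )
        rows = [{"sample_id": c, "patient_id": c[:-1], "tissue": c[-1]} for c in cols]
        sheet = SampleSheet(pd.DataFrame(rows))
        res = preprocess.cluster_samples(m)
        # chance of mutual-NN pairing ~ 1/(2n-1); allow generous slack
        assert preprocess.patient_pairing_score(res, sheet) < 0.35

    def test_no_tm_patient_is_error(self, tiny_matrix):
        sheet = SampleSheet(pd.DataFrame(
            {"sample_id": ["s1", "s2", "s3"], "patient_id": ["p1", "p2", "p3"],
             "tissue": ["N", "T", "M"]}
        ))
        res = preprocess.cluster_samples(tiny_matrix)
        with pytest.raises(ValueError, match="both"):
            preprocess.patient_pairing_score(res, sheet)


class TestBiogenesisBalance:
    def test_identical_class_distributions_give_p_one(self):
        sheet = _sheet_ntm(10)
        tissue = np.array([sheet.tissue_of()[s] for s in sheet.sample_ids])
        values = np.zeros((2, 30))
        per_class = np.linspace(4, 8, 10)
        for cls in ("N", "T", "M"):
            values[0, tissue == cls] = per_class
            values[1, tissue == cls] = per_class + 1
        m = _matrix_for(sheet, values)
        balance = preprocess.biogenesis_balance(["f0", "f1"], m, sheet)
        assert (balance["p_value"] > 0.99).all()

    def test_shifted_class_detected(self):
        sheet = _sheet_ntm(26)
        rng = np.random.default_rng(10)
        tissue = np.array([sheet.tissue_of()[s] for s in sheet.sample_ids])
        values = rng.normal(6, 1, (3, 78))
        values[:, tissue == "T"] += 2.0
        balance = preprocess.biogenesis_balance(["f0", "f1", "f2"], _matrix_for(sheet, values), sheet)
        nt = balance.set_index(["class_a", "class_b"]).loc[("N", "T"), "p_value"]
        assert nt < 0.01

    def test_means_match_hand_arithmetic(self):
        sheet = SampleSheet(pd.DataFrame(
            {"sample_id": ["n1", "n2", "t1", "t2", "m1", "m2"],
             "patient_id": list("abcdef"),
             "tissue": ["N", "N", "T", "T", "M", "M"]}
        ))
        values = np.array([[1, 3, 5, 7, 2, 4], [2, 4, 6, 8, 3, 5], [0, 2, 4, 6, 1, 3]],
                          dtype=float)
        m = ExpressionMatrix(
            pd.DataFrame(values, index=["f0", "f1", "f2"], columns=sheet.sample_ids),
            "miRNA",
        )
        balance = preprocess.biogenesis_balance(["f0", "f1", "f2"], m, sheet)
        row = balance.set_index(["class_a", "class_b"]).loc[("N", "T")]
        assert row["mean_a"] == pytest.approx(2.0)   # (1+3+2+4+0+2)/6
        assert row["mean_b"] == pytest.approx(6.0)   # (5+7+6+8+4+6)/6


class TestExpressionEntropy:
    def test_constant_profile_zero_bits(self):
        assert preprocess.expression_entropy(np.full(50, 3.3)) == 0.0

    def test_uniform_over_eight_bins_three_bits(self):
        # 8 occupied equal-count bins out of 8 -> H = 3 bits
        profile = np.repeat(np.arange(8, dtype=float) + 0.5, 10)
        assert preprocess.expression_entropy(profile, n_bins=8) == pytest.approx(3.0)

    def test_matches_direct_histogram_computation(self):
        rng = np.random.default_rng(11)
        profile = rng.normal(6, 1.5, 200)
        counts, _ = np.histogram(profile, bins=10, range=(profile.min(), profile.max()))
        p = counts[counts > 0] / 200
        expected = -(p * np.log2(p)).sum()
        assert preprocess.expression_entropy(profile) == pytest.approx(expected)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_bounded_by_log2_nbins_and_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        profile = rng.normal(0, 1, 60)
        h = preprocess.expression_entropy(profile, n_bins=10)
        assert 0.0 <= h <= np.log2(10) + 1e-12
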