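import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conftest import brute_force_signed_rank_p
from reeffusion.datamodel import DEFAULT_LABELS, LabelSet
from reeffusion.evaluation import (
    build_report,
    confusion_matrix,
    error_reduction,
    per_image_accuracy,
    pr_curves,
    summarize_accuracy,
    wilcoxon_paired,
)


class TestAccuracy:
    def test_single_image_mean_equals_pointwise_accuracy(self):
        truth = ["Acropora", "Faviidae", "unknown", "Millepora"]
        pred = ["Acropora", "Faviidae", "Acropora", "Millepora"]
        acc = per_image_accuracy(["i"] * 4, truth, pred)
        assert acc == {"i": 0.75}

    def test_summary_mean_and_se(self):
        acc = {"a": 0.8, "b": 0.9, "c": 1.0}
        mean, se = summarize_accuracy(acc)
        assert mean == pytest.approx(0.9)
        assert se == pytest.approx(np.std([0.8, 0.9, 1.0], ddof=1) / np.sqrt(3))


class TestConfusionMatrix:
    def test_perfect_predictions_give_identity(self, labelset):
        truth = list(DEFAULT_LABELS)
        norm, counts = confusion_matrix(truth, truth, labelset)
        np.testing.assert_array_equal(norm, np.eye(10))
        np.testing.assert_array_equal(counts, np.ones(10))

    def test_hand_built_three_class_case(self, labelset):
        truth = ["Acropora", "Acropora", "Acropora", "Faviidae", "Faviidae", "unknown"]
        pred = ["Acropora", "Acropora", "Faviidae", "Faviidae", "unknown", "unknown"]
        norm, counts = confusion_matrix(truth, pred, labelset)
        i_acr, i_fav, i_unk = (
            labelset.index("Acropora"),
            labelset.index("Faviidae"),
            labelset.index("unknown"),
        )
        assert counts[i_acr] == 3 and counts[i_fav] == 2 and counts[i_unk] == 1
        assert norm[i_acr, i_acr] == pytest.approx(2 / 3)
        assert norm[i_acr, i_fav] == pytest.approx(1 / 3)
        assert norm[i_fav, i_fav] == pytest.approx(1 / 2)
        assert norm[i_unk, i_unk] == 1.0

    def test_empty_class_row_is_zeros_with_zero_count(self, labelset):
        norm, counts = confusion_matrix(["Acropora"], ["Acropora"], labelset)
        i_mil = labelset.index("Millepora")
        assert counts[i_mil] == 0
        assert (norm[i_mil] == 0).all()

    def test_rows_sum_to_one_and_counts_conserved(self, rng, labelset):
        truth = [DEFAULT_LABELS[i] for i in rng.integers(0, 10, 500)]
        pred = [DEFAULT_LABELS[i] for i in rng.integers(0, 10, 500)]
        norm, counts = confusion_matrix(truth, pred, labelset)
        nz = counts > 0
        np.testing.assert_allclose(norm[nz].sum(axis=1), 1.0, atol=1e-9)
        assert (norm * counts[:, None]).sum() == pytest.approx(500)

    def test_length_mismatch_rejected(self, labelset):
        with pytest.raises(ValueError):
            confusion_matrix(["Acropora"], [], labelset)


class TestPRCurves:
    def test_perfectly_ranked_scores_reach_corner(self, labelset):
        truth = ["Acropora"] * 5 + ["unknown"] * 5
        scores = np.zeros((10, 10))
        j = labelset.index("Acropora")
        scores[:5, j] = np.linspace(2, 3, 5)
        scores[5:, j] = np.linspace(-3, -2, 5)
        curves = pr_curves(truth, scores, labelset)
        c = curves["Acropora"]
        corner = (c["precision"] == 1.0) & (c["recall"] == 1.0)
        assert corner.any()

    def test_absent_class_marked_undefined(self, labelset):
        curves = pr_curves(["Acropora"], np.zeros((1, 10)), labelset)
        assert curves["Millepora"] is None

    def test_eight_sample_case_matches_threshold_enumeration_oracle(self, labelset):
        truth = np.array([1, 0, 1, 1, 0, 0, 1, 0])
        s = np.array([0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2])
        scores = np.zeros((8, 10))
        j = labelset.index("Faviidae")
        scores[:, j] = s
        labels = ["Faviidae" if t else "unknown" for t in truth]
        curves = pr_curves(labels, scores, labelset)["Faviidae"]
        # brute-force oracle over every distinct threshold
        got = np.column_stack([curves["precision"], curves["recall"]])
        for thr in s:
            sel = s >= thr
            tp = int((truth & sel).sum())
            point = np.array([tp / sel.sum(), tp / truth.sum()])
            assert np.any(np.all(np.abs(got - point) < 1e-9, axis=1))

    def test_precision_at_full_recall_approximates_prevalence(self, rng, labelset):
        n = 5000
        prevalence = 0.3
        truth = np.where(rng.uniform(size=n) < prevalence, "Acropora", "unknown")
        scores = rng.standard_normal((n, 10))
        curves = pr_curves(list(truth), scores, labelset)["Acropora"]
        at_full = curves["precision"][curves["recall"] == 1.0]
        assert abs(at_full.min() - (truth == "Acropora").mean()) < 0.03


class TestWilcoxon:
    def test_all_zero_differences_degenerate(self):
        a = {f"i{k}": 0.5 for k in range(6)}
        res = wilcoxon_paired(a, dict(a))
        assert res.p_value == 1.0 and res.degenerate

    def test_six_sample_case_matches_enumeration(self):
        d = [1, 2, 3, 4, 5, -1]
        a = {f"i{k}": v / 10 for k, v in enumerate(d)}
        b = {f"i{k}": 0.0 for k in range(6)}
        res = wilcoxon_paired(a, b)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(
            brute_force_signed_rank_p(np.array(d)), abs=1e-12
        )

    @pytest.mark.parametrize("case", range(20))
    def test_exact_p_matches_enumeration_on_random_ties(self, case):
        rng = np.random.default_rng(1000 + case)
        n = int(rng.integers(5, 13))
        # quantized differences force ties and zeros
        d = rng.integers(-3, 4, n) / 4.0
        if np.count_nonzero(d) == 0:
            d[0] = 0.25
        a = {f"i{k}": float(v) for k, v in enumerate(d)}
        b = {f"i{k}": 0.0 for k in range(n)}
        res = wilcoxon_paired(a, b)
        assert res.p_value == pytest.approx(brute_force_signed_rank_p(d), abs=1e-9)

    def test_matches_scipy_exact_without_ties(self, rng):
        d = rng.normal(0.1, 1.0, 12)
        a = {f"i{k}": float(v) for k, v in enumerate(d)}
        b = {f"i{k}": 0.0 for k in range(12)}
        res = wilcoxon_paired(a, b)
        expected = stats.wilcoxon(d, alternative="greater", method="exact").pvalue
        assert res.p_value == pytest.approx(float(expected), abs=1e-12)

    def test_shifted_distribution_rejects_with_high_power(self):
        rng = np.random.default_rng(42)
        rejections = 0
        for _ in range(200):
            d = rng.normal(0.05, 0.05, 70)
            a = {f"i{k}": float(v) for k, v in enumerate(d)}
            b = {f"i{k}": 0.0 for k in range(70)}
            if wilcoxon_paired(a, b).p_value < 0.05:
                rejections += 1
        assert rejections / 200 > 0.9

    def test_mismatched_image_sets_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_paired({"a": 1.0}, {"b": 1.0})


class TestErrorReduction:
    def test_headline_arithmetic(self):
        absolute, relative = error_reduction(87.8, 90.5)
        assert absolute == pytest.approx(2.7)
        assert relative == pytest.approx(22.13, abs=0.01)
        assert round(relative) == 22

    def test_no_change_gives_zero(self):
        assert error_reduction(91.0, 91.0) == (0.0, 0.0)

    def test_hand_arithmetic(self):
        assert error_reduction(50.0, 75.0) == (25.0, 50.0)

    def test_undefined_relative_flagged_as_nan(self):
        absolute, relative = error_reduction(100.0, 95.0)
        assert absolute == -5.0 and np.isnan(relative)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            error_reduction(-1.0, 50.0)

    @settings(derandomize=True, max_examples=100)
    @given(
        st.floats(0, 99.999), st.floats(0, 100)
    )
    def test_sign_and_scale_invariants(self, acc_a, acc_b):
        absolute, relative = error_reduction(acc_a, acc_b)
        assert absolute == pytest.approx(acc_b - acc_a, abs=1e-9)
        # relative reduction has the same sign and is the absolute reduction
        # rescaled by A's error rate
        assert relative == pytest.approx(
            absolute / (100 - acc_a) * 100, abs=1e-6
        )


class TestReport:
    def test_report_aggregates_consistently(self, rng, labelset):
        n = 400
        images = [f"img-{i // 100}" for i in range(n)]
        truth = [DEFAULT_LABELS[i] for i in rng.integers(0, 10, n)]
        pred = [
            t if rng.uniform() < 0.8 else DEFAULT_LABELS[rng.integers(10)]
            for t in truth
        ]
        scores = rng.standard_normal((n, 10))
        rep = build_report(images, truth, pred, scores, labelset)
        assert rep.n_images == 4
        assert 0 <= rep.mean_accuracy <= 1
        assert rep.binary_mean >= rep.mean_accuracy  # merging can only help
        overall = np.mean([t == p for t, p in zip(truth, pred)])
        # images have equal point counts, so the means agree
        assert rep.mean_accuracy == pytest.approx(overall)

    def test_report_renders_to_image_files(self, rng, labelset, tmp_path):
        from reeffusion.evaluation import render_confusion_matrix, render_pr_curves

        n = 100
        truth = [DEFAULT_LABELS[i] for i in rng.integers(0, 10, n)]
        pred = [DEFAULT_LABELS[i] for i in rng.integers(0, 10, n)]
        rep = build_report(["i"] * n, truth, pred, rng.standard_normal((n, 10)), labelset)
        render_confusion_matrix(rep, tmp_path / "confusion.png", labelset)
        render_pr_curves(rep, tmp_path / "pr.png")
        assert (tmp_path / "confusion.png").stat().st_size > 0
        assert (tmp_path / "pr.png").stat().st_size > 0
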