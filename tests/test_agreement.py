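import numpy as np
import pytest

from calciscan.agreement import (
    HALF_NORMAL_MULTIPLIER,
    ConfusionMatrix,
    PairedScores,
    agreement_report,
    bland_altman_fit,
    confusion_matrix,
    false_negative_zero,
    icc,
    kendalls_w,
    paired_difference_summary,
    proportion_agreement,
    qcd,
    qcd_from_quartiles,
    shift_counts,
    weighted_kappa,
)
from calciscan.scoring import CATEGORY_LABELS


def random_matrix(seed, k=5, total=200):
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(total, rng.dirichlet(np.ones(k * k))).reshape(k, k)
    return ConfusionMatrix(counts, CATEGORY_LABELS[:k])


class TestConfusionMatrix:
    def test_identical_pairs_pad_to_full_label_set(self):
        m = confusion_matrix(["0"] * 3, ["0"] * 3, CATEGORY_LABELS)
        assert m.counts[0, 0] == 3 and m.total == 3
        assert m.counts.shape == (5, 5)

    def test_table1_round_trip(self, table1):
        ref, auto = table1.to_pairs()
        rebuilt = confusion_matrix(ref, auto, table1.labels)
        assert np.array_equal(rebuilt.counts, table1.counts)

    def test_swapped_inputs_transpose(self, table1):
        ref, auto = table1.to_pairs()
        swapped = confusion_matrix(auto, ref, table1.labels)
        assert np.array_equal(swapped.counts, table1.counts.T)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix(["0"], ["banana"], CATEGORY_LABELS)


class TestCategoricalStats:
    def test_proportion_agreement_bounds(self):
        eye = ConfusionMatrix(np.eye(5, dtype=np.int64) * 10, CATEGORY_LABELS)
        assert proportion_agreement(eye) == 1.0
        off = ConfusionMatrix(np.array([[0, 5], [3, 0]]), CATEGORY_LABELS[:2])
        assert proportion_agreement(off) == 0.0

    def test_shift_counts_conserve_total(self, table1):
        shifts = shift_counts(table1)
        assert shifts.total == table1.total
        eye = ConfusionMatrix(np.eye(5, dtype=np.int64) * 7, CATEGORY_LABELS)
        assert shift_counts(eye).counts[0] == 35
        assert shift_counts(eye).n_more_than_one == 0
        one_off = ConfusionMatrix(np.array([[0, 5], [0, 0]]), CATEGORY_LABELS[:2])
        assert shift_counts(one_off).counts[1] == 5

    def test_false_negative_zero_trivial_cases(self):
        eye = ConfusionMatrix(np.eye(5, dtype=np.int64) * 7, CATEGORY_LABELS)
        assert false_negative_zero(eye) == (0, 0.0)
        all_zero_ref = np.zeros((5, 5), dtype=np.int64)
        all_zero_ref[0, :] = 4
        assert false_negative_zero(ConfusionMatrix(all_zero_ref, CATEGORY_LABELS))[0] == 0


class TestWeightedKappa:
    def test_identity_is_one_and_chance_is_zero(self):
        eye = ConfusionMatrix(np.eye(5, dtype=np.int64) * 9, CATEGORY_LABELS)
        assert weighted_kappa(eye) == pytest.approx(1.0)
        flat = ConfusionMatrix(np.full((2, 2), 25, dtype=np.int64), CATEGORY_LABELS[:2])
        assert weighted_kappa(flat) == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_transpose_invariance_and_upper_bound(self, seed):
        m = random_matrix(seed)
        k = weighted_kappa(m)
        assert weighted_kappa(m.transpose()) == pytest.approx(k)
        assert k <= 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_linear_weights_match_sklearn(self, seed):
        from sklearn.metrics import cohen_kappa_score

        m = random_matrix(seed)
        ref, auto = m.to_pairs()
        order = {lab: i for i, lab in enumerate(m.labels)}
        want = cohen_kappa_score(
            [order[r] for r in ref], [order[a] for a in auto], weights="linear"
        )
        assert weighted_kappa(m) == pytest.approx(want, abs=1e-12)

    def test_2x2_weighted_equals_unweighted(self):
        from sklearn.metrics import cohen_kappa_score

        m = random_matrix(3, k=2)
        ref, auto = m.to_pairs()
        order = {lab: i for i, lab in enumerate(m.labels)}
        unweighted = cohen_kappa_score([order[r] for r in ref], [order[a] for a in auto])
        assert weighted_kappa(m) == pytest.approx(unweighted, abs=1e-12)

    def test_degenerate_matrix_signaled(self):
        single = np.zeros((5, 5), dtype=np.int64)
        single[2, 2] = 10
        with pytest.raises(ValueError):
            weighted_kappa(ConfusionMatrix(single, CATEGORY_LABELS))

    def test_recovers_generating_kappa_at_large_n(self, table1):
        """Sampling pairs from a known cell distribution converges to the
        analytic kappa of the generating matrix."""
        p = table1.counts / table1.total
        rng = np.random.default_rng(0)
        counts = rng.multinomial(100_000, p.ravel()).reshape(5, 5)
        sampled = ConfusionMatrix(counts, CATEGORY_LABELS)
        assert weighted_kappa(sampled) == pytest.approx(weighted_kappa(table1), abs=0.01)


class TestICC:
    def test_identical_columns_give_one(self):
        x = np.column_stack([np.arange(10.0), np.arange(10.0)])
        assert icc(x) == pytest.approx(1.0)

    def test_small_table_matches_hand_decomposition(self):
        x = np.array([[1.0, 2.0], [3.0, 5.0], [2.0, 2.0], [6.0, 7.0]])
        # explicit scalar-loop two-way ANOVA, kept independent of the
        # vectorized implementation
        n, k = x.shape
        grand = sum(x[i][j] for i in range(n) for j in range(k)) / (n * k)
        msr = k * sum((sum(row) / k - grand) ** 2 for row in x) / (n - 1)
        msc = n * sum((sum(x[i][j] for i in range(n)) / n - grand) ** 2 for j in range(k)) / (k - 1)
        sse = sum(
            (x[i][j] - sum(x[i]) / k - sum(x[a][j] for a in range(n)) / n + grand) ** 2
            for i in range(n)
            for j in range(k)
        )
        mse = sse / ((n - 1) * (k - 1))
        assert icc(x, "two-way-mixed") == pytest.approx((msr - mse) / (msr + mse), abs=1e-12)
        want_random = (msr - mse) / (msr + mse + k * (msc - mse) / n)
        assert icc(x, "two-way-random") == pytest.approx(want_random, abs=1e-12)

    def test_simulation_recovers_true_icc(self):
        """Shared subject effect with variance ratio giving ICC = 0.8."""
        rng = np.random.default_rng(7)
        n = 1000
        subject = rng.normal(0, 2.0, n)  # var 4
        noise = rng.normal(0, 1.0, (n, 2))  # var 1 -> ICC = 4/5
        x = subject[:, None] + noise
        assert icc(x, "two-way-mixed") == pytest.approx(0.8, abs=0.03)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pingouin(self, seed):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, (12, 3)) + rng.normal(0, 1, 12)[:, None]
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(12), 3),
                "rater": np.tile(np.arange(3), 12),
                "score": x.ravel(),
            }
        )
        res = pingouin.intraclass_corr(
            df, targets="subject", raters="rater", ratings="score"
        ).set_index("Type")
        assert icc(x, "two-way-mixed") == pytest.approx(res.loc["ICC(C,1)", "ICC"], abs=1e-9)
        assert icc(x, "two-way-random") == pytest.approx(res.loc["ICC(A,1)", "ICC"], abs=1e-9)

    def test_degenerate_inputs_signaled(self):
        with pytest.raises(ValueError):
            icc(np.ones((5, 2)))
        with pytest.raises(ValueError):
            icc(np.array([[1.0, 2.0]]))


class TestKendallsW:
    def test_identical_rankings_give_one(self):
        x = np.column_stack([np.arange(8.0)] * 4)
        assert kendalls_w(x) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_two_raters_relate_to_spearman(self, seed):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, (30, 2))
        rho = spearmanr(x[:, 0], x[:, 1]).statistic
        assert kendalls_w(x) == pytest.approx((rho + 1) / 2, abs=1e-12)

    def test_independent_ratings_near_chance_level(self):
        """For m independent raters E[W] = 1/m, the chance level."""
        rng = np.random.default_rng(11)
        ws = [kendalls_w(rng.uniform(0, 1, (100, 4))) for _ in range(20)]
        assert np.mean(ws) == pytest.approx(1 / 4, abs=0.03)
        assert max(ws) < 0.45

    def test_tie_correction_with_categorical_ratings(self):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 5, (40, 3)).astype(float)
        w = kendalls_w(x)
        assert 0.0 <= w <= 1.0

    def test_constant_ratings_signaled(self):
        with pytest.raises(ValueError):
            kendalls_w(np.ones((5, 3)))


class TestQCD:
    def test_printed_quartile_values(self):
        assert qcd_from_quartiles(1.0, 9.0) == pytest.approx(0.80)
        assert round(qcd_from_quartiles(1.1, 449.0), 2) == 1.00

    def test_constant_sample_is_zero(self):
        assert qcd([3.0, 3.0, 3.0, 3.0]) == 0.0

    def test_linear_interpolation_quartiles(self):
        values = [1.0, 2.0, 3.0, 4.0]
        q1, q3 = np.percentile(values, [25, 75])
        assert qcd(values) == pytest.approx((q3 - q1) / (q3 + q1))

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            qcd([1.0, 2.0])


class TestPairedDifferences:
    def test_identical_columns(self):
        p = PairedScores(np.arange(5.0), np.arange(5.0))
        s = paired_difference_summary(p)
        assert (s["median"], s["p25"], s["p75"]) == (0.0, 0.0, 0.0)

    def test_median_and_offset(self):
        ref = np.array([1.0, 2, 3, 4, 5]) + 10
        assert paired_difference_summary(PairedScores(ref, np.full(5, 10.0)))["median"] == 3.0
        ref2 = np.array([7.0, 9.0, 12.0])
        assert paired_difference_summary(PairedScores(ref2, ref2 - 5))["median"] == 5.0


class TestBlandAltman:
    def test_multiplier_closed_form(self):
        assert HALF_NORMAL_MULTIPLIER == pytest.approx(1.96 * np.sqrt(np.pi / 2), abs=1e-12)
        assert HALF_NORMAL_MULTIPLIER == pytest.approx(2.4567, abs=5e-4)

    def test_noiseless_fit_recovers_coefficients(self):
        x = np.linspace(1.0, 900.0, 60)
        absdiff = 2.0 + 3.0 * np.sqrt(x)
        model = bland_altman_fit(PairedScores(x + absdiff / 2, x - absdiff / 2))
        assert model.intercept == pytest.approx(2.0, abs=1e-9)
        assert model.slope == pytest.approx(3.0, abs=1e-9)

    def test_limit_clipped_to_zero_for_negative_prediction(self):
        from calciscan.agreement import BlandAltmanModel

        model = BlandAltmanModel(intercept=-64.482, slope=15.332)
        assert model.limit(0.0) == 0.0
        # evaluated at a mean of 400 the printed-scale model gives ~595
        assert model.limit(400.0) == pytest.approx((-64.482 + 15.332 * 20) * HALF_NORMAL_MULTIPLIER)
        assert model.limit(400.0) == pytest.approx(594.9, abs=0.5)

    def test_half_normal_coverage(self):
        """~95% of simulated non-uniform differences fall inside the limits."""
        rng = np.random.default_rng(5)
        n = 10_000
        x = rng.uniform(0.0, 1000.0, n)
        mean_abs = 2.0 + 3.0 * np.sqrt(x)
        sigma = mean_abs * np.sqrt(np.pi / 2)
        d = rng.normal(0.0, sigma)
        paired = PairedScores(x + d / 2, x - d / 2)
        model = bland_altman_fit(paired)
        assert model.coverage(paired) == pytest.approx(0.95, abs=0.01)

    def test_degenerate_inputs_signaled(self):
        with pytest.raises(ValueError):
            bland_altman_fit(PairedScores([1.0, 2.0], [1.0, 2.0]))
        with pytest.raises(ValueError):
            bland_altman_fit(PairedScores([5.0, 5.0, 5.0], [5.0, 5.0, 5.0]))


class TestAgreementReport:
    def test_perfect_agreement(self):
        eye = ConfusionMatrix(np.eye(5, dtype=np.int64) * 8, CATEGORY_LABELS)
        scores = np.linspace(0, 500, 40)
        report = agreement_report(eye, {"agatston": PairedScores(scores, scores)})
        cat = report.categorical
        assert cat["proportion_agreement"] == 1.0
        assert cat["weighted_kappa"] == pytest.approx(1.0)
        assert cat["n_shift_more_than_one"] == 0
        assert report.measures["agatston"]["icc_two_way_mixed"] == pytest.approx(1.0)

    def test_categorical_only_input(self, table1):
        report = agreement_report(table1)
        assert report.measures == {}
        assert sum(report.categorical["shift_histogram"]) == table1.total
        assert "false_negative_zero_count" in report.categorical

    def test_simulated_distortion_report_is_consistent(self):
        from calciscan.phantom import RaterNoise, simulate_rater_scores
        from calciscan.scoring import ScoreRecord
        from calciscan.agreement import confusion_matrix

        rng = np.random.default_rng(8)
        truth = [
            ScoreRecord(f"s{i}", float(s), float(s) * 1.4, int(1 + s // 200))
            for i, s in enumerate(rng.uniform(0, 900, 60))
        ]
        table = simulate_rater_scores(truth, RaterNoise(drop_prob=0.1, jitter_sd=0.2), seed=9)
        m = confusion_matrix(table.category_ref, table.category_auto, CATEGORY_LABELS)
        report = agreement_report(
            m, {"agatston": PairedScores(table.agatston_ref, table.agatston_auto)}
        )
        assert sum(report.categorical["shift_histogram"]) == 60
        block = report.measures["agatston"]
        assert np.isfinite(block["icc_two_way_mixed"])
        assert np.isfinite(block["difference"]["median"])
        report.to_json()  # serializable
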