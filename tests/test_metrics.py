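"""Metrics vs independent brute-force oracles and closed forms."""

import numpy as np
import pytest

from wisdom import (
    MetricError,
    agreement_metrics,
    c_index_ordinal,
    calibration_table,
    count_mae,
    decision_curve,
    delong_test,
    roc_auc,
)
from wisdom.metrics import sensitivity_specificity


def auc_by_pair_enumeration(scores, labels):
    """Oracle: explicit loop over all positive/negative pairs."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    credit = 0.0
    for p in pos:
        for q in neg:
            credit += 1.0 if p > q else (0.5 if p == q else 0.0)
    return credit / (len(pos) * len(neg))


def c_index_by_pair_enumeration(pred, truth):
    credit, pairs = 0.0, 0
    n = len(pred)
    for i in range(n):
        for j in range(n):
            if truth[i] > truth[j]:
                pairs += 1
                credit += (
                    1.0 if pred[i] > pred[j] else (0.5 if pred[i] == pred[j] else 0.0)
                )
    return credit / pairs


class TestRocAuc:
    def test_perfect_separation(self):
        auc, _ = roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0], n_boot=50)
        assert auc == 1.0

    def test_all_ties_is_half(self):
        auc, _ = roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0], n_boot=50)
        assert auc == 0.5

    def test_eight_point_toy_matches_enumeration(self):
        scores = [0.1, 0.4, 0.35, 0.8, 0.8, 0.7, 0.2, 0.6]
        labels = [0, 0, 1, 1, 0, 1, 0, 1]
        auc, _ = roc_auc(scores, labels, n_boot=50)
        assert auc == pytest.approx(auc_by_pair_enumeration(scores, labels))

    @pytest.mark.parametrize("seed", range(8))
    def test_random_instances_match_enumeration_exactly(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 50))
        scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        auc, _ = roc_auc(scores, labels, n_boot=50)
        assert auc == pytest.approx(auc_by_pair_enumeration(scores, labels), abs=1e-12)

    def test_score_negation_complements(self, rng):
        scores = rng.random(30)  # ties almost surely absent
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        a1, _ = roc_auc(scores, labels, n_boot=50)
        a2, _ = roc_auc(-scores, labels, n_boot=50)
        assert a1 + a2 == pytest.approx(1.0)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.random(60)
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        auc, _ = roc_auc(scores, labels, n_boot=50)
        assert auc == pytest.approx(roc_auc_score(labels, scores))

    def test_single_class_raises(self):
        with pytest.raises(MetricError):
            roc_auc([0.3, 0.4], [1, 1], n_boot=10)

    def test_bootstrap_ci_brackets_point_estimate(self, rng):
        scores = rng.random(80)
        labels = (scores + rng.normal(0, 0.4, 80) > 0.5).astype(int)
        labels[:2] = [0, 1]
        auc, (lo, hi) = roc_auc(scores, labels, n_boot=200, seed=4)
        assert lo <= auc <= hi
        assert 0.0 <= lo < hi <= 1.0


class TestDeLong:
    def test_identical_scores_degenerate(self):
        s = [0.1, 0.9, 0.4, 0.6, 0.3, 0.8]
        y = [0, 1, 0, 1, 0, 1]
        auc_a, auc_b, z, p = delong_test(s, s, y)
        assert auc_a == auc_b
        assert z == 0.0 and p == 1.0

    def test_auc_consistency_and_symmetry(self, rng):
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        a = rng.random(40) + 0.3 * y
        b = rng.random(40) + 0.1 * y
        auc_a, auc_b, z, p = delong_test(a, b, y)
        assert auc_a == pytest.approx(roc_auc(a, y, n_boot=10)[0])
        auc_b2, auc_a2, z2, p2 = delong_test(b, a, y)
        assert z2 == pytest.approx(-z)
        assert p2 == pytest.approx(p)

    def test_p_value_close_to_permutation_reference(self):
        """Mid-size toy set: asymptotic p within a few points of an exact
        score-swap permutation reference computed independently."""
        rng = np.random.default_rng(42)
        n = 30
        y = np.array([0, 1] * (n // 2))
        a = rng.random(n) + 0.45 * y
        b = rng.random(n) + 0.30 * y
        _, _, _, p = delong_test(a, b, y)

        def auc_of(s):
            from scipy.stats import rankdata

            r = rankdata(s)
            npos = int(y.sum())
            return (r[y == 1].sum() - npos * (npos + 1) / 2) / (npos * (n - npos))

        obs = abs(auc_of(a) - auc_of(b))
        hits = 0
        draws = 20000
        for _ in range(draws):
            swap = rng.random(n) < 0.5
            aa = np.where(swap, b, a)
            bb = np.where(swap, a, b)
            if abs(auc_of(aa) - auc_of(bb)) >= obs - 1e-12:
                hits += 1
        p_perm = hits / draws
        assert p == pytest.approx(p_perm, abs=0.06)


class TestCountMae:
    def test_zero_when_equal(self):
        mae, _ = count_mae([1, 2, 3], [1, 2, 3], n_boot=20)
        assert mae == 0.0

    def test_hand_arithmetic(self):
        mae, _ = count_mae([0, 2, 5], [1, 2, 3], n_boot=20)
        assert mae == pytest.approx(1.0)

    def test_shift_property(self):
        k_true = np.array([0, 1, 2, 4])
        k_hat = k_true + np.array([0, 1, 2, 0])
        m1, _ = count_mae(k_hat, k_true, n_boot=20)
        m2, _ = count_mae(k_hat + 1, k_true, n_boot=20)
        assert m2 == pytest.approx(m1 + 1.0)

    def test_length_mismatch_raises(self):
        with pytest.raises(MetricError):
            count_mae([1, 2], [1])


class TestCIndex:
    def test_perfect_and_anti_ordering(self):
        truth = ["N0", "N0", "N1", "N1", "N2"]
        assert c_index_ordinal([0, 0, 2, 2, 7], truth) == 1.0
        assert c_index_ordinal([7, 7, 2, 2, 0], truth) == 0.0

    def test_toy_with_ties_matches_enumeration(self):
        pred = [0, 1, 1, 2, 2, 2, 0, 3, 5, 5]
        truth = [0, 0, 1, 1, 1, 2, 1, 2, 2, 0]
        c = c_index_ordinal(pred, truth)
        assert c == pytest.approx(c_index_by_pair_enumeration(pred, truth))

    @pytest.mark.parametrize("seed", range(8))
    def test_random_instances_match_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(5, 50))
        pred = rng.integers(0, 6, n)
        truth = rng.integers(0, 3, n)
        if np.unique(truth).size < 2:
            truth[0] = (truth[0] + 1) % 3
        c = c_index_ordinal(pred, truth)
        assert c == pytest.approx(
            c_index_by_pair_enumeration(pred.tolist(), truth.tolist()), abs=1e-12
        )

    def test_binary_reduction_equals_auc(self, rng):
        scores = rng.random(40)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        c = c_index_ordinal(scores, y)
        auc, _ = roc_auc(scores, y, n_boot=10)
        assert c == pytest.approx(auc)

    def test_single_stage_raises(self):
        with pytest.raises(MetricError):
            c_index_ordinal([1, 2], ["N0", "N0"])


class TestAgreement:
    def test_perfect_agreement(self):
        stages = ["N0", "N1", "N2", "N1", "N0"]
        out = agreement_metrics(stages, stages)
        assert out["kappa"] == pytest.approx(1.0)
        assert out["f1_macro"] == pytest.approx(1.0)
        assert np.trace(out["confusion_matrix"]) == 5

    def test_two_class_closed_form_kappa(self):
        """Printed 2x2 table a=40, b=10, c=10, d=40 gives kappa = 0.6."""
        pred = ["N0"] * 40 + ["N1"] * 10 + ["N0"] * 10 + ["N1"] * 40
        true = ["N0"] * 50 + ["N1"] * 50
        out = agreement_metrics(pred, true)
        assert out["kappa"] == pytest.approx(0.6)

    def test_independent_labels_kappa_near_zero(self):
        rng = np.random.default_rng(0)
        n = 6000
        pred = rng.integers(0, 3, n)
        true = rng.integers(0, 3, n)
        out = agreement_metrics(pred, true)
        assert abs(out["kappa"]) < 0.03

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import cohen_kappa_score, f1_score

        pred = rng.integers(0, 3, 200)
        true = rng.integers(0, 3, 200)
        out = agreement_metrics(pred, true)
        assert out["kappa"] == pytest.approx(cohen_kappa_score(true, pred))
        assert out["f1_macro"] == pytest.approx(
            f1_score(true, pred, average="macro", zero_division=0)
        )

    def test_confusion_matrix_sums_to_n(self, rng):
        pred = rng.integers(0, 3, 57)
        true = rng.integers(0, 3, 57)
        out = agreement_metrics(pred, true)
        assert out["confusion_matrix"].sum() == 57


class TestDecisionCurve:
    def test_all_negative_classifier_zero_benefit(self):
        table = decision_curve(
            np.zeros(50), np.r_[np.ones(20), np.zeros(30)].astype(int),
            [0.1, 0.3, 0.5],
        )
        assert np.allclose(table["net_benefit_model"], 0.0)
        assert np.allclose(table["net_benefit_none"], 0.0)

    def test_treat_all_closed_form(self):
        """pi = 0.39, p_t = 0.2: net benefit treat-all = 0.39 - 0.61*0.25."""
        y = np.r_[np.ones(39), np.zeros(61)].astype(int)
        table = decision_curve(np.full(100, 0.9), y, [0.2])
        assert table["net_benefit_all"].iloc[0] == pytest.approx(0.2375)

    def test_perfect_model_reaches_prevalence_bound(self, rng):
        y = rng.integers(0, 2, 200)
        probs = y.astype(float) * 0.98 + 0.01
        table = decision_curve(probs, y, np.linspace(0.05, 0.95, 10))
        pi = y.mean()
        assert np.allclose(table["net_benefit_model"], pi)

    def test_net_benefit_never_exceeds_prevalence(self, rng):
        probs = rng.random(150)
        y = (rng.random(150) < probs).astype(int)
        table = decision_curve(probs, y, np.linspace(0.05, 0.95, 19))
        assert (table["net_benefit_model"] <= y.mean() + 1e-12).all()

    def test_degenerate_thresholds_dropped(self):
        with pytest.warns(UserWarning):
            table = decision_curve([0.5, 0.6], [0, 1], [0.0, 0.5, 1.0])
        assert len(table) == 1


class TestCalibration:
    def test_bin_counts_partition(self, rng):
        probs = rng.random(333)
        labels = rng.integers(0, 2, 333)
        table = calibration_table(probs, labels, n_bins=10)
        assert table["n"].sum() == 333
        assert len(table) == 10

    def test_extreme_bins_for_perfect_binary_probs(self):
        probs = np.array([0.0, 0.0, 1.0, 1.0, 1.0])
        labels = np.array([0, 0, 1, 1, 1])
        table = calibration_table(probs, labels, n_bins=5)
        assert table["observed_rate"].iloc[0] == 0.0
        assert table["observed_rate"].iloc[-1] == 1.0

    def test_well_calibrated_simulation(self):
        rng = np.random.default_rng(7)
        probs = rng.random(4000)
        labels = (rng.random(4000) < probs).astype(int)
        table = calibration_table(probs, labels, n_bins=10)
        for _, row in table.iterrows():
            if row["n"] < 30:
                continue
            se = np.sqrt(row["mean_predicted"] * (1 - row["mean_predicted"]) / row["n"])
            assert abs(row["observed_rate"] - row["mean_predicted"]) < 4 * se + 0.02


def test_sensitivity_specificity_hand_case():
    scores = [0.9, 0.7, 0.3, 0.2, 0.8, 0.1]
    labels = [1, 1, 1, 0, 0, 0]
    sens, spec = sensitivity_specificity(scores, labels, 0.5)
    assert sens == pytest.approx(2 / 3)
    assert spec == pytest.approx(2 / 3)
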