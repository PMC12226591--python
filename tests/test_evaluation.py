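"""Splits, metrics and statistics, each checked against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cfctacs.evaluation import (
    SplitPlan,
    compute_metrics,
    cross_validate,
    make_split,
    one_sample_vs_chance,
    paired_ttest_fdr,
    run_ablation,
)


def auc_by_pair_counting(scores, labels):
    """Exhaustive Mann-Whitney U normalisation: the probability that a
    random positive outscores a random negative (ties count half)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def bh_stepup_oracle(pvals, alpha):
    """Brute-force Benjamini-Hochberg: largest k with p_(k) <= k/m * alpha,
    rejecting every p at or below that threshold."""
    m = len(pvals)
    order = np.argsort(pvals)
    sorted_p = np.asarray(pvals)[order]
    k_star = 0
    for k in range(1, m + 1):
        if sorted_p[k - 1] <= k / m * alpha:
            k_star = k
    reject = np.zeros(m, dtype=bool)
    if k_star:
        reject[order[:k_star]] = True
    return reject


class TestMakeSplit:
    def test_4to1_ratio_arithmetic(self):
        labels = np.repeat([45, 180], 30)
        plan = make_split(labels, test_fraction=0.2, seed=0)
        assert len(plan.test_idx) == 12
        assert len(plan.train_idx) == 48

    def test_folds_partition_training_set(self):
        labels = np.repeat([0, 1], 40)
        plan = make_split(labels, seed=1)
        union = np.sort(np.concatenate([va for _, va in plan.folds]))
        np.testing.assert_array_equal(union, plan.train_idx)
        for i, (_, va_i) in enumerate(plan.folds):
            for j, (_, va_j) in enumerate(plan.folds):
                if i < j:
                    assert len(np.intersect1d(va_i, va_j)) == 0

    def test_stratification_within_one_sample(self):
        labels = np.repeat([0, 1], 35)
        plan = make_split(labels, seed=2)
        for _, va in plan.folds:
            n1 = (labels[va] == 1).sum()
            assert abs(n1 - len(va) / 2) <= 1

    def test_too_few_samples_named_error(self):
        labels = np.array([0, 0, 1, 1, 0, 1])
        with pytest.raises(ValueError, match="folds"):
            make_split(labels, n_folds=5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            make_split(np.zeros(40))


class TestComputeMetrics:
    def test_perfect_scores(self):
        y = np.array([0, 0, 1, 1])
        proba = np.array([[0.9, 0.1], [0.8, 0.2], [0.1, 0.9], [0.2, 0.8]])
        m = compute_metrics(proba, y)
        assert m["accuracy"] == 1.0 and m["auc"] == 1.0

    def test_random_scores_auc_near_half(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 4000)
        scores = rng.random(4000)
        m = compute_metrics(scores, y)
        assert abs(m["auc"] - 0.5) < 0.03

    def test_six_of_eight_accuracy_and_u_statistic(self):
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        scores = np.array([0.1, 0.2, 0.8, 0.4, 0.6, 0.7, 0.85, 0.3])
        pred_correct = ((scores >= 0.5).astype(int) == y).sum()
        assert pred_correct == 6
        m = compute_metrics(scores, y)
        assert m["accuracy"] == 0.75
        assert m["auc"] == pytest.approx(auc_by_pair_counting(scores, y))

    @given(n=st.integers(10, 200), seed=st.integers(0, 100))
    @settings(max_examples=30, deadline=None)
    def test_auc_equals_pairwise_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        y = np.concatenate([np.zeros(n // 2), np.ones(n - n // 2)]).astype(int)
        scores = rng.random(n) + 0.3 * y
        m = compute_metrics(scores, y)
        assert m["auc"] == pytest.approx(auc_by_pair_counting(scores, y), abs=1e-9)

    def test_confusion_consistent_with_accuracy(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 50)
        proba = rng.dirichlet([1, 1], size=50)
        m = compute_metrics(proba, y)
        cm = m["confusion"]
        assert cm.sum() == 50
        assert np.trace(cm) / 50 == pytest.approx(m["accuracy"])

    def test_single_class_labels_error(self):
        with pytest.raises(ValueError, match="single-class"):
            compute_metrics(np.array([0.2, 0.8]), np.array([1, 1]))


class TestCrossValidate:
    class StubModel:
        """Deterministic stand-in whose validation accuracy is dialled in."""

        def __init__(self, acc):
            self.acc = acc

        def fit(self, X, y, X_val, y_val, tc):
            self.history = {
                "best_val_acc": self.acc,
                "val_acc": [self.acc],
                "best_val_loss": 1 - self.acc,
                "val_loss": [1 - self.acc],
            }
            self._y = None
            return self.history

        def predict_proba(self, X):
            # classify by the sign of the first feature, fabricated scores
            s = (X.reshape(len(X), -1)[:, 0] > 0).astype(float)
            return np.stack([1 - 0.8 * s - 0.1, 0.8 * s + 0.1], axis=1)

    def test_best_model_selection_is_argmax(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((60, 4))
        y = np.repeat([0, 1], 30)
        rng.shuffle(y)
        plan = make_split(y, seed=3)
        accs = iter([0.4, 0.9, 0.6, 0.9, 0.2])  # tie at folds 1 and 3

        from cfctacs.models import TrainConfig

        res = cross_validate(
            lambda s: self.StubModel(next(accs)), X, y, plan,
            TrainConfig(epochs=1, seed=0),
        )
        assert res.best_fold == 1  # argmax, tie broken by fold index
        assert res.fold_val_acc == [0.4, 0.9, 0.6, 0.9, 0.2]
        assert res.split_hash == plan.hash


class TestPairedTTests:
    def test_identical_vectors_error_not_p1(self):
        acc = {"a": np.array([1.0, 2.0, 3.0]), "b": np.array([1.0, 2.0, 3.0])}
        with pytest.raises(ValueError, match="zero-variance"):
            paired_ttest_fdr(acc, [("a", "b")])

    def test_single_comparison_adjusted_equals_raw(self):
        acc = {
            "a": np.array([60.0, 62, 58, 64, 61]),
            "b": np.array([50.0, 52, 49, 55, 50]),
        }
        res = paired_ttest_fdr(acc, [("a", "b")])[0]
        assert res.p_adj == pytest.approx(res.p)
        assert res.df == 4

    def test_bh_decisions_match_printed_example(self):
        """p = {0.01, 0.02, 0.04, 0.05} at alpha 0.05: the step-up rejects
        all four (p_(4) = 0.05 <= 4/4 * 0.05)."""
        oracle = bh_stepup_oracle(np.array([0.01, 0.02, 0.04, 0.05]), 0.05)
        assert oracle.all()

    @given(
        m=st.integers(1, 12),
        seed=st.integers(0, 10_000),
        alpha=st.sampled_from([0.01, 0.05, 0.1]),
    )
    @settings(max_examples=200, deadline=None)
    def test_bh_against_bruteforce_oracle(self, m, seed, alpha):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(seed)
        pvals = rng.random(m) ** rng.uniform(0.5, 3)
        reject, *_ = multipletests(pvals, alpha=alpha, method="fdr_bh")
        np.testing.assert_array_equal(reject, bh_stepup_oracle(pvals, alpha))


class TestOneSample:
    def test_closed_form_t(self):
        vals = np.array([60.0, 62.0, 58.0, 64.0])
        res = one_sample_vs_chance(vals, 50.0)
        d = vals - 50.0
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert res.t == pytest.approx(t_hand)
        assert res.df == 3

    def test_zero_variance_error(self):
        with pytest.raises(ValueError):
            one_sample_vs_chance(np.array([50.0, 50.0, 50.0]))

    def test_n1_error(self):
        with pytest.raises(ValueError):
            one_sample_vs_chance(np.array([55.0]))


class TestAblationReport:
    def test_paired_design_hash_verified(self):
        rows = [
            {"participant": 0, "config": "a", "accuracy": 70.0, "split_hash": "x"},
            {"participant": 0, "config": "b", "accuracy": 60.0, "split_hash": "y"},
        ]
        with pytest.raises(ValueError, match="partitions"):
            run_ablation(rows)

    def test_group_summary(self):
        rows = [
            {"participant": p, "config": c, "accuracy": a, "split_hash": f"h{p}"}
            for p, c, a in [
                (0, "a", 70.0), (0, "b", 50.0), (1, "a", 80.0), (1, "b", 55.0),
            ]
        ]
        df = run_ablation(rows)
        group = df.attrs["group"].set_index("config")
        assert group.loc["a", "mean"] == 75.0
        assert group.loc["b", "mean"] == 52.5
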