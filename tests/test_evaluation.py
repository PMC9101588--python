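"""Metric implementations checked against independent brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from esdm.basemodels import ModelSpec, fit_model
from esdm.evaluation import (
    auc,
    evaluate_replicates,
    mean_deviance,
    optimal_threshold,
    permutation_importance,
    roc_curve,
    tss_at,
)
from esdm.sampling import BootstrapSplit


# ---------------------------------------------------------------------------
# brute-force oracles (deliberately naive)
# ---------------------------------------------------------------------------

def auc_by_pair_enumeration(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def confusion_by_counting(scores, labels, threshold):
    tp = sum(1 for s, l in zip(scores, labels) if l == 1 and s > threshold)
    fn = sum(1 for s, l in zip(scores, labels) if l == 1 and s <= threshold)
    tn = sum(1 for s, l in zip(scores, labels) if l == 0 and s <= threshold)
    fp = sum(1 for s, l in zip(scores, labels) if l == 0 and s > threshold)
    return tp, fp, tn, fn


def _random_instance(rng):
    n = int(rng.integers(4, 51))
    labels = np.zeros(n, dtype=int)
    labels[: int(rng.integers(1, n))] = 1
    rng.shuffle(labels)
    if labels.sum() in (0, n):
        labels[0], labels[-1] = 1, 0
    # mix of continuous scores and deliberate ties
    scores = np.round(rng.random(n), int(rng.integers(1, 4)))
    return scores, labels


class TestMetricOracles:
    def test_metrics_match_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            scores, labels = _random_instance(rng)
            assert auc(scores, labels) == pytest.approx(
                auc_by_pair_enumeration(scores, labels), abs=1e-12)
            # every ROC point matches exhaustive confusion counting
            for t, sens, fpr in roc_curve(scores, labels):
                tp, fp, tn, fn = confusion_by_counting(scores, labels, t)
                assert sens == pytest.approx(tp / (tp + fn), abs=1e-12)
                assert fpr == pytest.approx(fp / (fp + tn), abs=1e-12)
            # optimal threshold matches exhaustive search (lowest maximizer)
            candidates = roc_curve(scores, labels)[:, 0]
            objective = []
            for t in candidates:
                tp, fp, tn, fn = confusion_by_counting(scores, labels, t)
                objective.append(tp / (tp + fn) + tn / (tn + fp))
            best = max(objective)
            lowest_best = min(t for t, o in zip(candidates, objective)
                              if abs(o - best) < 1e-12)
            assert optimal_threshold(scores, labels) == pytest.approx(lowest_best, abs=1e-12)
            # deviance matches direct summation
            eps = 1e-10
            p = np.clip(scores, eps, 1 - eps)
            direct = -2 * sum(
                l * np.log(pi) + (1 - l) * np.log(1 - pi) for pi, l in zip(p, labels)
            ) / len(labels)
            assert mean_deviance(scores, labels) == pytest.approx(direct, abs=1e-12)

    def test_closed_forms(self):
        assert auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0
        assert auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5
        assert mean_deviance([0.5] * 4, [1, 0, 1, 0]) == pytest.approx(2 * np.log(2))
        assert mean_deviance([1.0, 0.0], [1, 0]) == pytest.approx(0.0, abs=1e-8)

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="AUC undefined"):
            auc([0.1, 0.2], [1, 1])


class TestTSS:
    def test_perfect_classifier_tss_one(self):
        tss, sens, spec = tss_at([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0], 0.5)
        assert (tss, sens, spec) == (1.0, 1.0, 1.0)

    def test_constant_scores_tss_zero(self):
        for t in (0.2, 0.5, 0.9):
            tss, sens, spec = tss_at([0.5] * 6, [1, 0, 1, 0, 1, 0], t)
            assert tss == pytest.approx(0.0)
            assert sens + spec == pytest.approx(1.0)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_prevalence_invariance_duplicating_negatives(self, seed):
        rng = np.random.default_rng(seed)
        scores, labels = _random_instance(rng)
        neg = labels == 0
        scores2 = np.concatenate([scores, scores[neg]])
        labels2 = np.concatenate([labels, labels[neg]])
        t = float(rng.random())
        assert tss_at(scores, labels, t)[0] == pytest.approx(
            tss_at(scores2, labels2, t)[0], abs=1e-12)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_auc_complement_for_tie_free_scores(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        scores = rng.permutation(np.linspace(0.01, 0.99, n))  # tie-free
        labels = np.zeros(n, dtype=int)
        labels[: n // 2 or 1] = 1
        rng.shuffle(labels)
        assert auc(scores, labels) + auc(-scores, labels) == pytest.approx(1.0)


class TestOptimalThreshold:
    def test_separable_returns_lowest_maximizer(self):
        # any threshold in (0.2, 0.8) attains max; lowest candidate is 0.2
        assert optimal_threshold([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == pytest.approx(0.2)

    def test_all_ties_returns_lowest_candidate(self):
        scores = [0.5] * 6
        # candidates: 1.5 (above max), 0.5, -0.5 (below min); all give sens+spec=1
        assert optimal_threshold(scores, [1, 0, 1, 0, 1, 0]) == pytest.approx(-0.5)

    def test_attained_objective_dominates_all_candidates(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            scores, labels = _random_instance(rng)
            t_star = optimal_threshold(scores, labels)
            best = sum(tss_at(scores, labels, t_star)[1:])
            for t in roc_curve(scores, labels)[:, 0]:
                assert best >= sum(tss_at(scores, labels, t)[1:]) - 1e-12


class TestEvaluateReplicates:
    def test_deterministic_family_identical_splits_sd_zero(self, easy_dataset):
        idx = np.arange(len(easy_dataset.y))
        split = BootstrapSplit(0, idx[: int(0.8 * len(idx))], idx[int(0.8 * len(idx)):])
        splits = [BootstrapSplit(i, split.train_idx, split.test_idx) for i in range(4)]
        ev = evaluate_replicates(ModelSpec("GLM"), easy_dataset, splits, seed=0)
        assert ev.metrics["auc"].std() == pytest.approx(0.0, abs=1e-12)
        # summary mean equals the arithmetic mean of per-replicate values
        assert ev.summary().loc["mean", "auc"] == pytest.approx(ev.metrics["auc"].mean())

    def test_failed_family_counts_failures(self, easy_dataset):
        from esdm.sampling import make_bootstrap_splits

        splits = make_bootstrap_splits(len(easy_dataset.y), easy_dataset.y,
                                       n_replicates=3, seed=0)
        spec = ModelSpec("BRT", min_n=10_000)  # impossible minimum => all fail
        with pytest.raises(Exception, match="all 3 replicates failed"):
            evaluate_replicates(spec, easy_dataset, splits, seed=0)


@pytest.fixture(scope="module")
def glm_with_inert_feature():
    rng = np.random.default_rng(12)
    n = 400
    X = rng.normal(size=(n, 3))
    y = (2.5 * X[:, 0] + rng.normal(scale=0.8, size=n) > 0).astype(int)
    model = fit_model(ModelSpec("GLM"), X, y, seed=0)
    from esdm.basemodels import predict_model

    return (lambda Z: predict_model(model, Z)), X, y


class TestPermutationImportance:
    def test_driver_dominates_and_inert_near_zero(self, glm_with_inert_feature):
        predict, X, y = glm_with_inert_feature
        groups = {"driver": [0], "inert_a": [1], "inert_b": [2]}
        imp = permutation_importance(predict, X, y, groups, n_permutations=10, seed=0)
        assert imp["importance_auc"].idxmax() == "driver"
        assert imp["importance_cor"].idxmax() == "driver"
        assert imp.loc["inert_a", "importance_auc"] < 1.0
        assert imp.loc["inert_b", "importance_cor"] < 1.0

    def test_constant_column_importance_exactly_zero(self, glm_with_inert_feature):
        predict, X, y = glm_with_inert_feature
        Xc = X.copy()
        Xc[:, 2] = 0.7  # permutation of a constant column is the identity
        imp = permutation_importance(predict, Xc, y, {"const": [2]},
                                     n_permutations=5, seed=1)
        assert imp.loc["const", "importance_auc"] == 0.0
        assert imp.loc["const", "importance_cor"] == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_predictions_warn_and_zero(self):
        X = np.random.default_rng(0).normal(size=(30, 2))
        y = np.array([0, 1] * 15)
        with pytest.warns(UserWarning, match="zero-variance"):
            imp = permutation_importance(lambda Z: np.full(len(Z), 0.5), X, y,
                                         {"a": [0], "b": [1]}, n_permutations=3, seed=0)
        assert (imp == 0).all().all()

    def test_spearman_flag(self, glm_with_inert_feature):
        predict, X, y = glm_with_inert_feature
        imp = permutation_importance(predict, X, y, {"driver": [0]},
                                     n_permutations=3, seed=2, method="spearman")
        assert imp.loc["driver", "importance_cor"] > 0
        with pytest.raises(ValueError):
            permutation_importance(predict, X, y, {"d": [0]}, method="kendall")
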