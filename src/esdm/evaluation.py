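"""Discrimination metrics, threshold selection, replicate evaluation and
permutation variable importance.

All metrics use the prediction rule ``score > threshold => presence``.  The
true skill statistic (TSS) is sensitivity + specificity - 1, which ranges
over [-1, 1] and is invariant to prevalence; values below 0 are possible and
are not clipped.  AUC is the Mann-Whitney form, with ties counted 1/2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr

from .basemodels import FitError, FittedModel, ModelSpec, fit_model, predict_model
from .sampling import BootstrapSplit, SpeciesDataset

__all__ = [
    "roc_curve",
    "auc",
    "tss_at",
    "optimal_threshold",
    "mean_deviance",
    "evaluate_metrics",
    "ReplicateEvaluation",
    "evaluate_replicates",
    "permutation_importance",
]

_DEVIANCE_EPS = 1e-10

METRIC_COLUMNS = ["auc", "tss", "sensitivity", "specificity", "threshold", "deviance"]


def _check_two_classes(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    pos = labels == 1
    neg = labels == 0
    if not pos.any() or not neg.any():
        raise ValueError("AUC undefined: both classes must be present")
    return pos, neg


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """ROC points as an array of (threshold, sensitivity, 1 - specificity).

    Candidate thresholds are the unique score values plus one sentinel above
    the maximum and one below the minimum, ordered so the curve runs from
    (0, 0) to (1, 1).
    """
    scores = np.asarray(scores, dtype=float)
    pos, neg = _check_two_classes(labels)
    uniq = np.unique(scores)
    thresholds = np.concatenate([[uniq[-1] + 1.0], uniq[::-1], [uniq[0] - 1.0]])
    n_pos, n_neg = pos.sum(), neg.sum()
    out = np.empty((len(thresholds), 3))
    for i, t in enumerate(thresholds):
        pred = scores > t
        out[i] = (t, (pred & pos).sum() / n_pos, (pred & neg).sum() / n_neg)
    return out


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC: P(positive score > negative score), ties count 1/2.

    Equals the trapezoidal area under :func:`roc_curve`.
    """
    scores = np.asarray(scores, dtype=float)
    pos, neg = _check_two_classes(labels)
    ranks = rankdata(scores)
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def tss_at(
    scores: np.ndarray, labels: np.ndarray, threshold: float
) -> tuple[float, float, float]:
    """(tss, sensitivity, specificity) at one threshold (rule: score > t)."""
    scores = np.asarray(scores, dtype=float)
    pos, neg = _check_two_classes(labels)
    pred = scores > threshold
    sensitivity = float((pred & pos).sum() / pos.sum())
    specificity = float((~pred & neg).sum() / neg.sum())
    return sensitivity + specificity - 1.0, sensitivity, specificity


def optimal_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Candidate threshold maximizing sensitivity + specificity.

    Candidates come from :func:`roc_curve`; ties are broken toward the LOWEST
    such threshold, which favours sensitivity (conservative for presence
    screening).
    """
    curve = roc_curve(scores, labels)
    objective = curve[:, 1] + (1.0 - curve[:, 2])  # sens + spec
    best = objective.max()
    winners = curve[np.isclose(objective, best), 0]
    return float(winners.min())


def mean_deviance(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mean binomial deviance, ``-2 * mean(y ln p + (1-y) ln(1-p))``.

    Scores are clipped to [eps, 1-eps] with eps = 1e-10 before the logs.
    """
    p = np.clip(np.asarray(scores, dtype=float), _DEVIANCE_EPS, 1 - _DEVIANCE_EPS)
    y = np.asarray(labels, dtype=float)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def evaluate_metrics(scores: np.ndarray, labels: np.ndarray) -> dict[str, float]:
    """All metrics of one score vector: AUC, optimal-threshold TSS family, deviance."""
    t = optimal_threshold(scores, labels)
    tss, sens, spec = tss_at(scores, labels, t)
    return {
        "auc": auc(scores, labels),
        "tss": tss,
        "sensitivity": sens,
        "specificity": spec,
        "threshold": t,
        "deviance": mean_deviance(scores, labels),
    }


@dataclass
class ReplicateEvaluation:
    """Per-replicate test metrics for one (species, family) pair.

    ``metrics`` has one row per successful replicate; ``test_scores`` keeps
    the raw test predictions (index-aligned with ``metrics['replicate']``) so
    the ensemble can be scored on the same held-out data.
    """

    family: str
    metrics: pd.DataFrame
    test_scores: dict[int, np.ndarray]
    n_failures: int
    failures: list[tuple[int, str]]

    def summary(self) -> pd.DataFrame:
        agg = self.metrics[METRIC_COLUMNS].agg(["mean", "std"])
        agg["n_replicates"] = [len(self.metrics)] * 2
        agg["n_failures"] = [self.n_failures] * 2
        return agg


def evaluate_replicates(
    model_spec: ModelSpec,
    dataset: SpeciesDataset,
    splits: list[BootstrapSplit],
    seed: int = 0,
) -> ReplicateEvaluation:
    """Fit one family on every replicate's training split and score its test split.

    Replicates whose fit fails are recorded and excluded from the summary;
    if every replicate fails a :class:`FitError` is raised for the pair.
    """
    rows = []
    test_scores: dict[int, np.ndarray] = {}
    failures: list[tuple[int, str]] = []
    for split in splits:
        try:
            model = fit_model(
                model_spec,
                dataset.X[split.train_idx],
                dataset.y[split.train_idx],
                seed=seed + split.replicate_id,
                feature_names=dataset.feature_names,
                continuous_mask=dataset.continuous_mask,
            )
            scores = predict_model(model, dataset.X[split.test_idx])
            metrics = evaluate_metrics(scores, dataset.y[split.test_idx])
        except FitError as err:
            failures.append((split.replicate_id, err.cause))
            continue
        test_scores[split.replicate_id] = scores
        rows.append({"replicate": split.replicate_id, **metrics})
    if not rows:
        raise FitError(
            model_spec.family,
            f"all {len(splits)} replicates failed for species {dataset.species!r}",
        )
    return ReplicateEvaluation(
        family=model_spec.family,
        metrics=pd.DataFrame(rows),
        test_scores=test_scores,
        n_failures=len(failures),
        failures=failures,
    )


def permutation_importance(
    predict_fn,
    X_eval: np.ndarray,
    labels: np.ndarray,
    feature_groups: dict[str, list[int]],
    n_permutations: int = 10,
    seed: int = 0,
    method: str = "pearson",
) -> pd.DataFrame:
    """Permutation variable importance on a 0-100 scale.

    For each covariate (a one-hot group is permuted jointly) and each of
    ``n_permutations`` shuffles:

    * ``importance_cor`` = 100 * (1 - r) between the original predictions and
      the predictions with that covariate's rows permuted (Pearson by
      default; ``method="spearman"`` for the rank version);
    * ``importance_auc`` = 100 * max(0, (AUC_orig - AUC_perm) / AUC_orig).

    Both are averaged over permutations and floored at 0.  If the original
    predictions have zero variance the importances are 0 with a warning.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    X_eval = np.asarray(X_eval, dtype=float)
    _check_two_classes(labels)
    rng = np.random.default_rng(seed)
    base_pred = np.asarray(predict_fn(X_eval), dtype=float)
    degenerate = np.std(base_pred) == 0
    if degenerate:
        warnings.warn("zero-variance predictions: importances set to 0", stacklevel=2)
    base_auc = auc(base_pred, labels)
    rows = []
    for name, cols in feature_groups.items():
        cor_drops, auc_drops = [], []
        for _ in range(n_permutations):
            perm = rng.permutation(len(X_eval))
            X_perm = X_eval.copy()
            X_perm[:, cols] = X_eval[np.ix_(perm, cols)]
            pred = np.asarray(predict_fn(X_perm), dtype=float)
            if degenerate or np.std(pred) == 0:
                cor_drops.append(0.0)
            else:
                if method == "pearson":
                    r = float(np.corrcoef(base_pred, pred)[0, 1])
                else:
                    r = float(spearmanr(base_pred, pred).statistic)
                cor_drops.append(1.0 - r)
            if degenerate or base_auc <= 0:
                auc_drops.append(0.0)
            else:
                auc_drops.append(max(0.0, (base_auc - auc(pred, labels)) / base_auc))
        rows.append({
            "covariate": name,
            "importance_cor": max(0.0, 100.0 * float(np.mean(cor_drops))),
            "importance_auc": max(0.0, 100.0 * float(np.mean(auc_drops))),
        })
    return pd.DataFrame(rows).set_index("covariate")
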