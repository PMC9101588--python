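"""Weighted-average ensemble of the nine base families, statsmodels-style.

:class:`EnsembleSDM` is the model object: it holds one species' dataset and
the evaluation protocol (replicate count, train fraction, family registry).
``fit()`` runs the whole protocol — per-replicate fits and test-set metrics
for every family, skill-proportional weights, the species-level optimal
threshold, and a final refit of each member on the full dataset — and returns
an :class:`EnsembleSDMResults` carrying the estimates, per-replicate metrics,
diagnostics and prediction/importance methods.

Weights are proportional to each family's mean maximal TSS over replicates
(``max(sens + spec) - 1``, floored at 0) so a no-skill family gets weight 0
rather than weight proportional to 1; the raw ``sens + spec`` mode is
available behind ``weight_statistic="sens_spec"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .basemodels import FitError, FittedModel, ModelSpec, fit_model, predict_model, registry_default
from .evaluation import (
    METRIC_COLUMNS,
    ReplicateEvaluation,
    evaluate_metrics,
    evaluate_replicates,
    permutation_importance,
)
from .grids import CovariateStack
from .sampling import SpeciesDataset, make_bootstrap_splits

__all__ = [
    "compute_weights",
    "species_threshold",
    "design_matrix_from_stack",
    "EnsembleSDM",
    "EnsembleSDMResults",
]


def compute_weights(skills: dict[str, float], floor_at_zero: bool = True) -> dict[str, float]:
    """Normalized skill-proportional weights.

    ``skills[f]`` is family *f*'s mean maximal TSS over replicates.  Negative
    skills are floored at 0 and zero-skill families are dropped.  Raises when
    no family has positive skill.
    """
    if len(skills) < 2:
        raise ValueError("need at least two families to ensemble")
    if not all(np.isfinite(list(skills.values()))):
        raise ValueError("non-finite skill statistic")
    clipped = {f: max(0.0, s) if floor_at_zero else s for f, s in skills.items()}
    total = sum(clipped.values())
    if total <= 0:
        raise ValueError("no skillful members: every family has skill <= 0")
    return {f: s / total for f, s in clipped.items() if s > 0}


def _weights_or_single(skills: dict[str, float]) -> dict[str, float]:
    """compute_weights, degrading to weight 1 for a deliberate single family."""
    if len(skills) == 1:
        ((family, skill),) = skills.items()
        if skill <= 0:
            raise ValueError("no skillful members: every family has skill <= 0")
        return {family: 1.0}
    return compute_weights(skills)


def species_threshold(thresholds: dict[str, float], weights: dict[str, float]) -> float:
    """Weighted average of per-family mean optimal thresholds."""
    missing = [f for f in weights if f not in thresholds]
    if missing:
        raise ValueError(f"no threshold for weighted families {missing}")
    return float(sum(weights[f] * thresholds[f] for f in weights))


def design_matrix_from_stack(
    stack: CovariateStack, feature_names: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """(design matrix over valid cells, valid mask) matching a dataset's encoding.

    Feature names are either layer names (continuous) or ``layer=code``
    one-hot indicators.  A categorical code present in the landscape but not
    in the encoding simply gets all-zero indicators.
    """
    valid = stack.valid_mask
    cols = []
    for name in feature_names:
        if "=" in name and name not in stack.layer_names:
            layer_name, code = name.rsplit("=", 1)
            vals = stack.get_layer(layer_name).values[valid]
            cols.append((vals == int(code)).astype(float))
        else:
            cols.append(stack.get_layer(name).values[valid])
    return np.column_stack(cols), valid


class EnsembleSDM:
    """Ensemble species distribution model for one species' dataset.

    Parameters
    ----------
    dataset : SpeciesDataset
        Presences, pseudo-absences and the model-ready design matrix.
    specs : list of ModelSpec, optional
        Families to combine; defaults to the full nine-family registry.
    n_replicates, train_frac : evaluation protocol (default 100 and 0.8).
    weight_statistic : "tss" (default) or "sens_spec" (raw sens+spec weights).
    refit : "full" (default) refits members on the whole dataset for map
        prediction; "replicate" keeps the first successful replicate model.
    """

    def __init__(
        self,
        dataset: SpeciesDataset,
        specs: list[ModelSpec] | None = None,
        n_replicates: int = 100,
        train_frac: float = 0.8,
        weight_statistic: str = "tss",
        with_replacement: bool = False,
        refit: str = "full",
    ) -> None:
        if weight_statistic not in ("tss", "sens_spec"):
            raise ValueError("weight_statistic must be 'tss' or 'sens_spec'")
        if refit not in ("full", "replicate"):
            raise ValueError("refit must be 'full' or 'replicate'")
        self.dataset = dataset
        self.specs = specs if specs is not None else registry_default()
        if not self.specs:
            raise ValueError("no member families configured")
        self.n_replicates = n_replicates
        self.train_frac = train_frac
        self.weight_statistic = weight_statistic
        self.with_replacement = with_replacement
        self.refit = refit

    def fit(self, seed: int = 0) -> "EnsembleSDMResults":
        ds = self.dataset
        splits = make_bootstrap_splits(
            n=len(ds.y),
            labels=ds.y,
            n_replicates=self.n_replicates,
            train_frac=self.train_frac,
            seed=seed,
            with_replacement=self.with_replacement,
        )
        evaluations: dict[str, ReplicateEvaluation] = {}
        family_failures: dict[str, str] = {}
        for k, spec in enumerate(self.specs):
            try:
                evaluations[spec.family] = evaluate_replicates(
                    spec, ds, splits, seed=seed + 1000 * (k + 1)
                )
            except FitError as err:
                family_failures[spec.family] = err.cause
        if not evaluations or (len(self.specs) >= 2 and len(evaluations) < 2):
            raise FitError(
                "ENSEMBLE",
                f"too few families evaluable for {ds.species!r}: "
                f"failures {family_failures}",
            )

        skills = {
            f: float(ev.metrics["tss"].mean())
            + (1.0 if self.weight_statistic == "sens_spec" else 0.0)
            for f, ev in evaluations.items()
        }
        weights = _weights_or_single(skills)
        mean_thresholds = {
            f: float(ev.metrics["threshold"].mean()) for f, ev in evaluations.items()
        }
        threshold = species_threshold(mean_thresholds, weights)

        # ensemble test metrics per replicate: weighted average of member test
        # scores, renormalized over the families that fitted that replicate
        ens_rows = []
        for split in splits:
            avail = [f for f in weights if split.replicate_id in evaluations[f].test_scores]
            if not avail:
                continue
            w = np.array([weights[f] for f in avail])
            w = w / w.sum()
            scores = sum(
                wi * evaluations[f].test_scores[split.replicate_id]
                for wi, f in zip(w, avail)
            )
            ens_rows.append({
                "replicate": split.replicate_id,
                **evaluate_metrics(scores, ds.y[split.test_idx]),
            })

        # final members for map prediction
        members: dict[str, FittedModel] = {}
        for k, spec in enumerate(self.specs):
            if spec.family not in weights:
                continue
            try:
                if self.refit == "full":
                    members[spec.family] = fit_model(
                        spec, ds.X, ds.y, seed=seed + 1000 * (k + 1),
                        feature_names=ds.feature_names,
                        continuous_mask=ds.continuous_mask,
                    )
                else:
                    first = min(evaluations[spec.family].test_scores)
                    split = splits[first]
                    members[spec.family] = fit_model(
                        spec, ds.X[split.train_idx], ds.y[split.train_idx],
                        seed=seed + 1000 * (k + 1) + first,
                        feature_names=ds.feature_names,
                        continuous_mask=ds.continuous_mask,
                    )
            except FitError as err:  # pragma: no cover - refit rarely fails
                family_failures[spec.family] = f"refit: {err.cause}"
        weights = _weights_or_single({f: skills[f] for f in members})

        tidy = pd.concat(
            [
                ev.metrics.assign(family=f)
                for f, ev in evaluations.items()
            ]
            + [pd.DataFrame(ens_rows).assign(family="ENSEMBLE")],
            ignore_index=True,
        )[["family", "replicate"] + METRIC_COLUMNS]

        return EnsembleSDMResults(
            model=self,
            species=ds.species,
            weights=pd.Series(weights, name="weight").sort_index(),
            species_threshold_=threshold,
            members=members,
            evaluations=evaluations,
            replicate_metrics=tidy,
            family_failures=family_failures,
            seed=seed,
        )


@dataclass
class EnsembleSDMResults:
    """Fitted ensemble: weights, threshold, replicate metrics, predictions."""

    model: EnsembleSDM
    species: str
    weights: pd.Series
    species_threshold_: float
    members: dict[str, FittedModel]
    evaluations: dict[str, ReplicateEvaluation]
    replicate_metrics: pd.DataFrame
    family_failures: dict[str, str]
    seed: int

    @property
    def species_threshold(self) -> float:
        return self.species_threshold_

    def family_summary(self) -> pd.DataFrame:
        """Mean and sd of each test metric per family (and the ensemble)."""
        g = self.replicate_metrics.groupby("family")[METRIC_COLUMNS]
        out = g.mean().add_suffix("_mean").join(g.std().add_suffix("_sd"))
        out["n_replicates"] = g.size()
        out["weight"] = self.weights.reindex(out.index)  # NaN for the ENSEMBLE row
        out["n_failures"] = [
            self.evaluations[f].n_failures if f in self.evaluations else 0
            for f in out.index
        ]
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Weighted-average probability of presence for design-matrix rows."""
        w = self.weights
        return sum(
            w[f] * predict_model(self.members[f], np.asarray(X, dtype=float))
            for f in w.index
        )

    def predict_raster(self, stack: CovariateStack) -> np.ndarray:
        """Continuous [0, 1] prediction raster; nodata (NaN) outside valid cells."""
        missing = [
            n for n in self.model.dataset.feature_groups if n not in stack.layer_names
        ]
        if missing:
            raise ValueError(f"stack is missing member feature layers: {missing}")
        X, valid = design_matrix_from_stack(stack, self.members[self.weights.index[0]].feature_names)
        out = np.full(stack.grid.shape, np.nan)
        out[valid] = self.predict(X)
        return out

    def permutation_importance(
        self, n_permutations: int = 10, seed: int | None = None, method: str = "pearson"
    ) -> pd.DataFrame:
        """Ensemble permutation importance on the full species dataset."""
        ds = self.model.dataset
        return permutation_importance(
            self.predict,
            ds.X,
            ds.y,
            ds.feature_groups,
            n_permutations=n_permutations,
            seed=self.seed if seed is None else seed,
            method=method,
        )

    def summary(self) -> str:
        """Plain-text summary table of weights, metrics and the threshold."""
        fs = self.family_summary()
        lines = [
            f"Ensemble SDM results: {self.species}",
            f"  members: {len(self.weights)}  replicates: {self.model.n_replicates}"
            f"  n: {len(self.model.dataset.y)} ({self.model.dataset.n_presences} presences)",
            f"  species optimal threshold (weighted): {self.species_threshold_:.4f}",
            "",
            fs[["weight", "auc_mean", "auc_sd", "tss_mean", "tss_sd",
                "threshold_mean", "deviance_mean", "n_failures"]]
            .round(4)
            .to_string(),
        ]
        if self.family_failures:
            lines.append("")
            lines.append(f"  family failures: {self.family_failures}")
        return "\n".join(lines)
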