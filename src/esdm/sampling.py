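"""Per-species modelling datasets: pseudo-absence generation, dataset
assembly with one-hot categorical encoding, and stratified 80/20 replicate
splits.

Presence-only records carry no absences, so each species gets randomly placed
pseudo-absences at twice the number of presence cells, drawn uniformly
without replacement from the valid, non-presence cells of the study region.
Pseudo-absences are drawn once per species and reused across replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import CovariateStack, extract_covariates

__all__ = [
    "SpeciesDataset",
    "BootstrapSplit",
    "generate_pseudo_absences",
    "make_bootstrap_splits",
    "build_species_dataset",
]


@dataclass
class BootstrapSplit:
    replicate_id: int
    train_idx: np.ndarray
    test_idx: np.ndarray


@dataclass
class SpeciesDataset:
    """One species' presences, pseudo-absences and model-ready design matrix.

    ``X`` holds continuous layers as-is and the categorical layer expanded to
    one-hot indicator columns; ``feature_groups`` maps each original covariate
    name to its column indices so grouped operations (permutation importance)
    can treat an encoded covariate as one unit.  Rows are canonically ordered
    by (row, col, label) so assembly is independent of input record order.
    """

    species: str
    presence_cells: set[tuple[int, int]]
    pseudo_absence_cells: set[tuple[int, int]]
    cells: np.ndarray  # (n, 2) row/col per dataset row
    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]
    feature_groups: dict[str, list[int]]
    continuous_mask: np.ndarray
    seed: int

    @property
    def n_presences(self) -> int:
        return len(self.presence_cells)

    def __post_init__(self) -> None:
        if self.presence_cells & self.pseudo_absence_cells:
            raise ValueError("presence and pseudo-absence cells overlap")


def generate_pseudo_absences(
    presences: set[tuple[int, int]],
    stack: CovariateStack,
    ratio: float = 2.0,
    seed: int = 0,
) -> set[tuple[int, int]]:
    """Uniform sample of ``round(ratio * n_presences)`` background cells.

    Drawn without replacement from valid cells that hold no presence of this
    species; reproducible under ``seed``.
    """
    candidates = stack.valid_cells()
    presence_set = set(map(tuple, presences))
    keep = np.array([tuple(c) not in presence_set for c in candidates])
    candidates = candidates[keep]
    n_needed = int(round(ratio * len(presences)))
    if len(candidates) < n_needed:
        raise ValueError(
            f"cannot draw {n_needed} pseudo-absences: only {len(candidates)} "
            f"valid non-presence cells available (shortfall {n_needed - len(candidates)})"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(candidates), size=n_needed, replace=False)
    return {tuple(map(int, candidates[i])) for i in chosen}


def _allocate_train_counts(class_sizes: list[int], n_train: int) -> list[int]:
    """Largest-remainder allocation of n_train across classes, keeping at
    least one train and one test member per class."""
    total = sum(class_sizes)
    raw = [n_train * s / total for s in class_sizes]
    counts = [int(np.floor(r)) for r in raw]
    remainders = [r - c for r, c in zip(raw, counts)]
    for idx in sorted(range(len(counts)), key=lambda i: -remainders[i]):
        if sum(counts) == n_train:
            break
        counts[idx] += 1
    # every class must appear in both train and test
    for i, (c, s) in enumerate(zip(counts, class_sizes)):
        if c == 0:
            counts[i] = 1
            counts[int(np.argmax(counts))] -= 1
        elif c == s:
            counts[i] = s - 1
            counts[int(np.argmin([c / s for c, s in zip(counts, class_sizes)]))] += 1
    return counts


def make_bootstrap_splits(
    n: int,
    labels: np.ndarray,
    n_replicates: int = 100,
    train_frac: float = 0.8,
    seed: int = 0,
    with_replacement: bool = False,
) -> list[BootstrapSplit]:
    """Repeated random train/test partitions, stratified by class.

    Each replicate draws a fresh random partition with
    ``|train| = round(train_frac * n)`` and the remainder in test; class
    proportions in train stay within one member of the global proportions.
    With ``with_replacement=True`` the training indices are additionally
    bootstrap-resampled (with replacement) from the training partition, for
    users who read "bootstrap" literally; the test set stays disjoint either
    way.
    """
    labels = np.asarray(labels)
    if n < 5:
        raise ValueError("need at least 5 samples to split")
    if len(labels) != n:
        raise ValueError("labels length must equal n")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if counts.min() < 2:
        raise ValueError("cannot stratify: a class has fewer than 2 members")
    n_train = int(round(train_frac * n))
    train_counts = _allocate_train_counts(list(counts), n_train)
    rng = np.random.default_rng(seed)
    splits: list[BootstrapSplit] = []
    class_indices = [np.flatnonzero(labels == c) for c in classes]
    for rep in range(n_replicates):
        train_parts, test_parts = [], []
        for idx, k in zip(class_indices, train_counts):
            perm = rng.permutation(idx)
            train_parts.append(perm[:k])
            test_parts.append(perm[k:])
        train = np.sort(np.concatenate(train_parts))
        test = np.sort(np.concatenate(test_parts))
        if with_replacement:
            train = np.sort(rng.choice(train, size=len(train), replace=True))
        splits.append(BootstrapSplit(replicate_id=rep, train_idx=train, test_idx=test))
    return splits


def build_species_dataset(
    species: str,
    presence_cells: set[tuple[int, int]],
    stack: CovariateStack,
    ratio: float = 2.0,
    seed: int = 0,
) -> SpeciesDataset:
    """Assemble a model-ready dataset for one species.

    Draws pseudo-absences, extracts covariates at all cells in canonical
    (row, col, label) order and one-hot encodes categorical layers with an
    encoding fixed by the categories present among the dataset's own cells.
    """
    pseudo = generate_pseudo_absences(presence_cells, stack, ratio=ratio, seed=seed)
    records = sorted(
        [(r, c, 1) for r, c in presence_cells] + [(r, c, 0) for r, c in pseudo]
    )
    cells = np.array([(r, c) for r, c, _ in records], dtype=int)
    y = np.array([lab for _, _, lab in records], dtype=int)
    raw = extract_covariates(cells, stack)

    columns: list[np.ndarray] = []
    names: list[str] = []
    groups: dict[str, list[int]] = {}
    cont_flags: list[bool] = []
    for j, layer in enumerate(stack.layers):
        if layer.kind == "continuous":
            groups[layer.name] = [len(names)]
            names.append(layer.name)
            columns.append(raw[:, j])
            cont_flags.append(True)
        else:
            codes = np.unique(raw[:, j]).astype(int)
            groups[layer.name] = []
            for code in codes:
                groups[layer.name].append(len(names))
                names.append(f"{layer.name}={code}")
                columns.append((raw[:, j] == code).astype(float))
                cont_flags.append(False)
    X = np.column_stack(columns) if columns else np.empty((len(y), 0))
    return SpeciesDataset(
        species=species,
        presence_cells=set(presence_cells),
        pseudo_absence_cells=pseudo,
        cells=cells,
        X=X,
        y=y,
        feature_names=names,
        feature_groups=groups,
        continuous_mask=np.array(cont_flags, dtype=bool),
        seed=seed,
    )
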