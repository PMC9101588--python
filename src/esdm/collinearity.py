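"""Pairwise-correlation screening of continuous covariate layers.

Highly collinear covariates destabilise regression-type distribution models,
so layers are screened before any species-specific work: Pearson |r| is
computed over all valid cells of the study region and layers are dropped
greedily until no remaining pair exceeds the threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .grids import CovariateStack

__all__ = ["CollinearityReport", "collinearity_filter"]


@dataclass
class CollinearityReport:
    kept: list[str]
    dropped: list[tuple[str, str, float]]  # (dropped layer, partner kept, r)
    zero_variance: list[str]


def collinearity_filter(
    stack: CovariateStack, threshold: float = 0.8
) -> CollinearityReport:
    """Greedily drop continuous layers until all pairwise |r| <= threshold.

    The drop rule is deterministic: pairs are visited in descending |r| and
    the layer appearing LATER in the stack's layer order is dropped, so users
    can protect preferred layers by putting them first.  Categorical layers
    are exempt from the screen and always kept (in place).  Zero-variance
    layers are dropped up front with a warning and reported separately.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    cont = [layer.name for layer in stack.layers if layer.kind == "continuous"]
    if len(cont) < 2:
        raise ValueError("collinearity screen needs at least two continuous layers")
    valid = stack.valid_mask
    data = {name: stack.get_layer(name).values[valid] for name in cont}

    zero_var = [name for name in cont if np.std(data[name]) == 0]
    if zero_var:
        warnings.warn(
            f"dropping zero-variance layers from the collinearity screen: {zero_var}",
            stacklevel=2,
        )
    alive = [name for name in cont if name not in zero_var]
    dropped: list[tuple[str, str, float]] = []

    order = {name: i for i, name in enumerate(stack.layer_names)}
    while True:
        worst: tuple[float, str, str] | None = None
        for i in range(len(alive)):
            for j in range(i + 1, len(alive)):
                r = float(np.corrcoef(data[alive[i]], data[alive[j]])[0, 1])
                if abs(r) > threshold:
                    if worst is None or abs(r) > abs(worst[0]):
                        worst = (r, alive[i], alive[j])
        if worst is None:
            break
        r, first, second = worst
        # drop the lower-priority (later-ordered) member of the pair
        loser, keeper = (second, first) if order[first] < order[second] else (first, second)
        alive.remove(loser)
        dropped.append((loser, keeper, r))

    kept = [
        layer.name
        for layer in stack.layers
        if layer.kind == "categorical" or layer.name in alive
    ]
    return CollinearityReport(kept=kept, dropped=dropped, zero_variance=zero_var)
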