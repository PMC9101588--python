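import numpy as np
import pytest

from esdm.grids import CovariateStack, GridSpec, Layer
from esdm.synthetic import define_virtual_species, generate_landscape, sample_occurrences
from esdm.occurrences import deduplicate_occurrences
from esdm.sampling import build_species_dataset


@pytest.fixture(scope="session")
def small_grid() -> GridSpec:
    return GridSpec(n_rows=10, n_cols=10, x_origin=-100.0, y_origin=23.0,
                    cell_size=1 / 120)


@pytest.fixture(scope="session")
def toy_stack(small_grid) -> CovariateStack:
    """10x10 stack: two deterministic continuous layers + one categorical."""
    rows, cols = np.indices(small_grid.shape).astype(float)
    layers = [
        Layer("gradient_ew", cols, "continuous"),
        Layer("gradient_ns", rows, "continuous"),
        Layer("landcover", (cols >= 5).astype(float), "categorical"),
    ]
    return CovariateStack(small_grid, layers)


@pytest.fixture(scope="session")
def landscape():
    """Default synthetic landscape (120x120, 6 continuous + landcover)."""
    return generate_landscape(seed=11)


@pytest.fixture(scope="session")
def easy_dataset(landscape):
    """Single-driver virtual species dataset (40 presences, 2x pseudo-absences)."""
    sp = define_virtual_species(landscape, ["env1"], [6.0], name="easy")
    occ = sample_occurrences(sp, 40, seed=21)
    cells = deduplicate_occurrences(occ, landscape.grid)[sp.name]
    return build_species_dataset(sp.name, cells, landscape.stack, seed=22)
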