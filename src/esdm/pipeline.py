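"""End-to-end orchestration: config, deterministic seeding, artifacts.

A :class:`PipelineConfig` names the inputs (covariate rasters, occurrence CSV,
optional region and stream GeoJSON) and the protocol parameters; the
:class:`Pipeline` runs per-species ensembles and stacks them into richness
maps, writing tidy CSV and ASCII-grid artifacts plus a parameter manifest.

Seeding is hierarchical — master seed -> per-species seed (stable hash of the
species name) -> replicate/family offsets — so runs are bit-for-bit
reproducible and independent of species execution order.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .basemodels import registry_default
from .collinearity import collinearity_filter
from .ensemble import EnsembleSDM
from .grids import CovariateStack, Layer, read_ascii_grid, region_mask_from_geojson, write_ascii_grid
from .occurrences import deduplicate_occurrences, filter_species_min_unique, load_occurrences
from .sampling import build_species_dataset
from .stacking import BinaryMap, binarize, mask_stream_buffer, stack_richness
from .terrain import derive_percent_slope

__all__ = ["PipelineConfig", "Pipeline", "species_seed"]

logger = logging.getLogger("esdm")

_CSV_FLOAT_FORMAT = "%.10g"


def species_seed(master_seed: int, species: str) -> int:
    """Stable per-species sub-seed derived by hashing the species name."""
    digest = hashlib.blake2b(
        f"{master_seed}:{species}".encode(), digest_size=4
    ).digest()
    return int.from_bytes(digest, "big") % (2**31)


@dataclass
class PipelineConfig:
    """Declarative run configuration; round-trips through YAML unchanged."""

    covariates: list[dict] = field(default_factory=list)  # {name, path, kind}
    occurrences: str = ""
    region: str | None = None
    streams: str | None = None
    output_dir: str = "esdm_output"
    min_unique: int = 10
    pa_ratio: float = 2.0
    n_replicates: int = 100
    train_frac: float = 0.8
    collinearity_threshold: float = 0.8
    buffer_km: float = 2.0
    families: list[str] | None = None
    seed: int = 0
    derive_slope_from: str | None = None
    n_permutations: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.train_frac < 1:
            raise ValueError("train_frac must lie in (0, 1)")
        if not 0 < self.collinearity_threshold <= 1:
            raise ValueError("collinearity_threshold must lie in (0, 1]")
        if self.pa_ratio <= 0 or self.buffer_km <= 0:
            raise ValueError("pa_ratio and buffer_km must be positive")
        if self.min_unique < 1 or self.n_replicates < 1:
            raise ValueError("min_unique and n_replicates must be >= 1")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


class Pipeline:
    """Loads inputs once, then runs per-species ensembles and hotspot stacking."""

    def __init__(self, config: PipelineConfig) -> None:
        self.config = config
        self.stack = self._load_stack()
        table = load_occurrences(config.occurrences)
        cells = deduplicate_occurrences(table, self.stack.grid)
        self.species_cells, self.excluded = filter_species_min_unique(
            cells, config.min_unique
        )
        logger.info(
            "loaded %d covariate layers; %d species retained, %d excluded (<%d unique cells)",
            self.stack.n_layers, len(self.species_cells), len(self.excluded),
            config.min_unique,
        )
        self.out = Path(config.output_dir)
        self.out.mkdir(parents=True, exist_ok=True)

    def _load_stack(self) -> CovariateStack:
        cfg = self.config
        layers: list[Layer] = []
        grid = None
        for entry in cfg.covariates:
            values, g = read_ascii_grid(entry["path"])
            if grid is None:
                grid = g
            elif not grid.matches(g):
                raise ValueError(f"layer {entry['name']!r} is on a different grid")
            layers.append(Layer(name=entry["name"], values=values,
                                kind=entry.get("kind", "continuous")))
        if grid is None:
            raise ValueError("no covariate layers configured")
        region_mask = (
            region_mask_from_geojson(cfg.region, grid) if cfg.region else None
        )
        stack = CovariateStack(grid, layers, region_mask)
        if cfg.derive_slope_from:
            slope = derive_percent_slope(stack.get_layer(cfg.derive_slope_from), grid)
            stack = CovariateStack(grid, stack.layers + [slope], stack.region_mask)
        report = collinearity_filter(stack, cfg.collinearity_threshold)
        if report.dropped or report.zero_variance:
            logger.info("collinearity screen dropped %s (zero-variance: %s)",
                        [d[0] for d in report.dropped], report.zero_variance)
        return stack.subset(report.kept)

    # -- per-species -------------------------------------------------------

    def run_species(self, species: str) -> dict:
        """Fit one species' ensemble and write its artifacts.

        A species that failed the minimum-unique filter yields a structured
        skip record rather than an error.
        """
        cfg = self.config
        if species not in self.species_cells:
            count = dict(self.excluded).get(species)
            record = {"species": species, "skipped": True,
                      "reason": f"fewer than {cfg.min_unique} unique cells"
                                + (f" ({count})" if count is not None else "")}
            logger.warning("skipping %s: %s", species, record["reason"])
            return record
        seed = species_seed(cfg.seed, species)
        dataset = build_species_dataset(
            species, self.species_cells[species], self.stack,
            ratio=cfg.pa_ratio, seed=seed,
        )
        model = EnsembleSDM(
            dataset,
            specs=registry_default(cfg.families),
            n_replicates=cfg.n_replicates,
            train_frac=cfg.train_frac,
        )
        results = model.fit(seed=seed + 1)
        importance = results.permutation_importance(
            n_permutations=cfg.n_permutations, seed=seed + 2
        )
        prediction = results.predict_raster(self.stack)
        binary = binarize(prediction, results.species_threshold,
                          self.stack.grid, species=species)

        tag = species.replace(" ", "_")
        metrics = results.replicate_metrics.assign(species=species)
        metrics = metrics[["species"] + [c for c in metrics.columns if c != "species"]]
        metrics.to_csv(self.out / f"{tag}_metrics.csv", index=False,
                       float_format=_CSV_FLOAT_FORMAT)
        importance.to_csv(self.out / f"{tag}_importance.csv",
                          float_format=_CSV_FLOAT_FORMAT)
        weights = results.weights.rename_axis("family").reset_index()
        weights["species_threshold"] = results.species_threshold
        weights.to_csv(self.out / f"{tag}_weights.csv", index=False,
                       float_format=_CSV_FLOAT_FORMAT)
        write_ascii_grid(self.out / f"{tag}_prediction.asc", prediction, self.stack.grid)
        write_ascii_grid(self.out / f"{tag}_binary.asc", binary.values, self.stack.grid)
        manifest = {
            "species": species, "seed": seed,
            "n_presences": dataset.n_presences,
            "n_pseudo_absences": len(dataset.pseudo_absence_cells),
            "species_threshold": results.species_threshold,
            "families": list(results.weights.index),
            "family_failures": results.family_failures,
            "parameters": asdict(cfg),
        }
        with open(self.out / f"{tag}_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        logger.info("finished %s: threshold %.4f, members %s", species,
                    results.species_threshold, list(results.weights.index))
        return {"species": species, "skipped": False, "results": results,
                "binary": binary, "importance": importance}

    # -- stacking ----------------------------------------------------------

    def run_hotspots(self, binary_maps: list[BinaryMap] | None = None) -> dict:
        """Stack per-species binary maps into richness maps (+ stream buffer)."""
        cfg = self.config
        if binary_maps is None:
            binary_maps = []
            for species in sorted(self.species_cells):
                path = self.out / f"{species.replace(' ', '_')}_binary.asc"
                if not path.exists():
                    continue
                values, grid = read_ascii_grid(path)
                binary_maps.append(BinaryMap(grid=grid, values=values, species=species))
        if not binary_maps:
            raise ValueError("no species binary maps available to stack")
        richness = stack_richness(binary_maps)
        write_ascii_grid(self.out / "richness.asc", richness.values, richness.grid,
                         fmt="%.10g")
        out = {"richness": richness}
        if cfg.streams:
            buffered = mask_stream_buffer(richness, cfg.streams, cfg.buffer_km)
            write_ascii_grid(self.out / "richness_buffered.asc", buffered.values,
                             buffered.grid, fmt="%.10g")
            out["richness_buffered"] = buffered
        return out

    def run_all(self) -> dict:
        """All retained species in deterministic (sorted) order, then hotspots."""
        species_outputs = {}
        binary_maps = []
        for species in sorted(self.species_cells):
            record = self.run_species(species)
            species_outputs[species] = record
            if not record.get("skipped"):
                binary_maps.append(record["binary"])
        hotspots = self.run_hotspots(binary_maps)
        return {"species": species_outputs, **hotspots}
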