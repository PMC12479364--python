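"""Configuration objects for simulation and pipeline runs.

``SimulationConfig`` freezes the study design the generators emulate: five
infection models (LCMV, influenza, T. muris, H. polygyrus, C. rodentium) by
four sorted CD4+ populations (IL-21+ T_FH, IL-21- T_FH, T_FR, T_eff) with a
few biological replicates each, plus a tonsil-like single-cell layer and a
spatial layer with germinal-center-like regions.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Any, Mapping

import yaml

DEFAULT_CONDITIONS = ("lcmv", "influenza", "t_muris", "h_polygyrus", "c_rodentium")
DEFAULT_CELLTYPES = ("tfh_il21pos", "tfh_il21neg", "tfr", "teff")


class ConfigError(ValueError):
    """A configuration field violates its invariant."""


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic bulk / single-cell / spatial experiments.

    Counts follow a negative binomial with variance mu + dispersion * mu^2.
    Planted genes shift the mean by ``effect_lfc`` log2 units in the cell
    populations their category prescribes.
    """

    n_genes: int = 5000
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    celltypes: tuple[str, ...] = DEFAULT_CELLTYPES
    replicates_per_group: int = 3
    library_size_mean: float = 2e7
    library_size_cv: float = 0.3
    dispersion: float = 0.1
    n_core_up: int = 200
    n_core_down: int = 200
    n_tfr_shared: int = 100
    n_specific_per_condition: int = 100
    effect_lfc: float = 1.5
    # single-cell layer
    mito_gene_fraction: float = 0.02
    n_cells_per_cluster: int = 200
    n_clusters: int = 3
    n_donors: int = 3
    cell_library_mean: float = 5000.0
    high_mito_cell_fraction: float = 0.05
    # spatial layer
    grid_size: int = 50
    n_regions: int = 4
    region_radius: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        for field in (
            "n_genes",
            "replicates_per_group",
            "n_core_up",
            "n_core_down",
            "n_tfr_shared",
            "n_specific_per_condition",
            "n_cells_per_cluster",
            "n_clusters",
            "n_donors",
            "grid_size",
            "n_regions",
        ):
            v = getattr(self, field)
            if not isinstance(v, int) or v < 0:
                raise ConfigError(f"{field} must be a non-negative integer, got {v!r}")
        if self.dispersion < 0:
            raise ConfigError(f"dispersion must be >= 0, got {self.dispersion}")
        if not math.isfinite(self.effect_lfc):
            raise ConfigError("effect_lfc must be finite")
        if self.library_size_mean <= 0 or self.cell_library_mean <= 0:
            raise ConfigError("library size means must be positive")
        if not 0 <= self.mito_gene_fraction <= 1:
            raise ConfigError("mito_gene_fraction must lie in [0, 1]")
        if not 0 <= self.high_mito_cell_fraction <= 1:
            raise ConfigError("high_mito_cell_fraction must lie in [0, 1]")
        n_planted = (
            self.n_core_up
            + self.n_core_down
            + self.n_tfr_shared
            + self.n_specific_per_condition * len(self.conditions)
        )
        if n_planted > self.n_genes:
            raise ConfigError(
                f"planted gene counts sum to {n_planted} > n_genes = {self.n_genes}"
            )
        if self.region_radius < 0:
            raise ConfigError("region_radius must be >= 0")
        if self.n_regions > 0 and self.region_radius > self.grid_size / 2:
            raise ConfigError(
                f"region_radius {self.region_radius} exceeds half the grid size "
                f"({self.grid_size / 2})"
            )

    def replace(self, **kwargs: Any) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


# ---------------------------------------------------------------------------
# pipeline configuration (YAML-backed)

_PIPELINE_DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "out_dir": "results",
    # bulk DE engine
    "fc_threshold": 1.1,
    "fdr": 0.05,
    "min_library_size": 1_000_000,
    "filter_min_count": 10,
    "filter_min_total": 15,
    # signature rules
    "min_conditions": 3,
    "pool_il21_subsets": True,
    # single cell
    "mito_max": 0.20,
    "count_quantile": 0.10,
    "n_hvgs": 2000,
    "n_pcs": 30,
    "knn_k": 9,
    "louvain_resolution": 1.0,
    "min_cells": 10,
    # scoring / projection
    "score_mode": "up_only",
    "min_gene_coverage": 0.25,
    # simulation overrides (merged into SimulationConfig)
    "simulation": {},
}


@dataclasses.dataclass
class PipelineConfig:
    """Validated pipeline settings; unknown keys are rejected."""

    params: dict[str, Any]

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any] | None) -> "PipelineConfig":
        mapping = dict(mapping or {})
        unknown = set(mapping) - set(_PIPELINE_DEFAULTS)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        params = dict(_PIPELINE_DEFAULTS)
        params.update(mapping)
        sim_unknown = set(params["simulation"]) - {
            f.name for f in dataclasses.fields(SimulationConfig)
        }
        if sim_unknown:
            raise ConfigError(f"unknown simulation keys: {sorted(sim_unknown)}")
        return cls(params)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        return cls.from_mapping(yaml.safe_load(text) or {})

    def __getitem__(self, key: str) -> Any:
        return self.params[key]

    def simulation_config(self, seed: int | None = None) -> SimulationConfig:
        sim = dict(self.params["simulation"])
        if "conditions" in sim:
            sim["conditions"] = tuple(sim["conditions"])
        if "celltypes" in sim:
            sim["celltypes"] = tuple(sim["celltypes"])
        sim.setdefault("seed", self.params["seed"])
        if seed is not None:
            sim["seed"] = seed
        return SimulationConfig(**sim)
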