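"""Pipeline configuration.

All tunable thresholds of the workflow live in one dataclass so that a run is
fully described by (inputs, config, seed).  Defaults follow the published
parameterization of the method: strict QC boundaries (cells with fewer than
200 detected genes or more than 5% mitochondrial counts are dropped), sample
inclusion (at least 100 malignant cells and 60 T cells), cluster/cell-line
similarity threshold alpha = 0.4, response-divergence threshold epsilon = 1,
side-effect penalty lambda = 0.1, and a maximum combination size of 2.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Raised when a configuration value is outside its documented range."""


@dataclass
class Config:
    # quality control
    qc_min_genes: int = 200
    qc_max_mito_frac: float = 0.05
    mito_prefix: str = "MT-"
    # sample inclusion
    min_malignant_cells: int = 100
    min_t_cells: int = 60
    # clustering objective
    alpha_sim: float = 0.4
    eps_divergence: float = 1.0
    # combination optimizer
    lambda_side_effect: float = 0.1
    max_combo_size: int = 2
    respond_threshold: float = 0.5
    seed: int = 0
    # similarity kernel / refinement
    n_similarity_features: int = 300
    refine_top_k: int = 5
    # trajectories
    min_trajectory_cells: int = 10
    # graph clustering internals
    n_resolutions: int = 25
    knn_neighbors: int = 20
    n_pcs: int = 50

    def __post_init__(self) -> None:
        if self.qc_min_genes < 0:
            raise ConfigError("qc_min_genes must be non-negative")
        if not 0.0 <= self.qc_max_mito_frac <= 1.0:
            raise ConfigError("qc_max_mito_frac must lie in [0, 1]")
        if self.min_malignant_cells < 0 or self.min_t_cells < 0:
            raise ConfigError("inclusion thresholds must be non-negative")
        if not -1.0 <= self.alpha_sim <= 1.0:
            raise ConfigError("alpha_sim must lie in [-1, 1]")
        if self.lambda_side_effect < 0:
            raise ConfigError("lambda_side_effect must be non-negative")
        if self.max_combo_size < 1:
            raise ConfigError("max_combo_size must be at least 1")
        if not 0.0 < self.respond_threshold < 1.0:
            raise ConfigError("respond_threshold must lie in (0, 1)")
        for name in ("n_similarity_features", "refine_top_k",
                     "min_trajectory_cells", "n_resolutions",
                     "knn_neighbors", "n_pcs"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be at least 1")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
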