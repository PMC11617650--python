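"""Run configuration: every tunable of the pipeline with its default."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class RunConfig:
    """Tunables for the full pipeline.

    Defaults follow the study design this package implements: 10 000 trees
    aggregated into K = 7 engineered enviromic markers, 1000 ensemble runs of
    the reaction-norm model, a 5 km bin grid with a 50 km buffer, and four
    breeding zones. ``demo_*`` scale knobs live in the simulation section of
    the config file, not here.
    """

    seed: int = 1
    # grid
    cell_size_km: float = 5.0
    buffer_km: float = 50.0
    # marker engineering
    n_trees: int = 10_000
    n_markers: int = 7  # K
    genotype_subsample_fraction: float = 0.5
    min_samples_leaf: int = 2
    loo_n_trees: int = 200
    # reaction-norm ensemble
    n_runs: int = 1000
    ensemble_run_mode: str = "per_cluster"  # or "single_marker" (K=1 per run)
    sigma_structure: str = "unstructured"  # or "diagonal"
    max_reml_iter: int = 200
    reml_tol: float = 1e-8
    # recommendation
    alpha: float = 0.05
    representativeness: str = "min"  # min | knearest
    k_nearest: int = 3
    # zones
    n_zones: int = 4
    zone_subsample_bins: int = 2000
    # validation
    variogram_model: str = "spherical"
    variogram_n_lags: int = 15
    cv_refit_bank: bool = True
    cv_n_trees: int = 200
    cv_n_runs: int = 10
    # io
    paths: dict = field(default_factory=dict)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def replace(self, **kw) -> "RunConfig":
        d = asdict(self)
        d.update(kw)
        return RunConfig(**d)
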