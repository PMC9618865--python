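"""Pipeline configuration with YAML round-tripping.

Defaults follow the target study where it states a value (window 22
TRs, Gaussian sigma 3 TRs, step 1 TR, a k-range containing 4, edge
alpha 0.01, metric alpha 0.05) and the package's documented design
choices elsewhere.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Invalid or unknown configuration key/value."""


@dataclass
class PipelineConfig:
    seed: int = 0
    # cohort
    n_per_group: int = 19
    n_timepoints: int = 230
    tr: float = 2.0
    separation: str = "default"
    coupling_r2: float = 0.25
    # conditioning
    detrend: bool = True
    band: tuple[float, float] | None = None
    # windows
    window_length: int = 22
    window_sigma: float = 3.0
    window_step: int = 1
    fisher: bool = True
    # states
    k: int = 4
    k_range: tuple[int, int] = (2, 8)
    run_select_k: bool = False
    distance: str = "cityblock"
    n_init: int = 20
    exemplar_subsampling: bool = False
    # inference
    alpha_edges: float = 0.01
    alpha_metrics: float = 0.05
    nuisance: tuple[str, ...] = ("age", "education")
    clinical_covariates: tuple[str, ...] = (
        "age", "education", "FEV1", "FVC", "FEV1_FVC", "PaO2", "PaCO2",
        "SaO2", "pH", "CRP", "MMSE", "MoCA",
    )
    absent_state: str = "zero"

    def __post_init__(self) -> None:
        if self.band is not None:
            self.band = tuple(self.band)  # type: ignore[assignment]
        self.k_range = tuple(self.k_range)  # type: ignore[assignment]
        self.nuisance = tuple(self.nuisance)
        self.clinical_covariates = tuple(self.clinical_covariates)
        if self.k < 1:
            raise ConfigError("k must be >= 1")
        if self.alpha_edges <= 0 or self.alpha_edges >= 1:
            raise ConfigError("alpha_edges must lie in (0, 1)")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(d) - known)
        if unknown:
            raise ConfigError(f"unknown configuration keys: {unknown}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ConfigError("configuration file must hold a mapping")
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("band", "k_range", "nuisance", "clinical_covariates"):
            if d[key] is not None:
                d[key] = list(d[key])
        return d

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
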