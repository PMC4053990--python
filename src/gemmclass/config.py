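"""Pipeline configuration: every threshold of the analysis in one place.

Defaults are the published operating points of the original study design:
probes kept when both channel intensities exceed 10 and data are present on
>70% of arrays, 10-nearest-neighbor imputation, sample groups at Pearson
r >= 0.65, intrinsic cutoff one SD below the mean score, classes requiring
>= 5 tumors at SigClust P <= 0.01, 80% homogeneity shares, SAM selection at
FDR 0%, and GSA overlap at P <= 0.05 / FDR <= 0.1 replicated in >= 2 of 3
human cohorts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    intensity_min: float = 10.0
    presence_min: float = 0.70
    knn_k: int = 10
    unsup_min_obs: int = 3
    unsup_abs_log2: float = 3.0
    group_r_min: float = 0.65
    intrinsic_sd_cutoff: float = 1.0
    class_min_size: int = 5
    sigclust_alpha: float = 0.01
    sigclust_nsim: int = 1000
    homogeneity_share: float = 0.80
    sam_nperm: int = 1000
    sam_fdr_select: float = 0.0
    gsa_nperm: int = 1000
    gsa_alpha: float = 0.05
    gsa_fdr: float = 0.10
    counterpart_min_datasets: int = 2
    pca_platform_r2_max: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        fractions = ("presence_min", "sigclust_alpha", "homogeneity_share",
                     "sam_fdr_select", "gsa_alpha", "gsa_fdr",
                     "pca_platform_r2_max")
        for name in fractions:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} must lie in [0, 1]")
        counts = ("knn_k", "unsup_min_obs", "class_min_size", "sigclust_nsim",
                  "sam_nperm", "gsa_nperm", "counterpart_min_datasets")
        for name in counts:
            v = getattr(self, name)
            if int(v) != v or v <= 0:
                raise ConfigError(f"{name}={v} must be a positive integer")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if data is None:
            return cls()
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} is not a mapping")
        return cls.from_dict(data)
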