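"""Pipeline configuration and seed management.

A single :class:`PipelineConfig` carries every tunable of the analysis, from
slot rules to the stability-resampling budget.  The defaults reproduce the
published analysis settings: six 2-hour slots over 7 days, a one-third
compliance threshold, Sakoe-Chiba windows {2, 4, 8, 16} with the symmetricP0
step pattern, cluster numbers 2..10, 1000 subsamples of 50 % and a 0.85
Jaccard stability threshold.

A single master seed fans out to per-stage seeds through a fixed
``SeedSequence`` derivation so every stage is independently reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

#: The five psychotic-symptom items carried through the analysis.
ITEMS: tuple[str, ...] = ("voices", "see_things", "dislike", "suspicious", "harm")

N_DAYS = 7
SLOTS_PER_DAY = 6
N_SLOTS = N_DAYS * SLOTS_PER_DAY  # 42

#: Stage names, in pipeline order, used for seed derivation.
STAGES: tuple[str, ...] = (
    "simulate",
    "preprocess",
    "impute",
    "dtw",
    "cluster",
    "stability",
    "stats",
)


def derive_seed(master_seed: int, stage: str) -> int:
    """Derive a stable per-stage seed (< 2**31) from the master seed."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence(master_seed, spawn_key=(STAGES.index(stage),))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """All settings of the trajectory-clustering pipeline."""

    # input: either a CSV path or "synthetic"
    input_csv: str | None = None

    # compliance filtering
    min_response_rate: float = 1.0 / 3.0

    # imputation (missForest-style defaults)
    n_trees: int = 100
    max_impute_iter: int = 10

    # DTW
    windows: tuple[int, ...] = (2, 4, 8, 16)
    primary_window: int = 2
    normalize_dtw: bool = False

    # clustering
    k_range: tuple[int, ...] = tuple(range(2, 11))
    kmeans_n_init: int = 50
    kmeans_variant: str = "rows"  # "rows" (distance-profile k-means) or "pam"

    # stability
    n_resamples: int = 1000
    subsample_fraction: float = 0.5
    stability_threshold: float = 0.85
    stability_aggregate: str = "min"  # "min" or "mean"
    stability_n_init: int = 10  # k-means restarts inside the resampling loop

    # statistics
    fdr_level: float = 0.05

    # randomness
    seed: int = 0

    def seed_for(self, stage: str) -> int:
        return derive_seed(self.seed, stage)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = dict(raw)
        for key in ("windows", "k_range"):
            if key in cfg and cfg[key] is not None:
                cfg[key] = tuple(int(v) for v in cfg[key])
        return cls(**cfg)

    def to_yaml(self, path: str) -> None:
        data = self.to_dict()
        data["windows"] = list(self.windows)
        data["k_range"] = list(self.k_range)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_response_rate <= 1.0):
            raise ValueError("min_response_rate must lie in [0, 1]")
        if any(w < 1 for w in self.windows):
            raise ValueError("DTW windows must be >= 1")
        if any(k < 1 for k in self.k_range):
            raise ValueError("cluster numbers must be >= 1")
        if not (0.0 < self.subsample_fraction <= 1.0):
            raise ValueError("subsample_fraction must lie in (0, 1]")
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")
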