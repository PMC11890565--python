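"""Pipeline configuration: a flat, validated, diff-able YAML mapping."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All knobs of an end-to-end run.

    Threshold defaults: sparse filter 0.05 (inclusive), copy-number gain
    +0.3 / loss -0.3 (strict), TP53 recurrence minimum 10 patients,
    association-test eligibility 5 mutated samples.
    """

    seed: int = 0
    out_dir: str = "pipeline_out"
    data_dir: str | None = None  # cohort file directory (written in simulate mode)
    simulate: bool = True
    cohort: dict = field(default_factory=dict)  # CohortConfig overrides
    training_dataset: str = "train"
    sparse_threshold: float = 0.05
    gain_threshold: float = 0.3
    loss_threshold: float = -0.3
    recurrence_min: int = 10
    eligibility_min: int = 5
    alphas: list = field(default_factory=lambda: list(np.round(np.arange(0.1, 1.0, 0.1), 10)))
    lambdas: list = field(default_factory=lambda: list(np.logspace(2, -2, 20)))
    n_bootstrap: int = 100
    normalize_oob: bool = False
    fdr_family_mode: str = "separate"  # 'separate' or 'joint' across subtype comparisons
    risk_group_mode: str = "tertile"  # 'tertile' or 'median'
    model_combos: list | None = None  # None -> all seven combinations

    def __post_init__(self):
        if not (0.0 < self.sparse_threshold < 1.0):
            raise ValueError("sparse_threshold must lie in (0, 1)")
        if self.gain_threshold <= 0 or self.loss_threshold >= 0:
            raise ValueError("gain_threshold must be positive, loss_threshold negative")
        if self.recurrence_min < 1 or self.eligibility_min < 1:
            raise ValueError("recurrence_min and eligibility_min must be >= 1")
        if self.fdr_family_mode not in ("separate", "joint"):
            raise ValueError("fdr_family_mode must be 'separate' or 'joint'")
        if self.risk_group_mode not in ("tertile", "median"):
            raise ValueError("risk_group_mode must be 'tertile' or 'median'")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if self.model_combos is not None and len(self.model_combos) == 0:
            raise ValueError("model_combos is empty: no feature-type combination to train")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
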