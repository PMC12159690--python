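"""Study configuration: one object mirroring every CLI flag.

Defaults reproduce the canonical analysis settings: extreme-deviation
threshold tau = 4.13, stratified 5-fold cross-validation, 1000 label
permutations, SMOTE with k = 5 neighbors, top-decile region selection.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["StudyConfig"]


@dataclass
class StudyConfig:
    # metric settings
    tau: float = 4.13
    signed_red: bool = False
    top_fraction: float = 0.10
    # deviation settings
    dof_adjust: bool = False
    # classification settings
    feature_kind: str = "edges"
    thresholded_features: bool = False
    n_folds: int = 5
    svm_c: float = 1.0
    smote: bool = False
    smote_k: int = 5
    single_split: bool = False
    n_permutations: int = 1000
    # stability settings
    stability_min: int = 8
    stability_max: int = 64
    stability_step: int = 4
    stability_reps: int = 20
    # randomness
    seed: int = 0
    # paths
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.feature_kind not in ("edges", "red"):
            raise ValueError("feature_kind must be 'edges' or 'red'")
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must be in (0, 1]")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")

    def stability_sizes(self) -> list[int]:
        return list(range(self.stability_min, self.stability_max + 1, self.stability_step))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
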