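"""Run configuration: one flat record of every tunable, YAML round-trip.

Defaults: Gaussian σ = 0.7, seed window α = 150 px, tracking window
β = 75 px, validation margin γ = 15 px, and a 5 px separator margin.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from pathlib import Path

import yaml

from .preprocess import CropBox, PreprocessParams
from .reconstruct_eval import SSIMConstants
from .trace import TrackingParams

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    # preprocessing
    sigma: float = 0.7
    apply_crop: bool = True
    crop: tuple[int, int, int, int] = (280, 1520, 150, 2150)  # row_a, row_b, col_a, col_b
    # layout
    margin: int = 5
    sep_min_sep: int | None = None  # None -> width // 8
    baseline_min_sep: int | None = None  # None -> height // 8
    # tracking
    alpha: int = 150
    beta: int = 75
    gamma: int = 15
    # evaluation
    K1: float = 0.01
    K2: float = 0.03
    L: float = 1.0
    thickness: int = 1
    # logging
    log_level: str = "INFO"

    def preprocess_params(self) -> PreprocessParams:
        return PreprocessParams(crop=CropBox(*self.crop), sigma=self.sigma, apply_crop=self.apply_crop)

    def tracking_params(self) -> TrackingParams:
        return TrackingParams(alpha=self.alpha, beta=self.beta, gamma=self.gamma)

    def ssim_constants(self) -> SSIMConstants:
        return SSIMConstants(K1=self.K1, K2=self.K2, L=self.L)

    def to_yaml(self) -> str:
        d = asdict(self)
        d["crop"] = list(d["crop"])
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "crop" in data:
            data = dict(data, crop=tuple(data["crop"]))
        return cls(**data)

    def override(self, **kwargs) -> "RunConfig":
        """New config with non-None keyword overrides applied."""
        updates = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **updates)
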