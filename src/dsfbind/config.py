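"""Pipeline configuration: one flat-key structure, defaults = study constants."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .constants import (
    DEFAULT_DH0_KCAL,
    DEFAULT_DRFU_MAX,
    DEFAULT_T0_SINGLE_K,
    DELTA_TM_ACCEPTABLE_MIN_K,
    DELTA_TM_FLOOR_K,
    DELTA_TM_MAX_K,
    DELTA_TM_PREFERRED_MIN_K,
)

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the analysis, with units in the field names.

    ``t0_source`` is either ``"buffer_wells"`` (T0 = mean adopted Tm of the
    plate's buffer-only wells) or ``"fixed"`` (use ``t0_fixed_k``).
    """

    smooth_window_c: float = 1.0
    prominence_frac: float = 0.10
    min_separation_c: float = 2.0
    noise_floor_mads: float = 6.0
    peak_floor_mads: float = 8.0
    t0_source: str = "buffer_wells"
    t0_fixed_k: float = DEFAULT_T0_SINGLE_K
    dh0_kcal: float = DEFAULT_DH0_KCAL
    drfu_max: float = DEFAULT_DRFU_MAX
    floor_k: float = DELTA_TM_FLOOR_K
    acceptable_min_k: float = DELTA_TM_ACCEPTABLE_MIN_K
    preferred_min_k: float = DELTA_TM_PREFERRED_MIN_K
    window_max_k: float = DELTA_TM_MAX_K
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.floor_k < self.acceptable_min_k < self.preferred_min_k < self.window_max_k):
            raise ValueError("window thresholds must be ordered floor < acceptable < preferred < max")
        for name in ("smooth_window_c", "prominence_frac", "min_separation_c",
                     "t0_fixed_k", "dh0_kcal", "drfu_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.t0_source not in ("buffer_wells", "fixed"):
            raise ValueError("t0_source must be 'buffer_wells' or 'fixed'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **kwargs)
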