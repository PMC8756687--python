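"""Engine run configuration.

Defaults follow the full-scale calibration regime (5,000 prior draws,
five new mixture components per iteration, 100 proposals per
component, ESS target 5,000); toy problems override them.  The config
round-trips losslessly through dict/YAML serialization.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping

import yaml


@dataclass(frozen=True)
class RunConfig:
    """Tunable constants of one calibration run."""

    n_init: int = 5000
    n_centers: int = 5
    batch_per_component: int = 100
    target_ess: float = 5000.0
    max_iterations: int = 100
    shrink_factor: float = 0.5
    min_draws_retained: int = 50
    defensive_weight: float = 0.1
    cov_reg: float = 1e-8

    def __post_init__(self) -> None:
        for name in ("n_init", "n_centers", "batch_per_component", "max_iterations",
                     "min_draws_retained"):
            if getattr(self, name) < 0 or (name != "max_iterations" and getattr(self, name) == 0):
                raise ValueError(f"{name} must be positive")
        if self.target_ess < 1:
            raise ValueError("target_ess must be >= 1")
        if not 0.0 < self.shrink_factor <= 1.0:
            raise ValueError("shrink_factor must lie in (0, 1]")
        if not 0.0 < self.defensive_weight < 1.0:
            raise ValueError("defensive_weight must lie in (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, doc: Mapping) -> "RunConfig":
        return cls(**{k: doc[k] for k in cls.__dataclass_fields__ if k in doc})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False),
                              encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text(encoding="utf-8")))
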