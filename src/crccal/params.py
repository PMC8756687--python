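"""Natural-history model parameters.

The model carries 22 calibrated parameters plus two fixed inputs (the
minimum and maximum adenoma diameters ``d0`` and ``d_infinity``).  The
calibrated block covers four components of colorectal-cancer natural
history: adenoma risk (A, sigma_alpha, alpha1, four piecewise age
slopes), adenoma growth (a Frechet time-to-10mm pair per anatomical
site plus the Richards shape ``p_growth``), the size at malignant
transition (six log-normal mean coefficients and a log-scale sd), and
the preclinical-to-clinical sojourn time (Weibull scale/shape and a
rectum location effect).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

#: Names of the 22 calibrated parameters, in canonical column order.
CALIBRATED_NAMES: tuple[str, ...] = (
    "A",
    "sigma_alpha",
    "alpha1",
    "alpha20",
    "alpha50",
    "alpha60",
    "alpha70",
    "beta1_colon",
    "beta2_colon",
    "beta1_rectum",
    "beta2_rectum",
    "p_growth",
    "gamma0",
    "gamma1",
    "gamma2",
    "gamma3",
    "gamma4",
    "gamma5",
    "sigma_gamma",
    "lambda1",
    "lambda2",
    "lambda3",
)

#: Fixed inputs: never sampled during calibration.
FIXED_NAMES: tuple[str, ...] = ("d0", "d_infinity")

_POSITIVE = (
    "sigma_alpha",
    "beta1_colon",
    "beta2_colon",
    "beta1_rectum",
    "beta2_rectum",
    "p_growth",
    "sigma_gamma",
    "lambda1",
    "lambda2",
)
# sigma_alpha / sigma_gamma are standard deviations and may be zero
# (degenerate distributions are useful in tests); strictly-positive
# checks apply to shapes and scales only.
_NONNEG = ("sigma_alpha", "sigma_gamma")


@dataclass(frozen=True)
class NaturalHistoryParams:
    """One complete natural-history parameter set.

    All rates are per year, ages in years, diameters in mm.
    """

    A: float
    sigma_alpha: float
    alpha1: float
    alpha20: float
    alpha50: float
    alpha60: float
    alpha70: float
    beta1_colon: float
    beta2_colon: float
    beta1_rectum: float
    beta2_rectum: float
    p_growth: float
    gamma0: float
    gamma1: float
    gamma2: float
    gamma3: float
    gamma4: float
    gamma5: float
    sigma_gamma: float
    lambda1: float
    lambda2: float
    lambda3: float
    d0: float = 1.0
    d_infinity: float = 50.0

    def __post_init__(self) -> None:
        for name in _POSITIVE:
            v = getattr(self, name)
            if name in _NONNEG:
                if v < 0:
                    raise ValueError(f"{name} must be >= 0, got {v}")
            elif v <= 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        if not self.d0 < self.d_infinity:
            raise ValueError(
                f"d0 ({self.d0}) must be below d_infinity ({self.d_infinity})"
            )

    # -- vector conversion -------------------------------------------------

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def calibrated_vector(self, names: Iterable[str] = CALIBRATED_NAMES) -> np.ndarray:
        """Ordered values of (a subset of) the calibrated parameters."""
        return np.array([getattr(self, n) for n in names], dtype=float)

    def with_updates(self, updates: Mapping[str, float]) -> "NaturalHistoryParams":
        bad = set(updates) - set(CALIBRATED_NAMES) - set(FIXED_NAMES)
        if bad:
            raise KeyError(f"unknown parameter(s): {sorted(bad)}")
        return replace(self, **dict(updates))

    # -- serialization -----------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=False), encoding="utf-8"
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "NaturalHistoryParams":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls(**{k: float(v) for k, v in data.items()})


def params_frame(draws: Iterable[NaturalHistoryParams]) -> pd.DataFrame:
    """Stack parameter sets into a draws table, one named column per parameter."""
    return pd.DataFrame([p.to_dict() for p in draws])


def write_draws_csv(draws: Iterable[NaturalHistoryParams], path: str | Path) -> None:
    params_frame(draws).to_csv(path, index=False, float_format="%.17g")


def read_draws_csv(path: str | Path) -> list[NaturalHistoryParams]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [NaturalHistoryParams(**row) for row in df.to_dict(orient="records")]
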