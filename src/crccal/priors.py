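"""Prior specifications: independent truncated-normal or uniform margins.

Every calibrated parameter carries a bounded support so the defensive
component of the importance-sampling proposal is proper.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy import stats


@dataclass(frozen=True)
class MarginalPrior:
    """One parameter's prior: uniform(lower, upper) or a normal(mu, sd)
    truncated to [lower, upper]."""

    family: str  # "uniform" | "truncnorm"
    lower: float
    upper: float
    mu: float | None = None
    sd: float | None = None

    def __post_init__(self) -> None:
        if self.family not in ("uniform", "truncnorm"):
            raise ValueError(f"unknown prior family {self.family!r}")
        if not self.lower < self.upper:
            raise ValueError("prior support must have lower < upper")
        if self.family == "truncnorm" and (self.mu is None or self.sd is None or self.sd <= 0):
            raise ValueError("truncnorm prior needs mu and sd > 0")

    def _dist(self):
        if self.family == "uniform":
            return stats.uniform(self.lower, self.upper - self.lower)
        a = (self.lower - self.mu) / self.sd
        b = (self.upper - self.mu) / self.sd
        return stats.truncnorm(a, b, loc=self.mu, scale=self.sd)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self._dist().rvs(size=n, random_state=rng)

    def logpdf(self, x: np.ndarray) -> np.ndarray:
        return self._dist().logpdf(x)


@dataclass(frozen=True)
class PriorSpec:
    """Independent product prior over named free parameters."""

    margins: tuple[tuple[str, MarginalPrior], ...]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.margins)

    @property
    def dim(self) -> int:
        return len(self.margins)

    @property
    def bounds(self) -> np.ndarray:
        return np.array([[m.lower, m.upper] for _, m in self.margins])

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return np.column_stack([m.sample(n, rng) for _, m in self.margins])

    def logpdf(self, theta: np.ndarray) -> np.ndarray:
        """Log prior density of draws (rows); -inf outside the support."""
        theta = np.atleast_2d(theta)
        out = np.zeros(len(theta))
        for j, (_, m) in enumerate(self.margins):
            out += m.logpdf(theta[:, j])
        return out

    def in_support(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        b = self.bounds
        return np.all((theta >= b[:, 0]) & (theta <= b[:, 1]), axis=1)

    # -- serialization -----------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        doc = {}
        for name, m in self.margins:
            entry = {"family": m.family, "lower": m.lower, "upper": m.upper}
            if m.family == "truncnorm":
                entry.update(mu=m.mu, sd=m.sd)
            doc[name] = entry
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PriorSpec":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: Mapping[str, Mapping[str, object]]) -> "PriorSpec":
        margins = []
        for name, e in doc.items():
            margins.append(
                (
                    name,
                    MarginalPrior(
                        family=e["family"],
                        lower=float(e["lower"]),
                        upper=float(e["upper"]),
                        mu=float(e["mu"]) if "mu" in e else None,
                        sd=float(e["sd"]) if "sd" in e else None,
                    ),
                )
            )
        return cls(tuple(margins))
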