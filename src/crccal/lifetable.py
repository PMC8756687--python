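"""Synthetic other-cause mortality.

A piecewise-constant hazard life table rising with age stands in for
registry product-limit estimates: it preserves the censoring structure
(agents can die of other causes before any lesion becomes clinical)
without requiring external data.  Hazards are configurable; defaults
give a life expectancy in the high 70s and near-certain death by the
simulation horizon of 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_DEFAULT_BREAKS = (0.0, 40.0, 55.0, 65.0, 75.0, 85.0, 95.0)
# per-year hazards on the intervals between successive breaks
# (last value applies from the final break onward)
_DEFAULT_HAZARDS = (0.001, 0.004, 0.012, 0.03, 0.08, 0.18, 0.45)


@dataclass(frozen=True)
class LifeTable:
    """Piecewise-constant other-cause mortality hazard."""

    breaks: tuple[float, ...] = _DEFAULT_BREAKS
    hazards: tuple[float, ...] = _DEFAULT_HAZARDS
    max_age: float = 100.0

    def __post_init__(self) -> None:
        if len(self.hazards) != len(self.breaks):
            raise ValueError("need one hazard per age break")
        if any(h < 0 for h in self.hazards):
            raise ValueError("hazards must be non-negative")
        if list(self.breaks) != sorted(self.breaks):
            raise ValueError("breaks must be increasing")

    def cumulative_hazard(self, age: np.ndarray | float) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        br = np.asarray(self.breaks)
        hz = np.asarray(self.hazards)
        # time spent in each hazard band, clipped to [0, band width]
        upper = np.append(br[1:], np.inf)
        exposure = np.clip(age[..., None] - br, 0.0, upper - br)
        return exposure @ hz

    def survival(self, age: np.ndarray | float) -> np.ndarray:
        return np.exp(-self.cumulative_hazard(age))

    def sample_death_age(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw other-cause death ages by inverting the cumulative hazard.

        Ages are truncated at ``max_age`` (everyone dies by the horizon).
        """
        target = rng.exponential(size=n)  # cumulative hazard at death
        br = np.asarray(self.breaks)
        hz = np.asarray(self.hazards)
        cum_at_breaks = self.cumulative_hazard(br)
        idx = np.searchsorted(cum_at_breaks, target, side="right") - 1
        idx = np.clip(idx, 0, len(br) - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            extra = (target - cum_at_breaks[idx]) / hz[idx]
        extra = np.where(np.isfinite(extra), extra, np.inf)
        return np.minimum(br[idx] + extra, self.max_age)
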