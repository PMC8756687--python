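"""Calibration targets: definition, simulation and tolerance intervals.

A calibration target is a published summary statistic — an incidence
rate per 100,000, an adenoma prevalence, a size-bin percentage, a
preclinical-cancer yield per 1,000 lesions, or a screen-detection
proportion — together with the sample size it was estimated from and a
pair of accept bands: a wide *initial* interval where calibration
starts and a narrow *final* interval (here a Wilson score interval at
the target's own sample size) that accepted parameter draws must
ultimately satisfy.

Reported size categories (<=5 mm, 6-9 mm, >=10 mm) are operationalized
with half-open bins [1, 5.5), [5.5, 9.5) and [9.5, inf) mm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml
from statsmodels.stats.proportion import proportion_confint

from .lifetable import LifeTable
from .params import NaturalHistoryParams
from .population import Population, simulate_population
from .screening import SensitivityModel, colonoscopy_model, screen_population, sigmoidoscopy_model

#: Half-open size-bin edges (mm) for categorical lesion-size reporting.
SIZE_BIN_EDGES: tuple[float, float] = (5.5, 9.5)


def size_bin_label(size: float) -> str:
    """Half-open size category: [1, 5.5) -> 'le5', [5.5, 9.5) -> '6to9',
    [9.5, inf) -> 'ge10'."""
    if size < SIZE_BIN_EDGES[0]:
        return "le5"
    if size < SIZE_BIN_EDGES[1]:
        return "6to9"
    return "ge10"


class MonteCarloPrecisionError(RuntimeError):
    """The study population is too small to resolve a target's final band."""


@dataclass(frozen=True)
class ToleranceInterval:
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"interval must have lower < upper, got {self}")

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper

    def width(self) -> float:
        return self.upper - self.lower


@dataclass(frozen=True)
class StudySpec:
    """A simulated study population used to compute one group of targets."""

    id: str
    n_agents: int
    age_range: tuple[float, float]
    fraction_female: float = 0.5
    test: Literal["none", "colonoscopy", "sigmoidoscopy"] = "none"
    # agents enter (or are screened) at an age drawn uniformly in age_range
    condition: str = "free of clinical CRC; no prior screening"
    # natural histories are simulated to this age; events after the last
    # observed age cannot affect the study's statistics, so specs set it
    # just past the age range for speed (default: the full lifespan)
    horizon: float = 100.0

    def __post_init__(self) -> None:
        if self.n_agents <= 0:
            raise ValueError("n_agents must be positive")
        if not 0.0 <= self.fraction_female <= 1.0:
            raise ValueError("fraction_female must lie in [0, 1]")

    def sensitivity_model(self) -> SensitivityModel | None:
        if self.test == "colonoscopy":
            return colonoscopy_model()
        if self.test == "sigmoidoscopy":
            return sigmoidoscopy_model()
        return None


@dataclass(frozen=True)
class Target:
    """One calibration target with observed value and accept bands.

    ``scale`` maps the proportion scale used internally to the reported
    scale (1 for proportions, 1e5 for rates per 100,000, 100 for
    percentages, 1000 for per-1,000 yields).
    """

    name: str
    observed_value: float
    sample_size: float
    initial_interval: ToleranceInterval
    final_interval: ToleranceInterval
    study_spec_id: str
    scale: float = 1.0

    def __post_init__(self) -> None:
        fi, ii = self.final_interval, self.initial_interval
        if fi.lower < ii.lower - 1e-12 or fi.upper > ii.upper + 1e-12:
            raise ValueError(f"final interval must lie inside initial ({self.name})")
        if not fi.contains(self.observed_value):
            raise ValueError(f"observed value outside final interval ({self.name})")


# ---------------------------------------------------------------------------
# tolerance-interval construction
# ---------------------------------------------------------------------------

def tolerance_intervals(
    observed_value: float,
    sample_size: float,
    level: float = 0.95,
    inflation: float = 10.0,
    scale: float = 1.0,
    support: tuple[float, float] | None = None,
) -> tuple[ToleranceInterval, ToleranceInterval]:
    """Build (initial, final) accept bands around an observed proportion.

    The final band is the Wilson score interval at ``level``; the
    initial band widens it about the observed value by ``inflation``
    and truncates to the statistic's natural range.  ``observed_value``
    is on the reported scale; ``scale`` converts to proportions.
    """
    if sample_size <= 0:
        raise ValueError("sample_size must be positive")
    p = observed_value / scale
    if not 0.0 <= p <= 1.0:
        raise ValueError("observed value must map to a proportion in [0, 1]")
    lo, hi = proportion_confint(p * sample_size, sample_size, alpha=1 - level, method="wilson")
    final = ToleranceInterval(float(lo) * scale, float(hi) * scale)
    if support is None:
        support = (0.0, scale)
    init_lo = max(observed_value - inflation * (observed_value - final.lower), support[0])
    init_hi = min(observed_value + inflation * (final.upper - observed_value), support[1])
    return ToleranceInterval(init_lo, init_hi), final


def check_mc_precision(
    target: Target,
    n_agents: int,
    max_se_ratio: float = 0.2,
    mode: Literal["error", "warn", "ignore"] = "error",
) -> float:
    """Binomial Monte-Carlo SE of the simulated target vs its final band.

    Returns the ratio of the MC standard error (simulating the target
    with ``n_agents`` agents) to the final-interval half-width; above
    ``max_se_ratio`` the target is refused (or warned about) because
    simulation noise would dominate the accept decision.
    """
    p = target.observed_value / target.scale
    se = np.sqrt(max(p * (1 - p), 1e-12) / n_agents) * target.scale
    ratio = se / (target.final_interval.width() / 2.0)
    if ratio > max_se_ratio:
        msg = (
            f"target {target.name!r}: MC SE {se:.3g} is {ratio:.2f}x the final "
            f"half-width with {n_agents} agents (limit {max_se_ratio})"
        )
        if mode == "error":
            raise MonteCarloPrecisionError(msg)
        if mode == "warn":
            warnings.warn(msg, RuntimeWarning, stacklevel=2)
    return float(ratio)


# ---------------------------------------------------------------------------
# target simulation from a Population
# ---------------------------------------------------------------------------

def incidence_rate(
    pop: Population, age_band: tuple[float, float], sex: Literal["male", "female", "all"] = "all"
) -> float:
    """Clinical-cancer incidence per 100,000 person-years in an age band.

    Follows every agent through each one-year interval in the band:
    eligible if alive and free of clinical cancer at the interval
    start, an event if the first clinical cancer falls inside it.
    """
    first = pop.first_clinical_age()
    mask = _sex_mask(pop, sex)
    events = 0
    eligible = 0
    for a in np.arange(age_band[0], age_band[1]):
        at_risk = mask & (pop.death_age > a) & (first > a)
        eligible += int(at_risk.sum())
        events += int((at_risk & (first < a + 1.0)).sum())
    if eligible == 0:
        raise ValueError(f"no eligible agents in band {age_band} / {sex}")
    return events / eligible * 1e5


def _sex_mask(pop: Population, sex: str) -> np.ndarray:
    if sex == "all":
        return np.ones(pop.n, dtype=bool)
    if sex == "female":
        return pop.female == 1
    if sex == "male":
        return pop.female == 0
    raise ValueError(f"unknown sex {sex!r}")


def _prob_any(pop: Population, p_lesion: np.ndarray) -> np.ndarray:
    """Per-agent probability that >=1 lesion is detected, given per-lesion
    detection probabilities (independent detection)."""
    log_miss = np.zeros(pop.n)
    if len(pop.owner):
        np.add.at(log_miss, pop.owner, np.log1p(-np.minimum(p_lesion, 1.0 - 1e-15)))
    return 1.0 - np.exp(log_miss)


def detected_lesion_summaries(
    pop: Population,
    screen_age: np.ndarray,
    model: SensitivityModel,
    rng: np.random.Generator | None = None,
) -> dict[str, object]:
    """Colonoscopy-style detection summaries for one screened population.

    Returns adenoma-prevalence by sex, the percentage of detected
    adenomas per size bin (summing to 100), and detected preclinical
    cancers per 1,000 detected lesions per size bin.  Detection enters
    through its conditional expectation given the lesion roster
    (per-lesion detection probabilities), which estimates the same
    population quantities as Bernoulli detection draws with strictly
    smaller Monte Carlo variance.
    """
    res = screen_population(pop, screen_age, model)
    p_det, is_cancer, size = res["p_detect"], res["is_cancer"], res["size"]
    eligible = res["eligible"]
    if not p_det.sum() > 0:
        raise ValueError("zero detected lesions; summaries undefined")

    e_aden = np.where(~is_cancer, p_det, 0.0)
    has_aden = _prob_any(pop, e_aden)

    prevalence = {}
    for sex in ("male", "female"):
        m = _sex_mask(pop, sex) & eligible
        prevalence[sex] = float(has_aden[m].mean()) if m.any() else np.nan

    lo, hi = SIZE_BIN_EDGES
    bins = {
        "le5": size < lo,
        "6to9": (size >= lo) & (size < hi),
        "ge10": size >= hi,
    }
    n_det_aden = float(e_aden.sum())
    size_pct = {}
    cancers_per_1000 = {}
    for label, inbin in bins.items():
        size_pct[label] = (
            100.0 * float(e_aden[inbin].sum()) / n_det_aden if n_det_aden else np.nan
        )
        n_lesions = float(p_det[inbin].sum())
        cancers_per_1000[label] = (
            1000.0 * float(p_det[inbin & is_cancer].sum()) / n_lesions
            if n_lesions
            else np.nan
        )
    return {
        "prevalence": prevalence,
        "size_pct": size_pct,
        "cancers_per_1000": cancers_per_1000,
        "n_detected_adenomas": n_det_aden,
    }


def screen_detection_rates(
    pop: Population,
    screen_age: np.ndarray,
    model: SensitivityModel,
    rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """Proportion of screened agents with >=1 preclinical cancer detected,
    by sex and overall (person-count weighted).

    Uses the expected per-agent detection probability given the lesion
    roster (see :func:`detected_lesion_summaries`).
    """
    res = screen_population(pop, screen_age, model)
    e_cancer = np.where(res["is_cancer"], res["p_detect"], 0.0)
    cancer_found = _prob_any(pop, e_cancer)
    out = {}
    counts = {}
    for sex in ("male", "female"):
        m = _sex_mask(pop, sex) & res["eligible"]
        if not m.any():
            raise ValueError(f"empty {sex} stratum")
        out[sex] = float(cancer_found[m].mean())
        counts[sex] = int(m.sum())
    out["overall"] = combine_rates(
        out["male"], counts["male"], out["female"], counts["female"]
    )
    return out


def combine_rates(rate_m: float, n_m: float, rate_f: float, n_f: float) -> float:
    """Person-count-weighted overall rate from two sex-specific rates."""
    return (rate_m * n_m + rate_f * n_f) / (n_m + n_f)


# ---------------------------------------------------------------------------
# StudySpec-level wrappers (one population per call)
# ---------------------------------------------------------------------------

def _build_population(
    spec: StudySpec,
    params: NaturalHistoryParams,
    rng: np.random.Generator,
    life_table: LifeTable | None = None,
) -> tuple[Population, np.ndarray]:
    pop = simulate_population(
        params, spec.n_agents, rng, female=spec.fraction_female,
        life_table=life_table, horizon=spec.horizon,
    )
    screen_age = rng.uniform(spec.age_range[0], spec.age_range[1], size=spec.n_agents)
    return pop, screen_age


def simulate_incidence_target(
    study_spec: StudySpec,
    params: NaturalHistoryParams,
    age_band: tuple[float, float],
    sex: Literal["male", "female", "all"],
    rng: np.random.Generator,
    life_table: LifeTable | None = None,
) -> float:
    """Annual clinical-cancer incidence per 100,000 for one band and sex."""
    pop = simulate_population(
        params, study_spec.n_agents, rng, female=study_spec.fraction_female,
        life_table=life_table, horizon=study_spec.horizon,
    )
    return incidence_rate(pop, age_band, sex)


def simulate_prevalence_and_size_targets(
    study_spec: StudySpec,
    params: NaturalHistoryParams,
    rng: np.random.Generator,
    life_table: LifeTable | None = None,
) -> dict[str, object]:
    """Adenoma prevalence and detected-lesion size summaries (colonoscopy)."""
    model = study_spec.sensitivity_model()
    if model is None or model.test != "colonoscopy":
        raise ValueError("prevalence/size targets require a colonoscopy study spec")
    pop, screen_age = _build_population(study_spec, params, rng, life_table)
    return detected_lesion_summaries(pop, screen_age, model, rng)


def simulate_screen_detection_target(
    study_spec: StudySpec,
    params: NaturalHistoryParams,
    rng: np.random.Generator,
    life_table: LifeTable | None = None,
) -> dict[str, float]:
    """Sex-specific and overall screen-detection proportions."""
    model = study_spec.sensitivity_model()
    if model is None:
        raise ValueError("screen-detection targets require a screening test")
    pop, screen_age = _build_population(study_spec, params, rng, life_table)
    return screen_detection_rates(pop, screen_age, model, rng)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_TARGET_COLUMNS = [
    "name", "observed_value", "sample_size", "lower_init", "upper_init",
    "lower_final", "upper_final", "study_spec_id", "scale",
]


def write_targets_csv(targets: Sequence[Target], path: str | Path) -> None:
    rows = [
        {
            "name": t.name,
            "observed_value": t.observed_value,
            "sample_size": t.sample_size,
            "lower_init": t.initial_interval.lower,
            "upper_init": t.initial_interval.upper,
            "lower_final": t.final_interval.lower,
            "upper_final": t.final_interval.upper,
            "study_spec_id": t.study_spec_id,
            "scale": t.scale,
        }
        for t in targets
    ]
    pd.DataFrame(rows, columns=_TARGET_COLUMNS).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_targets_csv(path: str | Path) -> list[Target]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [
        Target(
            name=r["name"],
            observed_value=float(r["observed_value"]),
            sample_size=float(r["sample_size"]),
            initial_interval=ToleranceInterval(float(r["lower_init"]), float(r["upper_init"])),
            final_interval=ToleranceInterval(float(r["lower_final"]), float(r["upper_final"])),
            study_spec_id=str(r["study_spec_id"]),
            scale=float(r.get("scale", 1.0)),
        )
        for _, r in df.iterrows()
    ]


def write_study_specs_yaml(specs: Sequence[StudySpec], path: str | Path) -> None:
    doc = {
        s.id: {
            "n_agents": s.n_agents,
            "age_range": list(s.age_range),
            "fraction_female": s.fraction_female,
            "test": s.test,
            "condition": s.condition,
            "horizon": s.horizon,
        }
        for s in specs
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")


def read_study_specs_yaml(path: str | Path) -> dict[str, StudySpec]:
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    return {
        key: StudySpec(
            id=key,
            n_agents=int(v["n_agents"]),
            age_range=tuple(v["age_range"]),
            fraction_female=float(v["fraction_female"]),
            test=v.get("test", "none"),
            condition=v.get("condition", ""),
            horizon=float(v.get("horizon", 100.0)),
        )
        for key, v in doc.items()
    }
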