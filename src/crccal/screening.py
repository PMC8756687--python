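"""Size-dependent test sensitivity and one-time screening outcomes.

Colonoscopy sensitivity for adenomas is anchored at three sizes taken
from back-to-back colonoscopy studies — 0.81 at 5 mm, 0.92 at 10 mm and
0.98 at 15 mm — and interpolated monotonically (piecewise linear)
between them, reaching 1.0 at 20 mm and falling to a configurable
minimum at the 1 mm detection floor.  Preclinical cancers are easier to
recognise than size alone suggests, so their sensitivity is the maximum
of 0.95 and the size-based adenoma sensitivity: 0.95 up to 12 mm,
rising above it for larger cancers.

The whole model serialises to YAML so experiments that re-specify a
fixed input (for instance lowering small-adenoma sensitivity) are a
config change, not a code change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import yaml

from .natural_history import AgentHistory
from .params import NaturalHistoryParams
from .population import Population

TestType = Literal["colonoscopy", "sigmoidoscopy"]

DEFAULT_ANCHORS: tuple[tuple[float, float], ...] = (
    (1.0, 0.70),
    (5.0, 0.81),
    (10.0, 0.92),
    (15.0, 0.98),
    (20.0, 1.0),
)


@dataclass(frozen=True)
class SensitivityModel:
    """Size-dependent per-lesion detection probability for one test.

    ``anchors`` are (size mm, sensitivity) pairs, interpolated linearly
    and clamped outside their range; ``preclinical_floor`` is the
    minimum sensitivity for preclinical cancers regardless of size.
    ``colon_reach`` is the fraction of colonic lesions within the
    test's reach (1 for colonoscopy; a distal-colon stand-in fraction
    for flexible sigmoidoscopy, which always reaches the rectum).
    """

    anchors: tuple[tuple[float, float], ...] = DEFAULT_ANCHORS
    preclinical_floor: float = 0.95
    test: TestType = "colonoscopy"
    colon_reach: float = 1.0
    rectum_reach: float = 1.0

    def __post_init__(self) -> None:
        sizes = [a[0] for a in self.anchors]
        sens = [a[1] for a in self.anchors]
        if sizes != sorted(sizes):
            raise ValueError("anchor sizes must be increasing")
        if sens != sorted(sens):
            raise ValueError("sensitivities must be non-decreasing in size")
        if not all(0.0 <= s <= 1.0 for s in sens):
            raise ValueError("sensitivities must lie in [0, 1]")
        for name in ("preclinical_floor", "colon_reach", "rectum_reach"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    # -- sensitivities -----------------------------------------------------

    def adenoma_sensitivity(self, size: np.ndarray | float) -> np.ndarray | float:
        """Detection probability for an adenoma of ``size`` mm."""
        scalar = np.isscalar(size)
        size = np.asarray(size, dtype=float)
        if np.any(size < 1.0):
            raise ValueError("lesion size below the 1 mm detection floor")
        xs = np.array([a[0] for a in self.anchors])
        ys = np.array([a[1] for a in self.anchors])
        out = np.interp(size, xs, ys)
        return float(out) if scalar else out

    def preclinical_sensitivity(self, size: np.ndarray | float) -> np.ndarray | float:
        """Detection probability for a preclinical cancer of ``size`` mm."""
        out = np.maximum(self.preclinical_floor, self.adenoma_sensitivity(size))
        return float(out) if np.isscalar(size) else out

    def reach(self, is_rectum: np.ndarray | bool) -> np.ndarray | float:
        return np.where(np.asarray(is_rectum), self.rectum_reach, self.colon_reach)

    # -- serialization -----------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "test": self.test,
            "anchors": [list(a) for a in self.anchors],
            "preclinical_floor": self.preclinical_floor,
            "colon_reach": self.colon_reach,
            "rectum_reach": self.rectum_reach,
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SensitivityModel":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls(
            anchors=tuple(tuple(a) for a in doc["anchors"]),
            preclinical_floor=float(doc["preclinical_floor"]),
            test=doc.get("test", "colonoscopy"),
            colon_reach=float(doc.get("colon_reach", 1.0)),
            rectum_reach=float(doc.get("rectum_reach", 1.0)),
        )


def colonoscopy_model() -> SensitivityModel:
    """Default colonoscopy: full reach, standard anchors."""
    return SensitivityModel(test="colonoscopy")


def sigmoidoscopy_model(colon_reach: float = 0.4) -> SensitivityModel:
    """Flexible sigmoidoscopy: full rectal reach, partial colonic reach.

    With only two anatomical sites the reachable distal colon is
    represented by a configurable fraction of colonic lesions.
    """
    return SensitivityModel(test="sigmoidoscopy", colon_reach=colon_reach)


# ---------------------------------------------------------------------------
# screening outcomes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreenOutcome:
    """Per-lesion results of one agent's one-time screen."""

    screen_age: float
    lesion_sizes: tuple[float, ...]
    lesion_is_cancer: tuple[bool, ...]
    detected: tuple[bool, ...]

    @property
    def cancer_detected(self) -> bool:
        return any(d and c for d, c in zip(self.detected, self.lesion_is_cancer))

    @property
    def any_adenoma_detected(self) -> bool:
        return any(d and not c for d, c in zip(self.detected, self.lesion_is_cancer))


def simulate_screen(
    history: AgentHistory,
    screen_age: float,
    model: SensitivityModel,
    params: NaturalHistoryParams,
    rng: np.random.Generator,
) -> ScreenOutcome:
    """Screen one agent at ``screen_age``; each lesion present is detected
    independently with its size-based sensitivity times the test's reach.

    Lesions present are adenomas not yet transitioned and preclinical
    cancers not yet clinical.  Detected adenomas are considered removed
    (one-time screens only), which matters to callers tallying yield,
    not to this function.
    """
    if screen_age > history.death_age_other_cause:
        raise ValueError("screen_age is outside the agent's alive interval")
    if history.clinical_crc_age is not None and screen_age > history.clinical_crc_age:
        raise ValueError("agent has clinically detected cancer before screen_age")
    sizes, is_cancer, detected = [], [], []
    for a in history.adenomas:
        if a.init_age > screen_age:
            continue
        cancer = a.transition_age is not None and a.transition_age <= screen_age
        if cancer and a.clinical_age is not None and a.clinical_age <= screen_age:
            continue  # already clinical: excluded by precondition in practice
        size = max(a.diameter_at(screen_age, params), params.d0)
        sens = (
            model.preclinical_sensitivity(size)
            if cancer
            else model.adenoma_sensitivity(size)
        )
        p = sens * float(model.reach(a.location == "rectum"))
        sizes.append(size)
        is_cancer.append(cancer)
        detected.append(bool(rng.random() < p))
    return ScreenOutcome(screen_age, tuple(sizes), tuple(is_cancer), tuple(detected))


def screen_population(
    pop: Population,
    screen_age: np.ndarray,
    model: SensitivityModel,
    rng: np.random.Generator | None = None,
) -> dict[str, np.ndarray]:
    """Vectorized one-time screen of a whole population.

    ``screen_age`` is a per-agent attained age.  Returns lesion-level
    arrays (``present``, ``is_cancer``, ``size``, ``p_detect``) and the
    per-agent ``eligible`` mask (alive, free of clinical cancer at the
    screen).  ``p_detect`` combines size-based sensitivity with the
    reach probability for the lesion's site (zero for absent lesions);
    when ``rng`` is given, Bernoulli ``detected`` flags are drawn too.
    """
    first_clin = pop.first_clinical_age()
    eligible = (screen_age < pop.death_age) & (screen_age < first_clin)

    sa_lesion = screen_age[pop.owner]
    initiated = pop.init_age <= sa_lesion
    is_cancer = initiated & (pop.transition_age <= sa_lesion)
    not_clinical = ~(pop.clinical_age <= sa_lesion)
    present = initiated & not_clinical & eligible[pop.owner]

    size = np.maximum(pop.diameters_at(screen_age), pop.params.d0)
    sens = np.where(
        is_cancer,
        np.maximum(model.preclinical_floor, _interp_anchor(model, size)),
        _interp_anchor(model, size),
    )
    p = sens * np.where(pop.is_rectum, model.rectum_reach, model.colon_reach)
    out = {
        "eligible": eligible,
        "present": present,
        "is_cancer": is_cancer,
        "size": size,
        "p_detect": np.where(present, p, 0.0),
    }
    if rng is not None:
        out["detected"] = present & (rng.random(len(pop.owner)) < p)
    return out


def _interp_anchor(model: SensitivityModel, size: np.ndarray) -> np.ndarray:
    xs = np.array([a[0] for a in model.anchors])
    ys = np.array([a[1] for a in model.anchors])
    return np.interp(size, xs, ys)
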