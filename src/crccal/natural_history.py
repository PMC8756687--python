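"""Individual-level natural history of colorectal cancer.

Event histories follow the adenoma-carcinoma sequence in four
components:

1. **Adenoma risk** — adenomas arise via a non-homogeneous Poisson
   process whose log-intensity is piecewise linear in age with knots at
   50, 60 and 70 years and zero risk before age 20.  Person-level
   heterogeneity enters through a normal random intercept
   ``alpha0 ~ N(A, sigma_alpha)`` and a female effect ``alpha1``.
2. **Adenoma growth** — each adenoma draws a hypothetical time to reach
   10 mm from a Frechet distribution (site-specific shape/scale); that
   time pins the rate constant of a Richards growth curve running from
   ``d0`` = 1 mm to the asymptote ``d_infinity`` = 50 mm.
3. **Transition to preclinical cancer** — the lesion size at malignant
   transition is log-normal with a mean depending on sex, site and age
   at initiation (in decades, centred at 50); an adenoma transitions
   iff its growth curve reaches that size within the horizon.
4. **Sojourn time** — the preclinical-to-clinical interval is Weibull
   with scale ``lambda1`` and shape ``lambda2`` in the colon; rectal
   cancers use the scale multiplied by ``exp(lambda3)`` (an
   accelerated-scale location effect, so the rectal mean sojourn time
   is ``lambda1 * exp(lambda3) * Gamma(1 + 1/lambda2)``).

The per-agent functions here are deliberately plain scalar code: they
are the readable reference path, and the batch simulator in
:mod:`crccal.population` is tested against them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.special import gamma as gamma_fn

from .lifetable import LifeTable
from .params import NaturalHistoryParams

Location = Literal["colon", "rectum"]

#: Age knots of the piecewise-linear log-risk (start of risk, then slope
#: changes).  Slopes apply on [20,50), [50,60), [60,70), [70, inf).
RISK_KNOTS: tuple[float, ...] = (20.0, 50.0, 60.0, 70.0)

#: Default probability that a new adenoma is rectal rather than colonic.
#: Stand-in for full colon anatomy; a single interpretable knob.
DEFAULT_RECTUM_PROB = 0.25

DEFAULT_HORIZON = 100.0


# ---------------------------------------------------------------------------
# adenoma risk (component 1)
# ---------------------------------------------------------------------------

def adenoma_log_risk(
    age: float, female: int, alpha0: float, params: NaturalHistoryParams
) -> float:
    """Log instantaneous adenoma risk ``ln psi(age)``.

    Returns ``-inf`` (zero risk) before age 20.
    """
    if age < 0:
        raise ValueError(f"age must be >= 0, got {age}")
    if age < 20.0:
        return -math.inf
    out = alpha0 + params.alpha1 * female
    out += min(age - 20.0, 30.0) * params.alpha20
    if age >= 50.0:
        out += min(age - 50.0, 10.0) * params.alpha50
    if age >= 60.0:
        out += min(age - 60.0, 10.0) * params.alpha60
    if age >= 70.0:
        out += (age - 70.0) * params.alpha70
    return out


def _risk_segments(
    female: int, alpha0: float, params: NaturalHistoryParams, horizon: float
) -> list[tuple[float, float, float, float]]:
    """Break [20, horizon] into log-linear pieces (a0, a1, log-risk(a0), slope)."""
    # each age term is capped (min(a-20,30), min(a-50,10), min(a-60,10)),
    # so exactly one slope is active per segment
    slopes = {
        20.0: params.alpha20,
        50.0: params.alpha50,
        60.0: params.alpha60,
        70.0: params.alpha70,
    }
    edges = [k for k in RISK_KNOTS if k < horizon] + [horizon]
    segs = []
    for a0, a1 in zip(edges[:-1], edges[1:]):
        segs.append((a0, a1, adenoma_log_risk(a0, female, alpha0, params), slopes[a0]))
    return segs


def integrated_risk(
    female: int, alpha0: float, params: NaturalHistoryParams, horizon: float
) -> float:
    """Expected adenoma count ``∫_20^horizon psi(a) da`` in closed form."""
    if horizon <= 20.0:
        return 0.0
    total = 0.0
    for a0, a1, logpsi0, slope in _risk_segments(female, alpha0, params, horizon):
        length = a1 - a0
        if abs(slope) < 1e-12:
            total += math.exp(logpsi0) * length
        else:
            total += math.exp(logpsi0) * (math.exp(slope * length) - 1.0) / slope
    if not math.isfinite(total):
        raise FloatingPointError("adenoma intensity integral is non-finite")
    return total


def sample_adenoma_initiations(
    female: int,
    alpha0: float,
    params: NaturalHistoryParams,
    horizon: float,
    rng: np.random.Generator,
    rectum_prob: float = DEFAULT_RECTUM_PROB,
) -> list[tuple[float, Location]]:
    """Draw adenoma initiation ages and sites from the risk process.

    Thinning with a per-segment constant majorant: on each piece the
    log-intensity is linear, so its maximum sits at an endpoint and the
    scheme is exact.  Sites are assigned independently (rectum with
    probability ``rectum_prob``).
    """
    integrated_risk(female, alpha0, params, max(horizon, 20.0))  # finite-ness check
    events: list[tuple[float, Location]] = []
    if horizon <= 20.0:
        return events
    for a0, a1, logpsi0, slope in _risk_segments(female, alpha0, params, horizon):
        log_major = max(logpsi0, logpsi0 + slope * (a1 - a0))
        major = math.exp(log_major)
        if major <= 0.0:
            continue
        t = a0
        while True:
            t += rng.exponential(1.0 / major)
            if t >= a1:
                break
            if rng.random() * major <= math.exp(
                adenoma_log_risk(t, female, alpha0, params)
            ):
                loc: Location = "rectum" if rng.random() < rectum_prob else "colon"
                events.append((t, loc))
    return sorted(events)


# ---------------------------------------------------------------------------
# adenoma growth (component 2)
# ---------------------------------------------------------------------------

def frechet_cdf(t: float, shape: float, scale: float) -> float:
    """Frechet CDF ``exp(-(t/scale)^(-shape))`` for t >= 0."""
    if shape <= 0 or scale <= 0:
        raise ValueError("Frechet shape and scale must be positive")
    if t < 0:
        raise ValueError("t must be >= 0")
    if t == 0:
        return 0.0
    return math.exp(-((t / scale) ** (-shape)))


def sample_t10mm(
    location: Location, params: NaturalHistoryParams, rng: np.random.Generator
) -> float:
    """Time to reach 10 mm, drawn by inverting the Frechet CDF."""
    if location == "colon":
        shape, scale = params.beta1_colon, params.beta2_colon
    elif location == "rectum":
        shape, scale = params.beta1_rectum, params.beta2_rectum
    else:
        raise ValueError(f"unknown location {location!r}")
    if shape <= 0 or scale <= 0:
        raise ValueError("Frechet shape and scale must be positive")
    u = rng.random()
    # F^-1(u) = scale * (-ln u)^(-1/shape); u=0 maps to 0 (never in practice)
    return scale * (-math.log(u)) ** (-1.0 / shape) if u > 0 else 0.0


def richards_diameter(
    t: float, growth_rate: float, params: NaturalHistoryParams
) -> float:
    """Adenoma diameter (mm) at time ``t`` after initiation.

    Richards curve from ``d0`` at t=0 to ``d_infinity`` asymptotically,
    with shape ``p_growth`` controlling the sigmoid.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    p = params.p_growth
    base = (params.d0 / params.d_infinity) ** (1.0 / p) - 1.0
    return params.d_infinity * (1.0 + base * math.exp(-growth_rate * t)) ** p


def solve_growth_rate(t_10mm: float, params: NaturalHistoryParams) -> float:
    """Rate constant making the growth curve hit 10 mm at ``t_10mm``."""
    if t_10mm <= 0:
        raise ValueError("t_10mm must be positive")
    if params.d0 >= 10.0 or params.d_infinity <= 10.0:
        raise ValueError("need d0 < 10 mm < d_infinity to anchor the growth curve")
    p = params.p_growth
    num = (10.0 / params.d_infinity) ** (1.0 / p) - 1.0
    den = (params.d0 / params.d_infinity) ** (1.0 / p) - 1.0
    return -math.log(num / den) / t_10mm


def time_to_size(
    size: float, growth_rate: float, params: NaturalHistoryParams
) -> float:
    """Time for the growth curve to reach ``size`` mm (inf if >= d_infinity)."""
    if size <= params.d0:
        return 0.0
    if size >= params.d_infinity:
        return math.inf
    p = params.p_growth
    num = (size / params.d_infinity) ** (1.0 / p) - 1.0
    den = (params.d0 / params.d_infinity) ** (1.0 / p) - 1.0
    return -math.log(num / den) / growth_rate


# ---------------------------------------------------------------------------
# transition to preclinical cancer (component 3)
# ---------------------------------------------------------------------------

def transition_size_mean_log(
    female: int, rectum: int, init_age: float, params: NaturalHistoryParams
) -> float:
    """Mean of log size-at-transition; age enters in decades centred at 50."""
    age_c = (init_age - 50.0) / 10.0
    return (
        params.gamma0
        + params.gamma1 * female
        + params.gamma2 * rectum
        + params.gamma3 * female * rectum
        + params.gamma4 * age_c
        + params.gamma5 * age_c**2
    )


def sample_transition_size(
    female: int,
    rectum: int,
    init_age: float,
    params: NaturalHistoryParams,
    rng: np.random.Generator,
) -> float:
    """Lesion size (mm) at which this adenoma would turn malignant."""
    mu = transition_size_mean_log(female, rectum, init_age, params)
    return math.exp(rng.normal(mu, params.sigma_gamma))


# ---------------------------------------------------------------------------
# sojourn time (component 4)
# ---------------------------------------------------------------------------

def sojourn_scale(location: Location, params: NaturalHistoryParams) -> float:
    if location == "colon":
        return params.lambda1
    if location == "rectum":
        return params.lambda1 * math.exp(params.lambda3)
    raise ValueError(f"unknown location {location!r}")


def sojourn_survival(t: float, location: Location, params: NaturalHistoryParams) -> float:
    """Weibull survival function of sojourn time at the given site."""
    if t < 0:
        raise ValueError("t must be >= 0")
    return math.exp(-((t / sojourn_scale(location, params)) ** params.lambda2))


def sample_sojourn_time(
    location: Location, params: NaturalHistoryParams, rng: np.random.Generator
) -> float:
    """Preclinical-to-clinical interval (years) for one cancer."""
    return sojourn_scale(location, params) * rng.weibull(params.lambda2)


def mean_sojourn_time(params: NaturalHistoryParams, location: Location) -> float:
    """Closed-form mean sojourn time: ``scale * Gamma(1 + 1/shape)``."""
    return sojourn_scale(location, params) * float(gamma_fn(1.0 + 1.0 / params.lambda2))


# ---------------------------------------------------------------------------
# whole-agent simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Adenoma:
    """One lesion's full trajectory."""

    init_age: float
    location: Location
    t_10mm: float
    growth_rate: float
    transition_size: float
    transition_age: float | None
    sojourn_time: float | None
    clinical_age: float | None

    def diameter_at(self, age: float, params: NaturalHistoryParams) -> float:
        """Diameter (mm) at attained age ``age`` (0 before initiation)."""
        if age < self.init_age:
            return 0.0
        return richards_diameter(age - self.init_age, self.growth_rate, params)


@dataclass(frozen=True)
class AgentSpec:
    """Inputs defining one simulated person."""

    id: int
    female: int
    birth_year: int = 0


@dataclass(frozen=True)
class AgentHistory:
    """One agent's simulated event history."""

    spec: AgentSpec
    alpha0: float
    death_age_other_cause: float
    adenomas: tuple[Adenoma, ...]

    @property
    def clinical_crc_age(self) -> float | None:
        """Age at first clinically detected cancer, censored by other-cause death."""
        ages = [
            a.clinical_age
            for a in self.adenomas
            if a.clinical_age is not None and a.clinical_age < self.death_age_other_cause
        ]
        return min(ages) if ages else None


def agent_rng(master_seed: int, agent_id: int) -> np.random.Generator:
    """Per-agent generator: seeded by ``SeedSequence([master_seed, agent_id])``.

    Single-agent histories are therefore reproducible independent of
    batch order or partitioning.
    """
    return np.random.default_rng(np.random.SeedSequence([master_seed, agent_id]))


def simulate_agent(
    spec: AgentSpec,
    params: NaturalHistoryParams,
    horizon: float = DEFAULT_HORIZON,
    rng: np.random.Generator | None = None,
    *,
    life_table: LifeTable | None = None,
    rectum_prob: float = DEFAULT_RECTUM_PROB,
    master_seed: int | None = None,
) -> AgentHistory:
    """Simulate one agent's complete natural history up to ``horizon``.

    Pass either ``rng`` or ``master_seed`` (the latter engages the
    per-agent seeding rule).
    """
    if horizon > DEFAULT_HORIZON:
        raise ValueError(f"horizon must be <= {DEFAULT_HORIZON}")
    if rng is None:
        if master_seed is None:
            raise ValueError("provide rng or master_seed")
        rng = agent_rng(master_seed, spec.id)
    life_table = life_table or LifeTable()

    alpha0 = rng.normal(params.A, params.sigma_alpha)
    death_age = float(life_table.sample_death_age(1, rng)[0])
    death_age = min(death_age, horizon)

    adenomas = []
    for init_age, loc in sample_adenoma_initiations(
        spec.female, alpha0, params, horizon, rng, rectum_prob
    ):
        t10 = sample_t10mm(loc, params, rng)
        rate = solve_growth_rate(t10, params)
        tsize = sample_transition_size(
            spec.female, int(loc == "rectum"), init_age, params, rng
        )
        dt = time_to_size(tsize, rate, params)
        transition_age = init_age + dt if init_age + dt <= horizon else None
        sojourn = clinical = None
        if transition_age is not None:
            sojourn = sample_sojourn_time(loc, params, rng)
            clinical = transition_age + sojourn
        adenomas.append(
            Adenoma(init_age, loc, t10, rate, tsize, transition_age, sojourn, clinical)
        )
    return AgentHistory(spec, alpha0, death_age, tuple(adenomas))


def history_frame(histories: Sequence[AgentHistory]) -> "pd.DataFrame":
    """Tidy event table (agent id, event, age, location, size) for debugging."""
    import pandas as pd

    rows = []
    for h in histories:
        rows.append((h.spec.id, "death_other_cause", h.death_age_other_cause, "", np.nan))
        for a in h.adenomas:
            rows.append((h.spec.id, "adenoma_init", a.init_age, a.location, 1.0))
            if a.transition_age is not None:
                rows.append(
                    (h.spec.id, "preclinical_onset", a.transition_age, a.location,
                     a.transition_size)
                )
            if a.clinical_age is not None:
                rows.append(
                    (h.spec.id, "clinical_crc", a.clinical_age, a.location, np.nan)
                )
    return pd.DataFrame(rows, columns=["agent_id", "event", "age", "location", "size"])
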