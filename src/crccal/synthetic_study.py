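"""Synthetic calibration scenarios with a known ground truth.

No external registry or trial data ship with the package.  Instead a
scenario fixes a ground-truth parameter vector, simulates the model at
that truth to produce "observed" calibration targets with realistic
binomial sampling noise at stated sample sizes, and packages priors,
study populations and accept bands in the same structure a real
calibration would use:

* an original target set ``y`` spanning the usual target kinds —
  registry incidence by sex, colonoscopy adenoma prevalence by sex,
  detected-size-bin percentages, preclinical cancers per 1,000 large
  lesions, and one *imprecise* overall screen-detection rate (a small
  study of 1,994 people);
* a new target set ``z`` of two precise sex-specific screen-detection
  rates from a large sigmoidoscopy trial (20,519 men and 20,155
  women), whose final bands sit inside the imprecise y-target's band.

The toy calibration frees the three sojourn-time parameters
(lambda1, lambda2, lambda3) and fixes everything else at truth, so the
full engine loop runs in minutes on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .config import RunConfig
from .imabc import CalibrationState, Simulator, run_calibration, warm_start_recalibration
from .lifetable import LifeTable
from .params import NaturalHistoryParams
from .posterior_compare import PosteriorSample, compare_parameters
from .priors import MarginalPrior, PriorSpec
from .targets import (
    StudySpec,
    Target,
    ToleranceInterval,
    check_mc_precision,
    detected_lesion_summaries,
    incidence_rate,
    screen_detection_rates,
    tolerance_intervals,
    write_study_specs_yaml,
    write_targets_csv,
)
from .population import simulate_population

#: Ground truth: sojourn parameters near full-scale recalibrated means,
#: remaining components at values giving realistic adenoma prevalence
#: (~30-40% at colonoscopy ages) and clinical incidence.
DEFAULT_TRUTH = NaturalHistoryParams(
    A=-6.2,
    sigma_alpha=1.1,
    alpha1=-0.35,
    alpha20=0.05,
    alpha50=0.02,
    alpha60=0.01,
    alpha70=0.005,
    beta1_colon=2.5,
    beta2_colon=13.0,
    beta1_rectum=2.5,
    beta2_rectum=11.0,
    p_growth=1.0,
    gamma0=3.5,
    gamma1=0.15,
    gamma2=-0.1,
    gamma3=0.02,
    gamma4=-0.1,
    gamma5=0.02,
    sigma_gamma=0.6,
    lambda1=3.77,
    lambda2=2.38,
    lambda3=0.87,
)

FREE_PARAMS: tuple[str, ...] = ("lambda1", "lambda2", "lambda3")

DEFAULT_PRIOR = PriorSpec(
    (
        ("lambda1", MarginalPrior("uniform", 0.5, 8.0)),
        ("lambda2", MarginalPrior("truncnorm", 0.5, 6.0, mu=2.5, sd=1.5)),
        ("lambda3", MarginalPrior("truncnorm", -2.0, 2.0, mu=0.0, sd=1.0)),
    )
)

#: Sample sizes of the synthetic "published studies" behind each target.
TARGET_SAMPLE_SIZES = {
    "incidence_male": 20000.0,
    "incidence_female": 20000.0,
    "prev_male": 1500.0,
    "prev_female": 1500.0,
    "size_le5_pct": 800.0,
    "size_ge10_pct": 800.0,
    "cancers_per_1000_ge10": 400.0,
    "screen_overall": 1994.0,   # the small, imprecise screening study
    "screen_male": 20519.0,     # large sigmoidoscopy trial, men
    "screen_female": 20155.0,   # large sigmoidoscopy trial, women
}

_TARGET_SCALES = {
    "incidence_male": 1e5,
    "incidence_female": 1e5,
    "prev_male": 1.0,
    "prev_female": 1.0,
    "size_le5_pct": 100.0,
    "size_ge10_pct": 100.0,
    "cancers_per_1000_ge10": 1000.0,
    "screen_overall": 1.0,
    "screen_male": 1.0,
    "screen_female": 1.0,
}

_STUDY_OF_TARGET = {
    "incidence_male": "registry",
    "incidence_female": "registry",
    "prev_male": "colonoscopy_study",
    "prev_female": "colonoscopy_study",
    "size_le5_pct": "colonoscopy_study",
    "size_ge10_pct": "colonoscopy_study",
    "cancers_per_1000_ge10": "colonoscopy_study",
    "screen_overall": "sigmoidoscopy_trial",
    "screen_male": "sigmoidoscopy_trial",
    "screen_female": "sigmoidoscopy_trial",
}

INCIDENCE_BAND = (55.0, 80.0)


def default_study_specs(
    n_agents: int = 2000, n_agents_trial: int = 10000
) -> dict[str, StudySpec]:
    """Study populations backing the synthetic targets.

    The sigmoidoscopy trial is simulated with more agents than the
    other studies because its screen-detection targets carry by far the
    narrowest tolerance bands (trial sample sizes above 20,000): each
    target's study must be simulated precisely enough that Monte Carlo
    noise does not swamp its accept band (the same precision rule the
    engine's MC-error check enforces).
    """
    return {
        "registry": StudySpec(
            id="registry", n_agents=n_agents, age_range=(20.0, 100.0), test="none",
            horizon=INCIDENCE_BAND[1] + 1.0,
        ),
        "colonoscopy_study": StudySpec(
            id="colonoscopy_study", n_agents=n_agents, age_range=(50.0, 75.0),
            test="colonoscopy", horizon=75.0,
        ),
        "sigmoidoscopy_trial": StudySpec(
            id="sigmoidoscopy_trial", n_agents=n_agents_trial, age_range=(55.0, 64.0),
            test="sigmoidoscopy", horizon=64.0,
        ),
    }


@dataclass(frozen=True)
class Scenario:
    """A complete synthetic calibration problem."""

    truth: NaturalHistoryParams
    free_params: tuple[str, ...]
    prior: PriorSpec
    study_specs: dict[str, StudySpec]
    targets_y: tuple[Target, ...]
    targets_z: tuple[Target, ...]
    master_seed: int
    life_table: LifeTable = field(default_factory=LifeTable)

    def make_simulator(self, backend: str = "numba") -> Simulator:
        return make_simulator(
            self.truth, self.free_params, self.study_specs, self.life_table, backend
        )

    def all_targets(self) -> tuple[Target, ...]:
        return self.targets_y + self.targets_z


# ---------------------------------------------------------------------------
# the simulator: theta -> simulated target statistics
# ---------------------------------------------------------------------------

def simulate_target_statistics(
    params: NaturalHistoryParams,
    study_specs: Mapping[str, StudySpec],
    seed: int,
    life_table: LifeTable | None = None,
    backend: str = "numpy",
) -> dict[str, float]:
    """All target statistics for one parameter set.

    One population per study spec, each on its own seeded substream so
    the result depends only on (params, seed, backend).  The "numba"
    backend runs compiled kernels an order of magnitude faster with an
    independent random stream; both sample the same model.
    """
    if backend == "numba":
        return _simulate_target_statistics_fast(params, study_specs, seed, life_table)
    if backend != "numpy":
        raise ValueError(f"unknown backend {backend!r}")
    life_table = life_table or LifeTable()
    out: dict[str, float] = {}

    reg = study_specs["registry"]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    pop = simulate_population(
        params, reg.n_agents, rng, female=reg.fraction_female,
        life_table=life_table, horizon=reg.horizon,
    )
    out["incidence_male"] = incidence_rate(pop, INCIDENCE_BAND, "male")
    out["incidence_female"] = incidence_rate(pop, INCIDENCE_BAND, "female")

    col = study_specs["colonoscopy_study"]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 12]))
    pop = simulate_population(
        params, col.n_agents, rng, female=col.fraction_female,
        life_table=life_table, horizon=col.horizon,
    )
    screen_age = rng.uniform(*col.age_range, size=col.n_agents)
    summ = detected_lesion_summaries(pop, screen_age, col.sensitivity_model(), rng)
    out["prev_male"] = summ["prevalence"]["male"]
    out["prev_female"] = summ["prevalence"]["female"]
    out["size_le5_pct"] = summ["size_pct"]["le5"]
    out["size_ge10_pct"] = summ["size_pct"]["ge10"]
    out["cancers_per_1000_ge10"] = summ["cancers_per_1000"]["ge10"]

    sig = study_specs["sigmoidoscopy_trial"]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 13]))
    pop = simulate_population(
        params, sig.n_agents, rng, female=sig.fraction_female,
        life_table=life_table, horizon=sig.horizon,
    )
    screen_age = rng.uniform(*sig.age_range, size=sig.n_agents)
    rates = screen_detection_rates(pop, screen_age, sig.sensitivity_model(), rng)
    out["screen_male"] = rates["male"]
    out["screen_female"] = rates["female"]
    out["screen_overall"] = rates["overall"]
    return out


def _fast_inputs(params, life_table):
    from .params import CALIBRATED_NAMES

    P = np.array(
        [getattr(params, n) for n in CALIBRATED_NAMES] + [params.d0, params.d_infinity]
    )
    lt_b = np.asarray(life_table.breaks, dtype=float)
    lt_h = np.asarray(life_table.hazards, dtype=float)
    return P, lt_b, lt_h


def _fast_stage_cheap(
    params: NaturalHistoryParams,
    study_specs: Mapping[str, StudySpec],
    seed: int,
    life_table: LifeTable,
) -> dict[str, float]:
    """Registry and colonoscopy-study statistics via compiled kernels."""
    from . import _fastsim
    from .screening import colonoscopy_model

    P, lt_b, lt_h = _fast_inputs(params, life_table)
    out: dict[str, float] = {}

    reg = study_specs["registry"]
    seed_reg = int(np.random.SeedSequence([seed, 11]).generate_state(1)[0])
    n_f = int(round(reg.fraction_female * reg.n_agents))
    ev_m, el_m, ev_f, el_f = _fastsim.registry_incidence(
        P, reg.n_agents, n_f, reg.horizon, lt_b, lt_h, life_table.max_age,
        0.25, INCIDENCE_BAND[0], INCIDENCE_BAND[1], seed_reg,
    )
    out["incidence_male"] = ev_m / el_m * 1e5 if el_m else np.nan
    out["incidence_female"] = ev_f / el_f * 1e5 if el_f else np.nan

    col = study_specs["colonoscopy_study"]
    cm = colonoscopy_model()
    ax = np.array([a[0] for a in cm.anchors])
    ay = np.array([a[1] for a in cm.anchors])
    seed_col = int(np.random.SeedSequence([seed, 12]).generate_state(1)[0])
    n_f = int(round(col.fraction_female * col.n_agents))
    t = _fastsim.screened_cohort(
        P, col.n_agents, n_f, col.horizon, lt_b, lt_h, life_table.max_age,
        0.25, col.age_range[0], col.age_range[1],
        ax, ay, cm.preclinical_floor, 1.0, 1.0, 5.5, 9.5, seed_col,
    )
    out["prev_male"] = t[2] / t[0] if t[0] else np.nan
    out["prev_female"] = t[3] / t[1] if t[1] else np.nan
    n_aden = t[6] + t[7] + t[8]
    out["size_le5_pct"] = 100.0 * t[6] / n_aden if n_aden else np.nan
    out["size_ge10_pct"] = 100.0 * t[8] / n_aden if n_aden else np.nan
    out["cancers_per_1000_ge10"] = 1000.0 * t[14] / t[11] if t[11] else np.nan
    return out


def _fast_stage_trial(
    params: NaturalHistoryParams,
    study_specs: Mapping[str, StudySpec],
    seed: int,
    life_table: LifeTable,
) -> dict[str, float]:
    """Sigmoidoscopy-trial screen-detection statistics via compiled kernels."""
    from . import _fastsim
    from .screening import colonoscopy_model, sigmoidoscopy_model

    P, lt_b, lt_h = _fast_inputs(params, life_table)
    cm = colonoscopy_model()
    ax = np.array([a[0] for a in cm.anchors])
    ay = np.array([a[1] for a in cm.anchors])
    sig = study_specs["sigmoidoscopy_trial"]
    sm = sigmoidoscopy_model()
    seed_sig = int(np.random.SeedSequence([seed, 13]).generate_state(1)[0])
    n_f = int(round(sig.fraction_female * sig.n_agents))
    t = _fastsim.screened_cohort(
        P, sig.n_agents, n_f, sig.horizon, lt_b, lt_h, life_table.max_age,
        0.25, sig.age_range[0], sig.age_range[1],
        ax, ay, sm.preclinical_floor, sm.colon_reach, sm.rectum_reach,
        5.5, 9.5, seed_sig,
    )
    out: dict[str, float] = {}
    out["screen_male"] = t[4] / t[0] if t[0] else np.nan
    out["screen_female"] = t[5] / t[1] if t[1] else np.nan
    out["screen_overall"] = (t[4] + t[5]) / (t[0] + t[1]) if t[0] + t[1] else np.nan
    return out


def _simulate_target_statistics_fast(
    params: NaturalHistoryParams,
    study_specs: Mapping[str, StudySpec],
    seed: int,
    life_table: LifeTable | None = None,
) -> dict[str, float]:
    """Compiled-kernel version of :func:`simulate_target_statistics`."""
    life_table = life_table or LifeTable()
    out = _fast_stage_cheap(params, study_specs, seed, life_table)
    out.update(_fast_stage_trial(params, study_specs, seed, life_table))
    return out


def make_simulator(
    truth: NaturalHistoryParams,
    free_params: Sequence[str],
    study_specs: Mapping[str, StudySpec],
    life_table: LifeTable | None = None,
    backend: str = "numba",
) -> Simulator:
    """Simulator over the free-parameter vector, all else fixed at truth.

    The numba backend also exposes ``stages`` — the cheap registry and
    colonoscopy statistics first, the large sigmoidoscopy trial second
    — so the engine can veto a draw before paying for the trial.
    """
    free = tuple(free_params)
    lt = life_table or LifeTable()

    def _params(theta: np.ndarray) -> NaturalHistoryParams:
        return truth.with_updates(dict(zip(free, np.asarray(theta, dtype=float))))

    def simulator(theta: np.ndarray, seed: int) -> dict[str, float]:
        return simulate_target_statistics(_params(theta), study_specs, seed, lt, backend)

    if backend == "numba":
        def stage_cheap(theta: np.ndarray, seed: int) -> dict[str, float]:
            return _fast_stage_cheap(_params(theta), study_specs, seed, lt)

        def stage_trial(theta: np.ndarray, seed: int) -> dict[str, float]:
            return _fast_stage_trial(_params(theta), study_specs, seed, lt)

        simulator.stages = [
            (stage_cheap, ("incidence_male", "incidence_female", "prev_male",
                           "prev_female", "size_le5_pct", "size_ge10_pct",
                           "cancers_per_1000_ge10")),
            (stage_trial, ("screen_male", "screen_female", "screen_overall")),
        ]
    return simulator


# ---------------------------------------------------------------------------
# scenario construction
# ---------------------------------------------------------------------------

def make_default_scenario(
    seed: int,
    n_agents: int = 2000,
    n_agents_trial: int = 10000,
    truth: NaturalHistoryParams = DEFAULT_TRUTH,
    prior: PriorSpec = DEFAULT_PRIOR,
    observed_n_factor: int = 10,
    inflation: float = 10.0,
) -> Scenario:
    """Build the default three-free-parameter scenario, deterministically.

    "Observed" target values are the model's own statistics at the
    ground truth, computed on populations ``observed_n_factor`` times
    larger than the per-draw study populations, then perturbed by
    binomial sampling noise at each target's stated sample size.
    """
    specs = default_study_specs(n_agents, n_agents_trial)
    big_specs = default_study_specs(
        n_agents * observed_n_factor, n_agents_trial * observed_n_factor
    )
    life_table = LifeTable()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    true_stats = simulate_target_statistics(truth, big_specs, seed=int(rng.integers(2**31)),
                                            life_table=life_table)

    targets_y, targets_z = [], []
    for name, n in TARGET_SAMPLE_SIZES.items():
        scale = _TARGET_SCALES[name]
        p_true = min(max(true_stats[name] / scale, 0.0), 1.0)
        observed = rng.binomial(int(n), p_true) / int(n) * scale
        initial, final = tolerance_intervals(
            observed, n, inflation=inflation, scale=scale
        )
        if name == "screen_overall":
            # the small screening study is the *imprecise* target: its
            # tolerance band is deliberately much wider than its Wilson
            # interval, so the precise trial bands nest strictly inside it
            final = ToleranceInterval(
                max(observed - 3.0 * (observed - final.lower), 0.0),
                min(observed + 3.0 * (final.upper - observed), scale),
            )
        t = Target(
            name=name,
            observed_value=observed,
            sample_size=n,
            initial_interval=initial,
            final_interval=final,
            study_spec_id=_STUDY_OF_TARGET[name],
            scale=scale,
        )
        check_mc_precision(t, specs[_STUDY_OF_TARGET[name]].n_agents, mode="warn")
        (targets_z if name in ("screen_male", "screen_female") else targets_y).append(t)

    return Scenario(
        truth=truth,
        free_params=FREE_PARAMS,
        prior=prior,
        study_specs=specs,
        targets_y=tuple(targets_y),
        targets_z=tuple(targets_z),
        master_seed=seed,
        life_table=life_table,
    )


def generate_observed_targets(scenario: Scenario, out_dir: str | Path) -> dict[str, Path]:
    """Write the scenario's fixture files (prior, study specs, targets, truth)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "prior": out / "prior.yaml",
        "study_specs": out / "study_specs.yaml",
        "targets_y": out / "targets_y.csv",
        "targets_z": out / "targets_z.csv",
        "truth": out / "truth.yaml",
    }
    scenario.prior.to_yaml(paths["prior"])
    write_study_specs_yaml(list(scenario.study_specs.values()), paths["study_specs"])
    write_targets_csv(scenario.targets_y, paths["targets_y"])
    write_targets_csv(scenario.targets_z, paths["targets_z"])
    scenario.truth.to_yaml(paths["truth"])
    return paths


# ---------------------------------------------------------------------------
# the two-arm recalibration experiment
# ---------------------------------------------------------------------------

def posterior_from_state(state: CalibrationState, label: str = "") -> PosteriorSample:
    """Weighted posterior sample over the free parameters."""
    thetas = state.thetas_array()
    values = {n: thetas[:, j] for j, n in enumerate(state.param_names)}
    return PosteriorSample(values, state.weights_array(), label)


@dataclass(frozen=True)
class TwoArmReport:
    """Outcome of the sequential-vs-scratch comparison."""

    state_orig: CalibrationState      # calibrated to y only
    state_seq: CalibrationState       # warm-started with z
    state_scratch: CalibrationState   # calibrated to {y, z} from the prior
    comparison: pd.DataFrame          # seq vs scratch, four metrics per parameter
    seq_post_restart_calls: int
    scratch_total_calls: int

    @property
    def all_converged(self) -> bool:
        return self.state_seq.converged and self.state_scratch.converged


def run_two_arm_experiment(
    scenario: Scenario,
    config: RunConfig,
    seed: int | None = None,
) -> TwoArmReport:
    """Calibrate to y then warm-start with z (arm 1); calibrate to the
    combined set from scratch (arm 2); compare the two posteriors."""
    seed = scenario.master_seed if seed is None else seed
    simulator = scenario.make_simulator()

    state_orig = run_calibration(
        scenario.prior, scenario.targets_y, simulator, config, seed=seed
    )
    calls_before = state_orig.n_sim_calls
    import copy

    state_seq = warm_start_recalibration(
        copy.deepcopy(state_orig), scenario.targets_z, simulator
    )
    seq_post_restart = state_seq.n_sim_calls - calls_before

    state_scratch = run_calibration(
        scenario.prior, scenario.all_targets(), simulator, config, seed=seed + 1
    )

    post_seq = posterior_from_state(state_seq, "seq")
    post_scratch = posterior_from_state(state_scratch, "scratch")
    comparison = compare_parameters(post_seq, post_scratch)
    return TwoArmReport(
        state_orig=state_orig,
        state_seq=state_seq,
        state_scratch=state_scratch,
        comparison=comparison,
        seq_post_restart_calls=seq_post_restart,
        scratch_total_calls=state_scratch.n_sim_calls,
    )
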