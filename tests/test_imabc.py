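"""Engine unit tests on cheap toy simulators."""

from __future__ import annotations

import copy
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from crccal.config import RunConfig
from crccal.imabc import (
    add_mixture_components,
    importance_weights,
    init_from_prior,
    load_state,
    run_calibration,
    save_state,
    shrink_intervals,
    warm_start_recalibration,
)
from crccal.priors import MarginalPrior, PriorSpec
from crccal.targets import Target, ToleranceInterval, tolerance_intervals


def identity_simulator(theta, seed):
    return {"x": float(theta[0])}


def quadratic_simulator(theta, seed):
    rng = np.random.default_rng(seed)
    return {
        "ss": float(theta[0] ** 2 + theta[1] ** 2 + rng.normal(0, 0.02)),
        "diff": float(theta[0] - theta[1] + rng.normal(0, 0.02)),
    }


def uniform_prior(lo=0.0, hi=1.0, name="x"):
    return PriorSpec(((name, MarginalPrior("uniform", lo, hi)),))


def target(name, lo, hi, init_lo=None, init_hi=None):
    init_lo = lo if init_lo is None else init_lo
    init_hi = hi if init_hi is None else init_hi
    mid = 0.5 * (lo + hi)
    return Target(
        name, mid, 100.0,
        ToleranceInterval(init_lo, init_hi),
        ToleranceInterval(lo, hi),
        "toy",
    )


TOY_CONFIG = RunConfig(
    n_init=200, n_centers=3, batch_per_component=40, target_ess=50.0,
    max_iterations=30, min_draws_retained=20,
)


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def test_vacuous_intervals_accept_everything():
    t = target("x", -1e30, 1e30)
    state = init_from_prior(uniform_prior(), [t], 300, identity_simulator, seed=1)
    assert len(state.draws) == 300
    assert state.ess() == pytest.approx(300.0)


def test_impossible_intervals_raise():
    t = target("x", 5.0, 6.0)  # outside the uniform(0,1) image
    with pytest.raises(RuntimeError):
        init_from_prior(uniform_prior(), [t], 200, identity_simulator, seed=1)


def test_prior_acceptance_fraction_matches_interval_mass():
    """Uniform(0,1) prior with accept band (0.4, 0.6): about 20% of draws
    survive."""
    t = target("x", 0.4, 0.6)
    n = 10**4
    state = init_from_prior(uniform_prior(), [t], n, identity_simulator, seed=3)
    frac = len(state.draws) / n
    se = math.sqrt(0.2 * 0.8 / n)
    assert frac == pytest.approx(0.2, abs=3 * se)


# ---------------------------------------------------------------------------
# weights
# ---------------------------------------------------------------------------

def test_prior_proposal_gives_uniform_weights():
    t = target("x", 0.3, 0.7)
    state = init_from_prior(uniform_prior(), [t], 500, identity_simulator, seed=4)
    w = importance_weights(state)
    assert np.allclose(w, 1.0 / len(w))


def test_draw_outside_interval_gets_zero_weight():
    t = target("x", 0.3, 0.7, init_lo=0.0, init_hi=1.0)
    state = init_from_prior(uniform_prior(), [t], 400, identity_simulator, seed=5)
    band = state.bands["x"]
    band.current = band.final
    state.draws[0].simulated["x"] = 0.9  # straggler now outside the band
    w = importance_weights(state)
    assert w[0] == 0.0
    assert w[1:].sum() == pytest.approx(1.0)


def test_weight_normalization_arithmetic():
    """Two in-band draws with prior/q ratios 2:1 get weights (2/3, 1/3)."""
    t = target("x", 0.0, 1.0)
    state = init_from_prior(uniform_prior(), [t], 2, identity_simulator, seed=6)
    state.draws[0].log_prior = math.log(2.0)
    state.draws[1].log_prior = math.log(1.0)
    state.draws[0].log_proposal = state.draws[1].log_proposal = 0.0
    raw = [math.exp(d.log_prior - d.log_proposal) for d in state.draws]
    w = np.array(raw) / sum(raw)
    assert w == pytest.approx([2 / 3, 1 / 3])


# ---------------------------------------------------------------------------
# mixture components
# ---------------------------------------------------------------------------

def test_component_centers_are_accepted_draw_locations():
    t = target("x", 0.2, 0.8)
    state = init_from_prior(uniform_prior(), [t], 300, identity_simulator, seed=7)
    add_mixture_components(state, 3, np.random.default_rng(1))
    locations = {float(d.theta[0]) for d in state.draws}
    for c in state.components:
        assert float(c.center[0]) in locations


def test_single_draw_component_centered_exactly():
    t = target("x", 0.0, 1.0)
    state = init_from_prior(uniform_prior(), [t], 1, identity_simulator, seed=8)
    add_mixture_components(state, 1, np.random.default_rng(1))
    assert state.components[0].center[0] == state.draws[0].theta[0]


def test_proposal_density_higher_at_center_than_far_away():
    prior = PriorSpec(
        (
            ("a", MarginalPrior("uniform", -10.0, 10.0)),
            ("b", MarginalPrior("uniform", -10.0, 10.0)),
        )
    )
    t = target("ss", 0.0, 3.0, init_lo=0.0, init_hi=250.0)
    state = init_from_prior(prior, [t], 400, quadratic_simulator, seed=9)
    add_mixture_components(state, 2, np.random.default_rng(1))
    center = state.components[0].center
    far = np.array([[9.9, -9.9]])
    dens_center = state._log_current_mixture(center[None, :])[0]
    dens_far = state._log_current_mixture(far)[0]
    assert dens_center >= dens_far


# ---------------------------------------------------------------------------
# interval shrinking
# ---------------------------------------------------------------------------

def test_shrink_is_fixed_point_at_final():
    t = target("x", 0.4, 0.6)
    state = init_from_prior(uniform_prior(), [t], 2000, identity_simulator, seed=10)
    before = state.bands["x"].current
    shrink_intervals(state)
    assert state.bands["x"].current == before  # initial == final here


def test_shrink_step_one_jumps_to_final():
    t = target("x", 0.4, 0.6, init_lo=0.0, init_hi=1.0)
    cfg = RunConfig(shrink_factor=1.0, min_draws_retained=10)
    state = init_from_prior(uniform_prior(), [t], 2000, identity_simulator, seed=11,
                            config=cfg)
    shrink_intervals(state)
    band = state.bands["x"]
    assert band.at_final()
    assert all(0.4 <= d.simulated["x"] <= 0.6 for d in state.draws)


def test_shrink_skips_when_too_few_draws_would_survive():
    t = target("x", 0.495, 0.505, init_lo=0.0, init_hi=1.0)
    cfg = RunConfig(shrink_factor=1.0, min_draws_retained=50)
    state = init_from_prior(uniform_prior(), [t], 300, identity_simulator, seed=12,
                            config=cfg)
    shrink_intervals(state)
    assert not state.bands["x"].at_final()  # the jump would keep ~3 draws
    assert len(state.draws) >= 50


def test_acceptance_invariant_after_shrink(rng):
    t = target("x", 0.3, 0.5, init_lo=0.0, init_hi=1.0)
    state = init_from_prior(uniform_prior(), [t], 1500, identity_simulator, seed=13)
    for _ in range(6):
        shrink_intervals(state)
        cur = state.bands["x"].current
        assert all(cur.contains(d.simulated["x"]) for d in state.draws)


# ---------------------------------------------------------------------------
# ESS identities
# ---------------------------------------------------------------------------

@given(st.integers(2, 200))
def test_equal_weights_ess_equals_n(n):
    w = np.full(n, 1.0 / n)
    assert (w.sum() ** 2 / (w**2).sum()) == pytest.approx(n)


@given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=50))
def test_ess_bounded_between_one_and_n(ws):
    w = np.array(ws)
    ess = w.sum() ** 2 / (w**2).sum()
    assert 1.0 - 1e-9 <= ess <= len(w) + 1e-9


def test_dominant_weight_drives_ess_to_one():
    w = np.array([1.0] + [1e-12] * 99)
    assert w.sum() ** 2 / (w**2).sum() == pytest.approx(1.0, abs=1e-6)


# ---------------------------------------------------------------------------
# the full loop
# ---------------------------------------------------------------------------

def test_toy_quadratic_calibration_converges():
    prior = PriorSpec(
        (
            ("a", MarginalPrior("uniform", -3.0, 3.0)),
            ("b", MarginalPrior("uniform", -3.0, 3.0)),
        )
    )
    targets = [
        target("ss", 0.8, 1.2, init_lo=0.0, init_hi=20.0),
        target("diff", -0.2, 0.2, init_lo=-5.0, init_hi=5.0),
    ]
    state = run_calibration(prior, targets, quadratic_simulator, TOY_CONFIG, seed=21)
    assert state.converged
    assert state.ess() >= TOY_CONFIG.target_ess
    for d in state.draws:
        assert state.in_intervals(d, "final")


def test_ess_target_one_converges_immediately():
    cfg = RunConfig(n_init=50, target_ess=1.0, max_iterations=5)
    t = target("x", 0.4, 0.6)
    state = run_calibration(uniform_prior(), [t], identity_simulator, cfg, seed=22)
    assert state.converged
    assert state.iteration == 0


def test_prior_draws_sufficing_short_circuits_loop():
    cfg = RunConfig(n_init=3000, target_ess=100.0, max_iterations=5)
    t = target("x", 0.3, 0.7)
    state = run_calibration(uniform_prior(), [t], identity_simulator, cfg, seed=23)
    assert state.converged
    assert state.iteration == 0
    assert not state.components


def test_unconverged_run_is_flagged():
    cfg = RunConfig(n_init=100, target_ess=1e6, max_iterations=2)
    t = target("x", 0.4, 0.6, init_lo=0.0, init_hi=1.0)
    state = run_calibration(uniform_prior(), [t], identity_simulator, cfg, seed=24)
    assert not state.converged


# ---------------------------------------------------------------------------
# warm start
# ---------------------------------------------------------------------------

def two_param_sim(theta, seed):
    return {"x": float(theta[0]), "y": float(theta[0] ** 2)}


def test_warm_start_with_vacuous_new_target_keeps_draws():
    cfg = RunConfig(n_init=800, target_ess=100.0, max_iterations=10)
    t = target("x", 0.3, 0.7)
    state = run_calibration(uniform_prior(), [t], two_param_sim, cfg, seed=25)
    thetas_before = state.thetas_array().copy()
    z = [target("y", -1e30, 1e30)]
    out = warm_start_recalibration(copy.deepcopy(state), z, two_param_sim)
    assert out.converged
    assert np.array_equal(out.thetas_array(), thetas_before)
    assert all("y" in d.simulated for d in out.draws)


def test_warm_start_rejects_duplicate_target_names():
    cfg = RunConfig(n_init=300, target_ess=30.0, max_iterations=5)
    t = target("x", 0.3, 0.7)
    state = run_calibration(uniform_prior(), [t], two_param_sim, cfg, seed=26)
    with pytest.raises(ValueError):
        warm_start_recalibration(state, [target("x", 0.0, 1.0)], two_param_sim)


def test_warm_start_signals_degenerate_restart():
    cfg = RunConfig(n_init=300, target_ess=30.0, max_iterations=5)
    t = target("x", 0.3, 0.7)
    state = run_calibration(uniform_prior(), [t], two_param_sim, cfg, seed=27)
    z = [target("y", 5.0, 6.0)]  # no stored draw can satisfy this
    with pytest.raises(RuntimeError):
        warm_start_recalibration(state, z, two_param_sim)


def test_seed_reuse_reproduces_stored_statistics():
    """Re-simulating a stored draw under its stored seed reproduces the
    original statistics bit-for-bit (the warm-start contract)."""
    cfg = RunConfig(n_init=300, target_ess=30.0, max_iterations=10)
    targets = [target("ss", 0.8, 1.2, init_lo=0.0, init_hi=20.0)]
    prior = PriorSpec(
        (
            ("a", MarginalPrior("uniform", -3.0, 3.0)),
            ("b", MarginalPrior("uniform", -3.0, 3.0)),
        )
    )
    state = run_calibration(prior, targets, quadratic_simulator, cfg, seed=28)
    for d in state.draws[:20]:
        again = quadratic_simulator(d.theta, d.seed)
        assert again["ss"] == d.simulated["ss"]


# ---------------------------------------------------------------------------
# state persistence
# ---------------------------------------------------------------------------

def test_state_round_trip_and_resume_equivalence(tmp_path):
    """Saving after the first calibration and resuming yields exactly the
    same warm-start result as continuing in memory."""
    cfg = RunConfig(n_init=600, target_ess=80.0, max_iterations=15)
    t = target("x", 0.3, 0.7, init_lo=0.0, init_hi=1.0)
    state = run_calibration(uniform_prior(), [t], two_param_sim, cfg, seed=29)
    path = tmp_path / "state.json"
    save_state(state, path)
    loaded = load_state(path)
    assert loaded.param_names == state.param_names
    assert loaded.master_seed == state.master_seed
    assert np.allclose(loaded.thetas_array(), state.thetas_array())
    assert np.allclose(loaded.weights_array(), state.weights_array())

    z = [target("y", 0.0, 0.6, init_lo=0.0, init_hi=1.0)]
    a = warm_start_recalibration(copy.deepcopy(state), z, two_param_sim)
    b = warm_start_recalibration(loaded, z, two_param_sim)
    assert a.converged == b.converged
    assert np.allclose(np.sort(a.thetas_array(), axis=0),
                       np.sort(b.thetas_array(), axis=0))
    assert a.n_sim_calls == b.n_sim_calls
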