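"""Unit and property tests for the natural-history components."""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats
from scipy.integrate import quad

from crccal.natural_history import (
    AgentSpec,
    adenoma_log_risk,
    frechet_cdf,
    integrated_risk,
    mean_sojourn_time,
    richards_diameter,
    sample_adenoma_initiations,
    sample_sojourn_time,
    sample_t10mm,
    sample_transition_size,
    simulate_agent,
    sojourn_survival,
    solve_growth_rate,
    time_to_size,
)


# ---------------------------------------------------------------------------
# adenoma risk (piecewise log-linear intensity)
# ---------------------------------------------------------------------------

def scalar_log_risk(age, female, alpha0, p):
    """Independent scalar transcription of the piecewise log-risk."""
    if age < 20:
        return -math.inf
    out = alpha0 + p.alpha1 * female
    out += min(age - 20, 30) * p.alpha20
    out += max(min(age - 50, 10), 0) * p.alpha50
    out += max(min(age - 60, 10), 0) * p.alpha60
    out += max(age - 70, 0) * p.alpha70
    return out


def test_log_risk_at_age_20_is_intercept_only(base_params):
    """At age 20 every age term vanishes: male risk is exp(alpha0)."""
    assert adenoma_log_risk(20.0, 0, base_params.A, base_params) == base_params.A
    assert adenoma_log_risk(20.0, 1, base_params.A, base_params) == pytest.approx(
        base_params.A + base_params.alpha1
    )


def test_log_risk_hand_computed_at_55(base_params):
    p = replace(base_params, alpha1=0.0, alpha20=0.03, alpha50=0.01,
                alpha60=0.0, alpha70=0.0)
    # -6 + 30*0.03 + 5*0.01
    assert adenoma_log_risk(55.0, 0, -6.0, p) == pytest.approx(-5.05)


@given(
    age=st.floats(0.0, 100.0),
    female=st.integers(0, 1),
    alpha0=st.floats(-8.0, -3.0),
)
def test_log_risk_matches_independent_scalar_form(age, female, alpha0, base_params):
    got = adenoma_log_risk(age, female, alpha0, base_params)
    want = scalar_log_risk(age, female, alpha0, base_params)
    if math.isinf(want):
        assert math.isinf(got)
    else:
        assert got == pytest.approx(want, abs=1e-12)


def test_zero_risk_before_age_20(base_params, rng):
    assert adenoma_log_risk(10.0, 0, -5.0, base_params) == -math.inf
    events = sample_adenoma_initiations(0, -2.0, base_params, horizon=20.0, rng=rng)
    assert events == []


def test_homogeneous_intensity_mean_event_count(base_params, rng):
    """With flat intensity 0.1/yr over 50 years the mean count is 5."""
    p = replace(base_params, alpha1=0.0, alpha20=0.0, alpha50=0.0,
                alpha60=0.0, alpha70=0.0)
    alpha0 = math.log(0.1)
    counts = [
        len(sample_adenoma_initiations(0, alpha0, p, horizon=70.0, rng=rng))
        for _ in range(2000)
    ]
    se = np.std(counts) / math.sqrt(len(counts))
    assert np.mean(counts) == pytest.approx(5.0, abs=3 * se)


def test_nhpp_count_matches_quadrature_integral(base_params, rng):
    """Empirical mean event count agrees with the numerically integrated
    intensity for a genuinely piecewise intensity."""
    alpha0 = -4.0
    expected = quad(
        lambda a: math.exp(scalar_log_risk(a, 1, alpha0, base_params)), 20, 90,
        points=[50, 60, 70],
    )[0]
    assert integrated_risk(1, alpha0, base_params, 90.0) == pytest.approx(
        expected, rel=1e-8
    )
    counts = [
        len(sample_adenoma_initiations(1, alpha0, base_params, horizon=90.0, rng=rng))
        for _ in range(2000)
    ]
    se = np.std(counts) / math.sqrt(len(counts))
    assert np.mean(counts) == pytest.approx(expected, abs=3 * se)


# ---------------------------------------------------------------------------
# growth: Frechet time-to-10mm and the Richards curve
# ---------------------------------------------------------------------------

def test_frechet_cdf_values():
    assert frechet_cdf(10.0, shape=2.0, scale=10.0) == pytest.approx(math.exp(-1))
    assert frechet_cdf(0.0, 2.0, 10.0) == 0.0
    assert frechet_cdf(1e9, 2.0, 10.0) == pytest.approx(1.0)
    # median by inversion: scale * ln(2)^(-1/shape)
    med = 10.0 * math.log(2) ** (-0.5)
    assert frechet_cdf(med, 2.0, 10.0) == pytest.approx(0.5)
    assert med == pytest.approx(12.011, abs=1e-3)


def test_frechet_cdf_rejects_bad_shape_scale():
    with pytest.raises(ValueError):
        frechet_cdf(1.0, -1.0, 2.0)
    with pytest.raises(ValueError):
        frechet_cdf(1.0, 1.0, 0.0)


def test_frechet_sampler_matches_cdf(base_params, rng):
    """KS statistic of 1e5 draws vs the analytic CDF below the 1% critical
    value."""
    draws = np.array(
        [sample_t10mm("colon", base_params, rng) for _ in range(10**5)]
    )
    d = stats.kstest(
        draws, lambda t: np.exp(-((t / base_params.beta2_colon) ** -base_params.beta1_colon))
    ).statistic
    assert d < 1.63 / math.sqrt(len(draws))  # 1% KS critical value


def test_growth_rate_closed_form(base_params):
    # p=1, d0=1, d_inf=50, t10=1: lambda = -ln(0.8/0.98)
    lam = solve_growth_rate(1.0, base_params)
    assert lam == pytest.approx(-math.log(0.8 / 0.98), abs=1e-5)
    assert lam == pytest.approx(0.20294, abs=1e-5)


def test_growth_rate_scales_inversely_with_t10mm(base_params):
    assert solve_growth_rate(4.0, base_params) == pytest.approx(
        solve_growth_rate(2.0, base_params) / 2.0
    )


@pytest.mark.parametrize("p_growth", [0.5, 1.0, 2.7])
def test_richards_endpoint_identities(base_params, p_growth):
    """d(0)=d0, d(t10)=10 with the solved rate, d(inf)=d_infinity."""
    p = replace(base_params, p_growth=p_growth)
    lam = solve_growth_rate(7.5, p)
    assert richards_diameter(0.0, lam, p) == pytest.approx(1.0, abs=1e-9)
    assert richards_diameter(7.5, lam, p) == pytest.approx(10.0, abs=1e-9)
    assert richards_diameter(1e4, lam, p) == pytest.approx(50.0, abs=1e-9)


def test_richards_diameter_strictly_increasing(base_params):
    lam = solve_growth_rate(5.0, base_params)
    t = np.linspace(0, 200, 400)
    d = np.array([richards_diameter(ti, lam, base_params) for ti in t])
    assert np.all(np.diff(d) > 0)
    assert d.min() >= base_params.d0 and d.max() < base_params.d_infinity


def test_growth_rate_rejects_degenerate_anchors(base_params):
    with pytest.raises(ValueError):
        solve_growth_rate(5.0, replace(base_params, d0=12.0, d_infinity=50.0))
    with pytest.raises(ValueError):
        solve_growth_rate(5.0, replace(base_params, d_infinity=9.0))


def test_time_to_size_inverts_diameter(base_params):
    lam = solve_growth_rate(6.0, base_params)
    t = time_to_size(25.0, lam, base_params)
    assert richards_diameter(t, lam, base_params) == pytest.approx(25.0, abs=1e-9)
    assert time_to_size(50.0, lam, base_params) == math.inf


# ---------------------------------------------------------------------------
# transition size
# ---------------------------------------------------------------------------

def test_transition_size_degenerate_lognormal(base_params, rng):
    p = replace(base_params, gamma1=0.0, gamma2=0.0, gamma3=0.0, gamma4=0.0,
                gamma5=0.0, sigma_gamma=0.0)
    s = sample_transition_size(0, 0, 50.0, p, rng)
    assert s == pytest.approx(math.exp(p.gamma0))


def test_transition_size_lognormal_mean_identity(base_params, rng):
    p = replace(base_params, gamma1=0.0, gamma2=0.0, gamma3=0.0, gamma4=0.0,
                gamma5=0.0, gamma0=2.0, sigma_gamma=0.4)
    draws = np.array([sample_transition_size(0, 0, 50.0, p, rng) for _ in range(10**5)])
    want = math.exp(2.0 + 0.4**2 / 2)
    se = draws.std() / math.sqrt(len(draws))
    assert draws.mean() == pytest.approx(want, abs=3 * se)


def test_transition_fraction_increases_with_max_diameter(base_params, rng):
    """The bigger an adenoma can grow, the likelier it is to reach its
    transition size: the transition probability rises with size."""
    lam = solve_growth_rate(5.0, base_params)
    sizes = np.array(
        [sample_transition_size(0, 0, 55.0, base_params, rng) for _ in range(4000)]
    )
    fracs = [
        np.mean(sizes <= d_max) for d_max in (5.0, 10.0, 20.0, 40.0)
    ]
    assert all(a <= b for a, b in zip(fracs, fracs[1:]))
    assert fracs[0] < fracs[-1]


# ---------------------------------------------------------------------------
# sojourn time
# ---------------------------------------------------------------------------

def test_sojourn_survival_at_scale(base_params):
    assert sojourn_survival(base_params.lambda1, "colon", base_params) == pytest.approx(
        math.exp(-1)
    )


def test_zero_location_effect_makes_sites_identical(base_params):
    p = replace(base_params, lambda3=0.0)
    assert mean_sojourn_time(p, "colon") == mean_sojourn_time(p, "rectum")
    r1 = np.random.default_rng(5)
    r2 = np.random.default_rng(5)
    a = [sample_sojourn_time("colon", p, r1) for _ in range(50)]
    b = [sample_sojourn_time("rectum", p, r2) for _ in range(50)]
    assert a == b


def test_mean_sojourn_time_closed_forms(base_params):
    # 3.77 * Gamma(1 + 1/2.38) and the rectal scale multiplier exp(0.87)
    assert mean_sojourn_time(base_params, "colon") == pytest.approx(3.342, abs=2e-3)
    assert mean_sojourn_time(base_params, "rectum") == pytest.approx(
        3.342 * math.exp(0.87), abs=2e-2
    )
    assert mean_sojourn_time(base_params, "rectum") == pytest.approx(7.98, abs=2e-2)


def test_sojourn_mc_mean_matches_closed_form(base_params, rng):
    for loc in ("colon", "rectum"):
        draws = np.array(
            [sample_sojourn_time(loc, base_params, rng) for _ in range(10**5)]
        )
        se = draws.std() / math.sqrt(len(draws))
        assert draws.mean() == pytest.approx(
            mean_sojourn_time(base_params, loc), abs=3 * se
        )


def test_sojourn_sampler_matches_weibull_cdf(base_params, rng):
    draws = np.array(
        [sample_sojourn_time("colon", base_params, rng) for _ in range(10**5)]
    )
    d = stats.kstest(
        draws, stats.weibull_min(base_params.lambda2, scale=base_params.lambda1).cdf
    ).statistic
    assert d < 1.63 / math.sqrt(len(draws))


def test_increasing_scale_stochastically_increases_sojourn(base_params):
    """Under a shared random stream, a larger Weibull scale gives pointwise
    larger draws."""
    hi = replace(base_params, lambda1=base_params.lambda1 * 1.5)
    r1, r2 = np.random.default_rng(9), np.random.default_rng(9)
    a = np.array([sample_sojourn_time("colon", base_params, r1) for _ in range(200)])
    b = np.array([sample_sojourn_time("colon", hi, r2) for _ in range(200)])
    assert np.all(b >= a)


# ---------------------------------------------------------------------------
# whole-agent simulation
# ---------------------------------------------------------------------------

def test_agent_with_zero_risk_has_no_adenomas(base_params):
    p = replace(base_params, A=-60.0, sigma_alpha=0.0)
    h = simulate_agent(AgentSpec(0, 0), p, master_seed=1)
    assert h.adenomas == ()
    assert h.clinical_crc_age is None


def test_huge_transition_size_prevents_cancer(base_params):
    p = replace(base_params, gamma0=30.0, sigma_gamma=0.0, A=-4.0)
    h = simulate_agent(AgentSpec(0, 0), p, master_seed=2)
    assert all(a.transition_age is None for a in h.adenomas)


def test_clinical_age_is_transition_plus_sojourn(base_params):
    found = 0
    for seed in range(60):
        h = simulate_agent(AgentSpec(seed, seed % 2), base_params, master_seed=3)
        for a in h.adenomas:
            if a.clinical_age is not None:
                assert a.clinical_age == pytest.approx(
                    a.transition_age + a.sojourn_time
                )
                found += 1
    assert found > 0


def test_per_agent_seeding_is_order_independent(base_params):
    """The same (master seed, agent id) gives the same history regardless of
    simulation order — the parallel-batch reproducibility contract."""
    a_then_b = [
        simulate_agent(AgentSpec(i, 0), base_params, master_seed=7) for i in (4, 9)
    ]
    b_then_a = [
        simulate_agent(AgentSpec(i, 0), base_params, master_seed=7) for i in (9, 4)
    ]
    assert a_then_b[0].adenomas == b_then_a[1].adenomas
    assert a_then_b[0].death_age_other_cause == b_then_a[1].death_age_other_cause
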