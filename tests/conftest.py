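"""Shared fixtures: small parameter sets and seeded generators."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from crccal.params import NaturalHistoryParams

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[
        HealthCheck.too_slow,
        HealthCheck.function_scoped_fixture,  # fixtures used read-only
    ],
)
settings.load_profile("ci")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)


@pytest.fixture
def base_params() -> NaturalHistoryParams:
    """A plain, hand-checkable parameter set."""
    return NaturalHistoryParams(
        A=-6.0,
        sigma_alpha=1.0,
        alpha1=-0.3,
        alpha20=0.03,
        alpha50=0.01,
        alpha60=0.01,
        alpha70=0.005,
        beta1_colon=2.0,
        beta2_colon=10.0,
        beta1_rectum=2.0,
        beta2_rectum=8.0,
        p_growth=1.0,
        gamma0=3.5,
        gamma1=0.1,
        gamma2=-0.1,
        gamma3=0.0,
        gamma4=-0.1,
        gamma5=0.02,
        sigma_gamma=0.5,
        lambda1=3.77,
        lambda2=2.38,
        lambda3=0.87,
    )
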