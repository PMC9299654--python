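import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import agonistic as ag

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def params():
    """Canonical stable-regime contest coefficients."""
    return ag.ContestParams()


@pytest.fixture
def stable_G():
    """Weak signal honesty: all traits converge."""
    return ag.GeneticArchitecture(GSB=0.4)


@pytest.fixture
def runaway_G():
    """Strong signal honesty: signal and body size run away."""
    return ag.GeneticArchitecture(GSB=0.8)


def make_table(
    state=ag.PopulationState(),
    n=10_000,
    seed=0,
    G=None,
    params=None,
    calibrate=True,
):
    """Contest table at a population state, intercept calibrated so that
    expected fitness is one (required for the normalized relative-fitness
    column to sit on the analytic gradient scale)."""
    G = G or ag.GeneticArchitecture()
    params = params or ag.ContestParams()
    if calibrate:
        params = params.with_intercept(ag.calibrated_intercept(params, G, state))
    rngs = ag.spawn_rngs(seed)
    males = ag.sample_population(n, state, G, rngs["sampling"])
    table = ag.run_contests(
        males, params, rng_pairing=rngs["pairing"], rng_noise=rngs["noise"]
    )
    return table, males, params, rngs
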