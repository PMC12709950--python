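import numpy as np
import pytest

import germisample as gs


@pytest.fixture(scope="session")
def timeline():
    return gs.Timeline.canonical()


@pytest.fixture(scope="session")
def training_cohort():
    """A 99-curve normal-speed training cohort (study-sized)."""
    spec = gs.CohortSpec(n_curves=99, rng_seed=42)
    return gs.generate_cohort(spec)


@pytest.fixture(scope="session")
def training_priors(training_cohort):
    curves, _ = training_cohort
    return gs.build_priors(curves)


@pytest.fixture(scope="session")
def test_cohort():
    """The 20-curve normal-speed simulated test set."""
    spec = gs.CohortSpec(n_curves=20, rng_seed=43)
    return gs.generate_cohort(spec)


@pytest.fixture()
def noisy_curve(timeline):
    theta = gs.GompertzParams(95.0, 20.0, 0.08)
    return gs.simulate_curve(theta, 2.0, timeline, rng=7)
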