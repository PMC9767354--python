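import numpy as np
import pytest

import litsim as ls


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def dichotomous_half():
    """Dichotomous model at 50% prevalence of true effects."""
    return ls.make_distribution("dichotomous", w_b=0.5)


@pytest.fixture(scope="session")
def small_literature():
    """A modest literature reused by structural tests (adequately powered,
    light bias, two_peaks at 50% prevalence)."""
    config = ls.SimulationConfig(
        distribution=ls.distribution_for_prevalence("two_peaks", 0.5),
        power_spec=ls.PowerSpec(power=0.8),
        bias=0.1,
        n_published_target=1000,
        seed=42,
    )
    return ls.simulate_literature(config)


@pytest.fixture(scope="session")
def null_biased_literature():
    """All effects exactly zero, full bias: every finding is a pushed FP."""
    config = ls.SimulationConfig(
        distribution=ls.make_distribution("dichotomous", w_b=0.0),
        power_spec=ls.PowerSpec(power=0.8, reference="min_effect"),
        bias=1.0,
        n_published_target=2000,
        seed=7,
    )
    return ls.simulate_literature(config)
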