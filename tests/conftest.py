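import numpy as np
import pytest

from bodymaps import (
    GeneratorConfig,
    default_stimulus_set,
    make_body_template,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def template():
    """Small body template shared across tests."""
    return make_body_template(80, 32)


@pytest.fixture(scope="session")
def stimuli():
    return default_stimulus_set()


@pytest.fixture(scope="session")
def small_cohort(template, stimuli):
    """A small simulated cohort with the default group structure."""
    cfg = GeneratorConfig(n_low=8, n_high=8, map_dropout_prob=0.0, seed=11)
    events, cohort, truth = simulate_cohort(cfg, template, stimuli)
    return cfg, events, cohort, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
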