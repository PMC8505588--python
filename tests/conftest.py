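"""Shared fixtures: a small synthetic cohort and recordings under both protocols."""

import numpy as np
import pytest

from eegauth import (
    FilterSpec,
    build_schedule,
    inject_blinks,
    make_cohort,
    simulate_ec,
    simulate_vs,
)


@pytest.fixture(scope="session")
def cohort():
    return make_cohort(3, seed=7, separation=1.0)


@pytest.fixture(scope="session")
def params(cohort):
    return cohort[0]


@pytest.fixture(scope="session")
def ec_recording(params):
    return simulate_ec(params, 30.0, 256.0)


@pytest.fixture(scope="session")
def vs_recording(params):
    return simulate_vs(params, build_schedule(10), 256.0)


@pytest.fixture(scope="session")
def vs_with_blinks(params):
    return inject_blinks(simulate_vs(params, build_schedule(30), 256.0), params)


@pytest.fixture(scope="session")
def fspec():
    return FilterSpec()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
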