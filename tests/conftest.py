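import warnings

import numpy as np
import pandas as pd
import pytest

import prosocial_motives as pm


@pytest.fixture(scope="session")
def destroy_grid():
    return pm.build_action_grid([pm.Context.DESTROY])


@pytest.fixture(scope="session")
def both_grid():
    return pm.build_action_grid([pm.Context.DESTROY, pm.Context.HELP])


@pytest.fixture(scope="session")
def judgment_grid():
    return pm.build_judgment_grid([pm.Context.DESTROY])


@pytest.fixture(scope="session")
def small_cohort():
    """Ten participants spanning the four profiles."""
    counts = {
        pm.Profile.UNCONDITIONALLY_SELFISH: 2,
        pm.Profile.COST_SENSITIVE: 3,
        pm.Profile.EFFICIENCY_SENSITIVE: 3,
        pm.Profile.HARM_SENSITIVE: 2,
    }
    return pm.sample_cohort(counts=counts, seed=11)


@pytest.fixture(scope="session")
def small_actions(small_cohort, destroy_grid):
    return pm.simulate_dataset(small_cohort, destroy_grid, "action", seed=12)


@pytest.fixture(scope="session")
def small_judgments(small_cohort, judgment_grid):
    return pm.simulate_dataset(small_cohort, judgment_grid, "judgment", seed=13)


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message=".*constant responses.*", category=UserWarning
        )
        warnings.filterwarnings(
            "ignore", message=".*weak cluster structure.*", category=UserWarning
        )
        yield
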