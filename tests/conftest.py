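import dataclasses

import numpy as np
import pytest

from weberkit.config import RunConfig
from weberkit.simulate import DEFAULT_GROUPS, simulate_group_study

#: Ratio bins and per-bin trial counts of the 75-trial numerosity design.
NUMBER_BIN_ALLOCATION = {2.0: 19, 4 / 3: 19, 6 / 5: 19, 8 / 7: 18}


@pytest.fixture
def rng():
    return np.random.default_rng(20140675)


@pytest.fixture(scope="session")
def small_groups():
    """Down-scaled cohort (8 per group) for fast pipeline contract tests."""
    return tuple(
        dataclasses.replace(g, n_participants=8) for g in DEFAULT_GROUPS
    )


@pytest.fixture(scope="session")
def small_study(small_groups):
    return simulate_group_study(small_groups, seed=7)


@pytest.fixture(scope="session")
def default_study():
    """One full-size simulated study under the default group parameters."""
    return simulate_group_study(DEFAULT_GROUPS, seed=11)


@pytest.fixture
def small_config(small_groups):
    return RunConfig(seed=7, groups=small_groups)
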