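import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import depscreen_cea as d

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def params():
    return d.load_config()


@pytest.fixture(scope="session")
def schedule():
    return d.default_schedule()


@pytest.fixture(scope="session")
def base_results(params, schedule):
    """Discounted totals for all five strategies under the shipped defaults."""
    return d.run_all_strategies(params, schedule, keep_trace=True)


def make_schedule(p_depression, p_death, age_start=20, age_end=70):
    """Build a flat schedule with constant probabilities for test scenarios."""
    ages = np.arange(age_start, age_end + 1)
    return d.AgeSchedule(
        pd.DataFrame(
            {
                "age": ages,
                "p_depression": np.full(len(ages), p_depression, dtype=float),
                "p_death": np.full(len(ages), p_death, dtype=float),
            }
        )
    )


@pytest.fixture(scope="session")
def flat_schedule():
    return make_schedule(0.139, 0.005)
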