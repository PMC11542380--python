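import numpy as np
import pytest

from alpopk.population import PRESETS
from alpopk.trial import Arm, TrialDesign, generate_trial


@pytest.fixture(scope="session")
def table1():
    return PRESETS["table1_day1"]


@pytest.fixture(scope="session")
def table2():
    return PRESETS["table2_day14"]


@pytest.fixture(scope="session")
def table3():
    return PRESETS["table3_day28"]


def single_occasion_design(n_subjects: int = 16, dose: float = 1000.0) -> TrialDesign:
    """One arm, one PK day (the recovery-study layout)."""
    return TrialDesign(
        arms=(Arm("g", n_subjects, ((1, 1, dose),), ((1, "day1"),)),)
    )


@pytest.fixture(scope="session")
def recovery_dataset(table1):
    """16 subjects, 12 samples, one 1,000-mg dose, day-1 truth."""
    return generate_trial(single_occasion_design(), {"day1": table1}, 7)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
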