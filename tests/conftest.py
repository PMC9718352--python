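import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from dreadchoice import DESIGNS, CohortSpec, TrialTable, generate_binomial_cohort

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def design1():
    return DESIGNS[1]


@pytest.fixture
def small_cohort(design1):
    """2 subjects x 2 sessions, fixed rate 0.75, no omissions."""
    spec = CohortSpec(n_subjects=2, n_sessions=2, p_choice=0.75, seed=42)
    return generate_binomial_cohort(spec, design1)


@pytest.fixture
def handmade_table(design1):
    """One subject, one session: 2 forced + 16 free with 2 omissions, 7 EL choices.

    Valid free trials: 14, of which 7 are the target (EL) -> exactly 50%.
    """
    rows = []
    for i, arm in enumerate(["EL", "LL"], start=1):
        rows.append(
            dict(experiment_id=1, subject_id="r1", session=1, trial_index=i,
                 trial_type="forced", offered=arm, chosen=arm, omission=False,
                 side_of_target="left")
        )
    choices = ["EL"] * 7 + ["LL"] * 7 + [None, None]
    for j, c in enumerate(choices, start=3):
        rows.append(
            dict(experiment_id=1, subject_id="r1", session=1, trial_index=j,
                 trial_type="free", offered="EL|LL", chosen=c, omission=c is None,
                 side_of_target="left")
        )
    return TrialTable(pd.DataFrame(rows), design1)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
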