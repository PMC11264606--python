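import numpy as np
import pandas as pd
import pytest

from prefscore import CohortSpec, generate_baseline, generate_followup
from prefscore.value_scoring import EQ5D_ITEMS, ValueSetTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def fixture_table():
    """Small synthetic tariff with distinct, level-monotone decrements."""
    dec = {}
    for j, item in enumerate(EQ5D_ITEMS):
        for level in range(1, 6):
            dec[(item, level)] = 0.0 if level == 1 else round(0.02 * (j + 1) + 0.03 * (level - 1), 4)
    return ValueSetTable(instrument="fixture", anchor=1.0, minimum=-1.0, maximum=1.0, decrements=dec)


@pytest.fixture(scope="session")
def default_spec():
    return CohortSpec()


@pytest.fixture(scope="session")
def baseline_cohort(default_spec):
    """Default-calibration baseline at the study's own sample size."""
    return generate_baseline(default_spec, seed=7)


@pytest.fixture(scope="session")
def large_baseline(default_spec):
    return generate_baseline(default_spec, n=100_000, seed=11)


@pytest.fixture(scope="session")
def followup_cohort(default_spec, baseline_cohort):
    return generate_followup(baseline_cohort, default_spec, seed=8)


@pytest.fixture(scope="session")
def linked_changes(baseline_cohort, followup_cohort):
    merged = baseline_cohort.set_index("person_id").loc[followup_cohort["person_id"]]
    return pd.DataFrame(
        {
            "d_eq5d": followup_cohort["eq5d_utility"].to_numpy() - merged["eq5d_utility"].to_numpy(),
            "d_propr": followup_cohort["propr_utility"].to_numpy() - merged["propr_utility"].to_numpy(),
        }
    )
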