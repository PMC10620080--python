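import numpy as np
import pandas as pd
import pytest

from soadc import ExprSimConfig, TimingSimConfig, generate_expression, generate_timing


@pytest.fixture(scope="session")
def default_cohort():
    """Mixed-culture cohort at the default geometry: 100 larvae x 4 cultures,
    wild type vs a knock-in shifted +4 h."""
    records, truth = generate_timing(TimingSimConfig(seed=0))
    return records, truth


@pytest.fixture(scope="session")
def null_cohort():
    """Two exchangeable genotypes: no shift, same base distribution."""
    records, truth = generate_timing(TimingSimConfig(shifts_hours={"A": 0.0, "B": 0.0}, seed=0))
    return records, truth


@pytest.fixture(scope="session")
def half_dose_expression():
    """Uncompensated table: male X at half the female level (c = 0)."""
    return generate_expression(ExprSimConfig(compensation=0.0, seed=0))


@pytest.fixture(scope="session")
def full_dc_expression():
    """Fully compensated table (c = 1): male and female X identical in law."""
    return generate_expression(ExprSimConfig(compensation=1.0, seed=0))


@pytest.fixture()
def tiny_records():
    """Hand-written six-individual cohort covering censoring and two cultures."""
    return pd.DataFrame(
        {
            "individual": [f"i{k}" for k in range(8)],
            "genotype": ["WT", "WT", "KI", "KI"] * 2,
            "sex": ["male", "female"] * 4,
            "culture": ["c1"] * 4 + ["c2"] * 4,
            "time_hours": [200.0, 210.0, 204.0, 214.0, 202.0, 212.0, 206.0, 150.0],
            "observed": [True] * 7 + [False],
        }
    )
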