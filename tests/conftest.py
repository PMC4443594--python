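import numpy as np
import pytest

from pmvr_cea import default_parameters, run_cea, run_cohort
from pmvr_cea.mortality import LifeTable


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def life_table():
    return LifeTable.bundled_german()


@pytest.fixture(scope="session")
def zero_life_table():
    ages = np.arange(50, 101)
    return LifeTable(age=ages, q_male=np.zeros_like(ages, dtype=float),
                     q_female=np.zeros_like(ages, dtype=float))


@pytest.fixture(scope="session")
def base_traces(params, life_table):
    return {arm: run_cohort(arm, params, life_table) for arm in ("PMVR", "OMT")}


@pytest.fixture(scope="session")
def base_result(params, life_table):
    return run_cea(params, life_table)
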