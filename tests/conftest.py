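import numpy as np
import pytest

import ropscreen as rs


@pytest.fixture(scope="session")
def table1_cohort():
    """A 10,000-infant cohort drawn with the Table-1-calibrated defaults."""
    params = rs.default_cohort_params(n=10_000, seed=20260922)
    return rs.generate_cohort(params)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_record(**overrides) -> rs.InfantRecord:
    base = dict(
        infant_id="i1",
        ga_weeks=31.0,
        birth_weight_g=1400.0,
        igf1_w3=45.0,
        sepsis_w3=0,
        rop_grade="none",
    )
    base.update(overrides)
    return rs.InfantRecord(**base)
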