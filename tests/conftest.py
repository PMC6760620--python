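import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bivakit.cohort_io import CohortTable, ParseReport, Sex, SubjectRecord

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_record(
    subject_id="S1",
    sex=Sex.MALE,
    age=10.0,
    height=1.40,
    weight=35.0,
    r_dup=(500.0, 500.0),
    xc_dup=(50.0, 50.0),
    pa_dup=(5.7, 5.7),
    **extra,
):
    return SubjectRecord(
        subject_id=subject_id,
        sex=sex,
        age=age,
        height=height,
        weight=weight,
        r_dup=r_dup,
        xc_dup=xc_dup,
        pa_dup=pa_dup,
        **extra,
    )


def make_table(records, source="fixture"):
    return CohortTable(records=list(records), provenance=ParseReport(source=source, rows_read=len(records)))


@pytest.fixture
def qc_toy_table():
    """Six records: one implausible-PA, one PA-repeatability, one R/H-
    repeatability failure (duplicate gap / height = 7 ohm/m), three clean."""
    return make_table(
        [
            make_record("clean1"),
            make_record("pa_high", pa_dup=(8.2, 8.4)),
            make_record("clean2", height=1.55, r_dup=(480.0, 481.0)),
            make_record("pa_gap", pa_dup=(6.0, 6.6)),
            make_record("rh_gap", height=1.50, r_dup=(605.25, 594.75)),  # gap 10.5 / 1.5 = 7
            make_record("clean3", xc_dup=(52.0, 51.0)),
        ],
        source="qc_toy",
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Clean synthetic cohort with truth, shared across tests."""
    from bivakit.synthetic_cohort import default_config, generate_cohort

    return generate_cohort(default_config(n=1200, seed=20250923 % 2**31))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
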