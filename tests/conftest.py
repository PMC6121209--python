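import pytest
from hypothesis import HealthCheck, settings

from ichscores import PatientRecord, table_fixtures

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def ich_table():
    return table_fixtures()[0]


@pytest.fixture(scope="session")
def modified_table():
    return table_fixtures()[1]


@pytest.fixture
def typical_record():
    """A mid-severity admission: GCS 7, 20 cm³ supratentorial bleed with
    IVH, MRS 4, unremarkable vitals."""
    return PatientRecord(
        age=70,
        sex="female",
        gcs=7,
        mrs=4,
        temperature=36.8,
        sbp=150,
        dbp=90,
        location="supratentorial",
        ivh=True,
        sah=False,
        volume_cm3=20.0,
        dead_30d=True,
    )
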