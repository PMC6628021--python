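import datetime as dt

import pytest

from apqi import EncounterRecord, default_config


@pytest.fixture(scope="session")
def config():
    return default_config()


def make_record(
    diagnoses=(),
    prescriptions=(),
    age=30.0,
    sex="F",
    site="GPC1",
    encounter_id="E1",
    date=dt.date(2017, 1, 15),
):
    """Terse encounter builder for hand-built fixtures."""
    return EncounterRecord(
        site_id=site,
        encounter_id=encounter_id,
        date=date,
        age_years=age,
        sex=sex,
        diagnoses=tuple(diagnoses),
        prescriptions=tuple(prescriptions),
    )


@pytest.fixture
def tonsillitis_quartet():
    """Four tonsillitis encounters: ages 0.5 (ineligible), 5, 30, 40;
    two of the eligible three treated (one recommended, one amoxicillin)."""
    return [
        make_record(["R76"], ["J01CE02"], age=5, encounter_id="E1"),
        make_record(["R76"], ["J01CA04"], age=30, encounter_id="E2"),
        make_record(["R76"], [], age=40, encounter_id="E3"),
        make_record(["R76"], ["J01CE02"], age=0.5, encounter_id="E4"),
    ]
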