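from datetime import datetime, timedelta

import pytest

from deltacheck.panel_model import PatientResult, ResultPair, load_panel

T0 = datetime(2018, 8, 1)


@pytest.fixture(scope="session")
def panel():
    return load_panel()


@pytest.fixture(scope="session")
def spec_of(panel):
    by_name = {s.name: s for s in panel}

    def get(name):
        return by_name[name]

    return get


def make_result(value, days=0.0, analyte="calcium", setting="inpatient", pid="P1"):
    return PatientResult(
        patient_id=pid, setting=setting, analyte=analyte,
        value=value, time=T0 + timedelta(days=days),
    )


def make_pair(prev, curr, days=1.0, analyte="calcium", setting="inpatient", pid="P1"):
    """Two-point pair with the given values and interval in days."""
    return ResultPair(
        previous=make_result(prev, 0.0, analyte, setting, pid),
        current=make_result(curr, days, analyte, setting, pid),
    )
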