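import datetime as dt

import pytest

from rxsupply.model import Component, PrescriptionRecord
from rxsupply.simulate import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def cohort():
    """Mid-sized seeded cohort under the default study conditions."""
    return generate_cohort(CohortConfig(n_patients=300, seed=11))


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(CohortConfig(n_patients=40, seed=3))


def make_record(**overrides) -> PrescriptionRecord:
    """A valid tablet prescription; fields overridable per test."""
    base = dict(
        patient_id="P1",
        prescription_id="RX1",
        issue_date=dt.date(2018, 1, 10),
        dispense_date=dt.date(2018, 1, 12),
        atc_code="C09AA02",
        components=(Component("tensoprel", 10.0, "mass"),),
        drug_form="tablet",
        package_id="PKG-tensoprel",
        n_packages=1,
        units_per_package=30,
    )
    base.update(overrides)
    return PrescriptionRecord(**base)


@pytest.fixture
def tablet_record():
    return make_record()
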