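from datetime import date

import pytest

import medagree as m


@pytest.fixture(scope="session")
def small_cohort():
    """Compact default-catalogue cohort used across the suite."""
    return m.generate_cohort(n_participants=150, seed=11)


@pytest.fixture(scope="session")
def small_classified(small_cohort):
    return m.classify_reports(
        small_cohort.questionnaires, small_cohort.claims, small_cohort.medications
    )


@pytest.fixture
def single_med():
    """One dense-dispensing four-level medication for focused cohorts."""
    return m.MedicationDefinition(
        medication_id="etanercept",
        display_name="Etanercept",
        med_class="btsDMARD",
        prescription_only=True,
        question_type="four_level",
        match_mode="atc7",
        codes=frozenset({"L04AB01"}),
        refill_interval_days=30,
    )


@pytest.fixture
def report_factory():
    def make(status, stop_date=None, qdate=date(2020, 6, 15), med="etanercept"):
        return m.SelfReportRecord(
            participant_id="P00001",
            questionnaire_date=qdate,
            medication_id=med,
            status=status,
            stop_date=stop_date,
        )

    return make
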