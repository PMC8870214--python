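import pytest

from hairyscore import build_fixture_cohort
from hairyscore.flow import summarize_sample
from hairyscore.scoring import score_cohort


@pytest.fixture(scope="session")
def fixture_cohort():
    """The deterministic 82-patient cohort (verified on construction)."""
    return build_fixture_cohort()


@pytest.fixture(scope="session")
def fixture_profiles(fixture_cohort):
    _, _, events = fixture_cohort
    return {ev.sample_id: summarize_sample(ev) for ev in events}


@pytest.fixture(scope="session")
def patient_profiles(fixture_cohort, fixture_profiles):
    _, samples, _ = fixture_cohort
    pid_of = {s.sample_id: s.patient_id for s in samples}
    return {pid_of[sid]: prof for sid, prof in fixture_profiles.items()}


@pytest.fixture(scope="session")
def fixture_scores(fixture_cohort, patient_profiles):
    patients, _, _ = fixture_cohort
    return score_cohort(patients, patient_profiles)


@pytest.fixture(scope="session")
def fixture_truth(fixture_cohort):
    patients, _, _ = fixture_cohort
    return {p.patient_id: p.group for p in patients}
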