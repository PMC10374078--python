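import datetime as dt

import pytest

import coilflow as cf


@pytest.fixture(scope="session")
def calib():
    return cf.default_calibration()


@pytest.fixture(scope="session")
def compat():
    return cf.default_compatibility()


@pytest.fixture(scope="session")
def service(calib):
    return cf.default_service_config(calib)


@pytest.fixture(scope="session")
def week_requests(calib):
    """One fixed week of demand at the department's booked 79 exams/day."""
    return cf.generate_requests(calib, 7, seed=11, daily_total=79)


@pytest.fixture(scope="session")
def week_traces(week_requests, compat, service):
    """Paired baseline/proposed traces for the fixed week."""
    base = cf.baseline_schedule(week_requests, compat, seed=11)
    prop = cf.proposed_schedule(week_requests, compat, seed=11)
    tb = cf.run_simulation(base, week_requests, service, compat, seed=11)
    tp = cf.run_simulation(prop, week_requests, service, compat, seed=11)
    return tb, tp


def make_request(
    rid="R1",
    coil="Torso",
    appt=dt.datetime(2016, 12, 1, 9, 0),
    patient_type="outpatient",
    contrast=False,
    wait_days=5,
):
    return cf.ExamRequest(
        request_id=rid,
        patient_type=patient_type,
        gender="female",
        needs_contrast=contrast,
        priority=(patient_type == "emergency"),
        coil=coil,
        booking_datetime=appt - dt.timedelta(days=wait_days),
        appointment_datetime=appt,
    )
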