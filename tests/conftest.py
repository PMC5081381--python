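import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from alarmsim import ChannelSeries, Cohort, MonitoringSession

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_series(values, channel="HR", interval=1.0, timestamps=None):
    values = np.asarray(values, dtype=float)
    if timestamps is None:
        timestamps = np.arange(values.size) * interval
    return ChannelSeries(channel, timestamps, values, nominal_interval=interval)


def make_cohort(series_by_patient):
    """{patient_id: [ChannelSeries, ...]} -> Cohort."""
    return Cohort(
        tuple(
            MonitoringSession.from_series(pid, series)
            for pid, series in series_by_patient.items()
        )
    )


@pytest.fixture
def toy_spo2_cohort():
    """One patient, the 8-sample low-SpO2 record with two violation runs."""
    s = make_series([95, 95, 84, 84, 84, 95, 84, 95], channel="SPO2")
    return make_cohort({"P1": [s]})


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
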