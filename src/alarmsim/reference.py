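"""Published reference tables used as inputs and comparison fixtures.

These are printed summary values from published general-care-unit
monitoring studies: the cloud-hosted continual-monitoring database
(94,575 h, 3430 patients) that anchors the default synthetic generator, and
the intermittent Bleyer and continual Tarassenko cohorts used for
cross-database comparison.  They are constants of the published record, not
quantities this package computes.
"""

from __future__ import annotations

import numpy as np

from .alarms import AlarmRateGrid
from .burden import AlarmLimit, AlarmSettings, ChannelSettings
from .population import PopulationProfile

__all__ = [
    "CLOUD_PERCENTILES",
    "CLOUD_MEAN_CI",
    "CLOUD_N_PATIENTS",
    "CLOUD_MONITORED_HOURS",
    "cloud_profile",
    "bleyer_profile",
    "tarassenko_profile",
    "SPO2_LOW_RATE_GRID",
    "default_alarm_settings",
    "EXCURSION_DURATION_QUANTILES",
]

# ---------------------------------------------------------------------------
# Cloud-hosted database distribution table (percent rank -> value)

CLOUD_N_PATIENTS = 3430
CLOUD_MONITORED_HOURS = 94_575.0

CLOUD_PERCENTILES: dict[str, dict[float, float]] = {
    "HR": {1: 50, 5: 58, 10: 63, 50: 81, 90: 105, 95: 112, 99: 128},
    "RR": {1: 7, 5: 10, 10: 11, 50: 16, 90: 23, 95: 25, 99: 30},
    "SPO2": {1: 86, 5: 89, 10: 91, 50: 95, 90: 99, 95: 100, 99: 100},
    "SBP": {1: 83, 5: 93, 10: 98, 50: 121, 90: 151, 95: 161, 99: 180},
}

CLOUD_MEAN_CI: dict[str, tuple[float, tuple[float, float]]] = {
    "HR": (82.7, (82.1, 83.2)),
    "RR": (16.8, (16.7, 17.0)),
    "SPO2": (94.9, (94.8, 95.0)),
    "SBP": (123.4, (122.7, 124.1)),
}

_BLEYER_PERCENTILES = {
    "HR": {1: 45, 5: 55, 10: 65, 50: 85, 90: 115, 95: 125, 99: 145},
    "RR": {1: 13, 5: 15, 10: 15, 50: 19, 90: 22, 95: 24, 99: 34},
    "SPO2": {1: 86, 5: 91, 10: 96, 50: 97, 90: 100, 95: 100, 99: 100},
}
_BLEYER_MEAN_CI = {
    "HR": (84.7, (84.5, 84.9)),
    "RR": (19.7, (19.6, 19.7)),
    "SPO2": (96.0, (95.9, 96.0)),
}
_BLEYER_N_PATIENTS = 27_722
_BLEYER_N_MEASUREMENTS = 1_150_000

# Tarassenko rows report no median.
_TARASSENKO_PERCENTILES = {
    "HR": {1: 50, 5: 58, 10: 63, 90: 105, 95: 113, 99: 128},
    "RR": {1: 7, 5: 10, 10: 13, 90: 26, 95: 29, 99: 34},
    "SPO2": {1: 84, 5: 90, 10: 93},
    "SBP": {1: 85, 5: 96, 10: 101, 90: 155, 95: 165, 99: 185},
}
_TARASSENKO_MEAN_CI = {
    "HR": (84.2, (83.0, 85.4)),
    "RR": (18.6, (18.2, 19.0)),
    "SPO2": (96.0, (95.8, 96.2)),
    "SBP": (128.5, (127.1, 129.9)),
}
_TARASSENKO_N_PATIENTS = 863


def _profile(channel, pcts, mean_ci, n_patients, n_meas, source):
    mean, ci = mean_ci[channel]
    return PopulationProfile(
        channel=channel,
        percentiles={float(r): float(v) for r, v in pcts[channel].items()},
        mean=mean,
        ci95=ci,
        n_patients=n_patients,
        n_measurements=n_meas,
        metadata={"source": source, "kind": "published summary table"},
    )


def cloud_profile(channel: str) -> PopulationProfile:
    """Published cloud-database distribution row for one channel."""
    return _profile(
        channel, CLOUD_PERCENTILES, CLOUD_MEAN_CI, CLOUD_N_PATIENTS, 0,
        "cloud-hosted continual-monitoring database",
    )


def bleyer_profile(channel: str) -> PopulationProfile:
    """Published intermittent-monitoring comparison row (Bleyer et al.)."""
    return _profile(
        channel, _BLEYER_PERCENTILES, _BLEYER_MEAN_CI, _BLEYER_N_PATIENTS,
        _BLEYER_N_MEASUREMENTS, "Bleyer et al. intermittent database",
    )


def tarassenko_profile(channel: str) -> PopulationProfile:
    """Published continual-monitoring comparison row (Tarassenko et al.)."""
    return _profile(
        channel, _TARASSENKO_PERCENTILES, _TARASSENKO_MEAN_CI,
        _TARASSENKO_N_PATIENTS, 0, "Tarassenko et al. continual database",
    )


# ---------------------------------------------------------------------------
# Published projected-alarm-rate grid for the low-SpO2 alarm
# (alarms/patient/day; rows = annunciation delay in s, columns = threshold %)

SPO2_LOW_RATE_GRID = AlarmRateGrid(
    channel="SPO2",
    direction="low",
    thresholds=(81.0, 83.0, 85.0, 87.0, 89.0),
    delays_s=(20.0, 25.0, 30.0, 35.0, 40.0),
    rates=np.array(
        [
            [0.9, 1.9, 4.8, 12.3, 28.8],
            [0.8, 1.6, 4.0, 10.4, 24.5],
            [0.7, 1.5, 3.7, 9.6, 22.8],
            [0.6, 1.3, 3.1, 8.3, 19.8],
            [0.6, 1.1, 2.7, 7.2, 17.5],
        ]
    ),
)


def default_alarm_settings() -> AlarmSettings:
    """The published multi-parameter settings profile used to project total
    burden: HR 150/5 s high and 30/5 s low, RR 35/120 s high and 4/120 s low,
    SpO2 85 %/30 s low, SBP 190 mmHg/60 s high, MAP 60 mmHg/60 s low."""
    return AlarmSettings(
        {
            "HR": ChannelSettings(
                high=AlarmLimit(150, 5), low=AlarmLimit(30, 5)
            ),
            "RR": ChannelSettings(
                high=AlarmLimit(35, 120), low=AlarmLimit(4, 120)
            ),
            "SPO2": ChannelSettings(low=AlarmLimit(85, 30)),
            "SBP": ChannelSettings(high=AlarmLimit(190, 60)),
            "MAP": ChannelSettings(low=AlarmLimit(60, 60)),
        }
    )


#: Published quantiles of the self-resolution time of threshold excursions:
#: 71 % of alarm episodes last 30 s or less and 95 % resolve within 120 s.
EXCURSION_DURATION_QUANTILES = ((30.0, 0.71), (120.0, 0.95))
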