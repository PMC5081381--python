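"""Threshold-violation episode detection, annunciation delays and rate grids.

The simulation core: given a numeric vital-sign record and a one-sided alarm
threshold, find the maximal contiguous runs of violating samples (*alarm
episodes*), then apply an *annunciation delay* — an episode annunciates a
single alarm if and only if the violation persists for at least the delay.
Projected alarm rates are expressed as alarms per patient per day of
monitored time, pooled over the cohort, and tabulated over threshold x delay
grids to support settings selection.

Conventions (surfaced as parameters so the alternatives can be run):

* the comparison is strict by default — ``value < low`` or ``value > high``
  violates, the threshold itself being the last acceptable value; pass
  ``inclusive=True`` on the ThresholdSpec for the ``<=`` / ``>=`` variant;
* one alarm per episode, no re-annunciation of long-persisting violations;
* the delay timer resets whenever the value returns within limits for even
  a single sample (no hysteresis);
* an episode still active at the record end or at a data gap is *censored*:
  it is counted, and annunciates only if its observed duration already
  reached the delay.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .timeseries import (
    SECONDS_PER_DAY,
    ChannelSeries,
    Cohort,
    DataError,
    ParameterError,
    canonical_channel,
)

__all__ = [
    "ThresholdSpec",
    "AlarmEpisode",
    "AlarmRateGrid",
    "DurationHistogram",
    "UndefinedRateError",
    "detect_episodes",
    "cohort_episodes",
    "annunciate",
    "alarm_rate",
    "rate_grid",
    "duration_distribution",
]

DIRECTIONS = ("low", "high")


class UndefinedRateError(DataError):
    """Alarm rate requested over zero monitored patient-time."""


@dataclass(frozen=True)
class ThresholdSpec:
    """One-sided alarm limit: channel, direction and threshold value."""

    channel: str
    direction: str
    threshold: float
    inclusive: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "channel", canonical_channel(self.channel))
        if self.direction not in DIRECTIONS:
            raise ParameterError(f"direction must be one of {DIRECTIONS}")
        if self.channel == "SPO2" and not (0 < self.threshold <= 100):
            raise ParameterError("SPO2 threshold must lie in (0, 100]")
        if self.channel in {"HR", "RR", "SBP", "DBP", "MAP"} and self.threshold <= 0:
            raise ParameterError(f"{self.channel} threshold must be > 0")

    def violates(self, values: np.ndarray) -> np.ndarray:
        if self.direction == "low":
            return values <= self.threshold if self.inclusive else values < self.threshold
        return values >= self.threshold if self.inclusive else values > self.threshold


@dataclass(frozen=True)
class AlarmEpisode:
    """A maximal contiguous threshold violation for one channel/direction.

    ``duration_s`` is the violating sample count times the nominal interval;
    ``censored`` flags a violation still active at the record end or a gap.
    """

    patient_id: str
    channel: str
    direction: str
    start_s: float
    duration_s: float
    censored: bool = False


def detect_episodes(
    series: ChannelSeries, spec: ThresholdSpec, patient_id: str = ""
) -> list[AlarmEpisode]:
    """Find the maximal gap-free runs of consecutive violating samples.

    Episodes are disjoint, ordered by start time, and never span a data gap;
    a run touching the end of its gap-free run (record end or gap) is marked
    censored.
    """
    if series.channel != spec.channel:
        raise ParameterError(
            f"channel mismatch: series {series.channel}, spec {spec.channel}"
        )
    episodes: list[AlarmEpisode] = []
    for a, b in series.gap_runs():
        mask = spec.violates(series.values[a:b]).astype(np.int8)
        edges = np.flatnonzero(np.diff(np.concatenate(([0], mask, [0]))))
        for s, e in zip(edges[0::2], edges[1::2]):
            episodes.append(
                AlarmEpisode(
                    patient_id=patient_id,
                    channel=spec.channel,
                    direction=spec.direction,
                    start_s=float(series.timestamps[a + s]),
                    duration_s=float((e - s) * series.nominal_interval),
                    censored=bool(e == b - a),
                )
            )
    return episodes


def cohort_episodes(cohort: Cohort, spec: ThresholdSpec) -> list[AlarmEpisode]:
    """All episodes for a threshold spec across every session carrying it."""
    out: list[AlarmEpisode] = []
    for session in cohort.sessions_with(spec.channel):
        out.extend(
            detect_episodes(session.channels[spec.channel], spec, session.patient_id)
        )
    return out


def annunciate(episodes: Sequence[AlarmEpisode], delay_s: float) -> list[AlarmEpisode]:
    """Episodes surviving an annunciation delay: observed duration >= delay.

    Each surviving episode yields exactly one alarm.  Censored episodes
    annunciate iff their observed duration already reached the delay; no
    unobserved persistence is assumed.
    """
    if delay_s < 0:
        raise ParameterError("delay_s must be >= 0")
    return [e for e in episodes if e.duration_s >= delay_s]


def alarm_rate(cohort: Cohort, spec: ThresholdSpec, delay_s: float) -> float:
    """Projected alarms/patient/day for one threshold and delay.

    Pooled cohort-level rate: total annunciated alarms divided by the total
    monitored patient-time on the channel (in days) — monitored time, not
    calendar enrollment, forms the denominator.
    """
    seconds = cohort.monitored_seconds(spec.channel)
    if seconds <= 0:
        raise UndefinedRateError(
            f"no monitored time on channel {spec.channel}; rate undefined"
        )
    n_alarms = len(annunciate(cohort_episodes(cohort, spec), delay_s))
    return n_alarms / (seconds / SECONDS_PER_DAY)


@dataclass(frozen=True)
class AlarmRateGrid:
    """Alarms/patient/day over a threshold x delay grid.

    ``rates[i, j]`` is the rate at ``delays_s[i]`` and ``thresholds[j]``.
    Values are kept at full precision; rounding is presentation-only via
    :meth:`to_frame`.
    """

    channel: str
    direction: str
    thresholds: tuple[float, ...]
    delays_s: tuple[float, ...]
    rates: np.ndarray

    def to_frame(self, decimals: int | None = None) -> pd.DataFrame:
        frame = pd.DataFrame(
            self.rates,
            index=pd.Index(self.delays_s, name="delay_s"),
            columns=pd.Index(self.thresholds, name=f"threshold_{self.channel.lower()}"),
        )
        return frame.round(decimals) if decimals is not None else frame

    def cell(self, delay_s: float, threshold: float) -> float:
        i = self.delays_s.index(delay_s)
        j = self.thresholds.index(threshold)
        return float(self.rates[i, j])


def rate_grid(
    cohort: Cohort,
    channel: str,
    direction: str,
    thresholds: Sequence[float],
    delays_s: Sequence[float],
    inclusive: bool = False,
) -> AlarmRateGrid:
    """Tabulate projected alarm rates over every threshold x delay pair.

    Episode detection runs once per threshold; delays are applied by
    filtering episode durations, so each cell equals the corresponding
    standalone :func:`alarm_rate` call.
    """
    thresholds = [float(t) for t in thresholds]
    delays_s = [float(d) for d in delays_s]
    if not thresholds or not delays_s:
        raise ParameterError("thresholds and delays must be non-empty")
    if sorted(thresholds) != thresholds or sorted(delays_s) != delays_s:
        raise ParameterError("thresholds and delays must be sorted ascending")
    channel = canonical_channel(channel)
    seconds = cohort.monitored_seconds(channel)
    if seconds <= 0:
        raise UndefinedRateError(f"no monitored time on channel {channel}")
    days = seconds / SECONDS_PER_DAY
    rates = np.empty((len(delays_s), len(thresholds)))
    for j, thr in enumerate(thresholds):
        spec = ThresholdSpec(channel, direction, thr, inclusive=inclusive)
        durations = np.array(
            [e.duration_s for e in cohort_episodes(cohort, spec)], dtype=float
        )
        for i, delay in enumerate(delays_s):
            rates[i, j] = np.count_nonzero(durations >= delay) / days
    return AlarmRateGrid(channel, direction, tuple(thresholds), tuple(delays_s), rates)


@dataclass(frozen=True)
class DurationHistogram:
    """Episode-duration histogram with the suppressed fraction at a delay.

    ``suppressed_fraction`` is the share of episodes that resolve before the
    delay elapses (duration < delay), i.e. the alarms a delay of that length
    silences; it is None when there are no episodes.  ``annunciated_bins``
    flags the bins whose lower edge is at or above the delay.
    """

    bin_edges_s: tuple[float, ...]
    counts: tuple[int, ...]
    suppression_delay_s: float
    suppressed_fraction: float | None
    annunciated_bins: tuple[bool, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left_s": self.bin_edges_s[:-1],
                "bin_right_s": self.bin_edges_s[1:],
                "count": self.counts,
                "annunciated": self.annunciated_bins,
            }
        )


def duration_distribution(
    episodes: Sequence[AlarmEpisode],
    bin_edges_s: Sequence[float],
    suppression_delay_s: float,
) -> DurationHistogram:
    """Histogram episode durations and measure delay suppression."""
    edges = [float(x) for x in bin_edges_s]
    if len(edges) < 2 or sorted(edges) != edges or len(set(edges)) != len(edges):
        raise ParameterError("bin edges must be increasing")
    if suppression_delay_s < 0:
        raise ParameterError("suppression_delay_s must be >= 0")
    durations = np.array([e.duration_s for e in episodes], dtype=float)
    counts, _ = np.histogram(durations, bins=edges)
    frac = (
        float(np.count_nonzero(durations < suppression_delay_s) / durations.size)
        if durations.size
        else None
    )
    flags = tuple(left >= suppression_delay_s for left in edges[:-1])
    return DurationHistogram(
        tuple(edges), tuple(int(c) for c in counts), float(suppression_delay_s), frac, flags
    )
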