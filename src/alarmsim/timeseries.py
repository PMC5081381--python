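"""Multi-channel vital-sign numeric time series: data model and cohort I/O.

A monitoring session holds one numeric series per vital-sign channel, sampled
at a nominal cadence (default 1 sample/s) with possible dropouts.  A *gap* is
any spacing between consecutive samples larger than twice the nominal
interval; gaps split a series into gap-free runs, and all downstream
processing (moving averages, alarm-episode detection) operates strictly
within runs.  Monitored time is counted as one nominal interval per sample,
so it is invariant under splitting a series at a gap.

Cohort files are long-format delimited text with columns
``patient_id,channel,t_seconds,value`` (one row per sample); a Parquet
variant with the identical schema is also supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CHANNELS",
    "SECONDS_PER_DAY",
    "SchemaError",
    "DataError",
    "ParameterError",
    "canonical_channel",
    "ChannelSeries",
    "MonitoringSession",
    "Cohort",
    "read_cohort",
    "write_cohort",
    "moving_average",
]

#: Closed channel vocabulary with physical units.
CHANNELS = ("HR", "RR", "SPO2", "SBP", "DBP", "MAP", "TEMP")
#: Units for display/metadata only.
CHANNEL_UNITS = {
    "HR": "beats/min",
    "RR": "breaths/min",
    "SPO2": "%",
    "SBP": "mmHg",
    "DBP": "mmHg",
    "MAP": "mmHg",
    "TEMP": "degC",
}
_STRICTLY_POSITIVE = frozenset({"HR", "RR", "SBP", "DBP", "MAP"})

SECONDS_PER_DAY = 86400.0

REQUIRED_COLUMNS = ("patient_id", "channel", "t_seconds", "value")


class SchemaError(ValueError):
    """A cohort file is missing required columns."""


class DataError(ValueError):
    """File contents violate the data model (ordering, duplicates, ranges)."""


class ParameterError(ValueError):
    """An operation was called with an invalid parameter."""


def canonical_channel(name: str) -> str:
    """Map a channel name to the closed vocabulary, case-insensitively."""
    key = str(name).strip().upper()
    if key not in CHANNELS:
        raise DataError(
            f"unknown channel {name!r}; expected one of {', '.join(CHANNELS)}"
        )
    return key


@dataclass(frozen=True)
class ChannelSeries:
    """One channel's numeric record: strictly increasing timestamps (seconds
    from session start) and finite values in the channel's physical units."""

    channel: str
    timestamps: np.ndarray
    values: np.ndarray
    nominal_interval: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "channel", canonical_channel(self.channel))
        t = np.asarray(self.timestamps, dtype=np.float64)
        v = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "timestamps", t)
        object.__setattr__(self, "values", v)
        if self.nominal_interval <= 0:
            raise ParameterError("nominal_interval must be > 0")
        if t.ndim != 1 or v.ndim != 1 or t.shape != v.shape:
            raise DataError("timestamps and values must be 1-D and equal length")
        if t.size and not np.all(np.diff(t) > 0):
            raise DataError(f"timestamps not strictly increasing on {self.channel}")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(v)):
            raise DataError(f"non-finite sample on {self.channel}")
        if self.channel == "SPO2" and v.size and (v.min() < 0 or v.max() > 100):
            raise DataError("SPO2 values must lie in [0, 100]")
        if self.channel in _STRICTLY_POSITIVE and v.size and v.min() <= 0:
            raise DataError(f"{self.channel} values must be > 0")

    def __len__(self) -> int:
        return int(self.timestamps.size)

    @property
    def gap_threshold(self) -> float:
        """Spacing above which consecutive samples are separated by a gap."""
        return 2.0 * self.nominal_interval

    def gap_mask(self) -> np.ndarray:
        """Boolean array of length n-1; True where a gap follows sample i."""
        return np.diff(self.timestamps) > self.gap_threshold

    def gap_runs(self) -> list[tuple[int, int]]:
        """Half-open index ranges of the maximal gap-free runs, in order."""
        n = len(self)
        if n == 0:
            return []
        cuts = np.flatnonzero(self.gap_mask()) + 1
        bounds = np.concatenate(([0], cuts, [n]))
        return [(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])]

    @property
    def monitored_seconds(self) -> float:
        """Sample count x nominal interval, summed over gap-free runs."""
        return len(self) * self.nominal_interval


@dataclass(frozen=True)
class MonitoringSession:
    """One patient's record: at most one ChannelSeries per channel name."""

    patient_id: str
    channels: Mapping[str, ChannelSeries] = field(default_factory=dict)

    def __post_init__(self) -> None:
        chans: dict[str, ChannelSeries] = {}
        for series in self.channels.values():
            if series.channel in chans:
                raise DataError(
                    f"patient {self.patient_id!r}: duplicate channel {series.channel}"
                )
            chans[series.channel] = series
        object.__setattr__(self, "channels", chans)

    @classmethod
    def from_series(cls, patient_id: str, series: Iterable[ChannelSeries]) -> "MonitoringSession":
        return cls(patient_id, {s.channel: s for s in series})

    def monitored_seconds(self, channel: str) -> float:
        s = self.channels.get(canonical_channel(channel))
        return s.monitored_seconds if s is not None else 0.0


@dataclass(frozen=True)
class Cohort:
    """A collection of monitoring sessions.

    A patient may appear in more than one session (e.g. a record split at a
    dropout); patient counts deduplicate ids, while monitored time and samples
    pool over all sessions.
    """

    sessions: tuple[MonitoringSession, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "sessions", tuple(self.sessions))

    def __len__(self) -> int:
        return len(self.sessions)

    @property
    def n_patients(self) -> int:
        return len({s.patient_id for s in self.sessions})

    def sessions_with(self, channel: str) -> list[MonitoringSession]:
        ch = canonical_channel(channel)
        return [s for s in self.sessions if ch in s.channels]

    def monitored_seconds(self, channel: str) -> float:
        ch = canonical_channel(channel)
        return float(sum(s.monitored_seconds(ch) for s in self.sessions))

    def pooled_values(self, channel: str) -> np.ndarray:
        """All samples on a channel pooled across sessions, file order."""
        ch = canonical_channel(channel)
        parts = [s.channels[ch].values for s in self.sessions_with(ch)]
        if not parts:
            return np.empty(0, dtype=np.float64)
        return np.concatenate(parts)

    def n_patients_with(self, channel: str) -> int:
        return len({s.patient_id for s in self.sessions_with(channel)})


def read_cohort(path, dialect: str = "csv", nominal_interval: float = 1.0) -> Cohort:
    """Read a long-format cohort file into a Cohort.

    Within each (patient, channel) group the rows must appear in strictly
    increasing time order; a non-monotone or duplicated timestamp raises
    :class:`DataError` naming the patient.  Channel names are matched
    case-insensitively against the closed vocabulary.
    """
    if dialect == "csv":
        frame = pd.read_csv(
            path, dtype={"patient_id": str}, float_precision="round_trip"
        )
    elif dialect == "parquet":
        frame = pd.read_parquet(path)
        frame["patient_id"] = frame["patient_id"].astype(str)
    else:
        raise ParameterError(f"unknown dialect {dialect!r}")

    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    sessions = []
    for pid, per_patient in frame.groupby("patient_id", sort=True):
        series = []
        for ch, grp in per_patient.groupby("channel", sort=True):
            name = canonical_channel(ch)
            t = grp["t_seconds"].to_numpy(dtype=np.float64)
            if t.size > 1 and not np.all(np.diff(t) > 0):
                raise DataError(
                    f"patient {pid!r}, channel {name}: timestamps not strictly "
                    "increasing (possible duplicate rows)"
                )
            series.append(
                ChannelSeries(
                    name,
                    t,
                    grp["value"].to_numpy(dtype=np.float64),
                    nominal_interval=nominal_interval,
                )
            )
        sessions.append(MonitoringSession.from_series(str(pid), series))
    return Cohort(tuple(sessions))


def cohort_to_frame(cohort: Cohort) -> pd.DataFrame:
    rows = {"patient_id": [], "channel": [], "t_seconds": [], "value": []}
    for session in cohort.sessions:
        for name in sorted(session.channels):
            s = session.channels[name]
            rows["patient_id"].append(np.repeat(session.patient_id, len(s)))
            rows["channel"].append(np.repeat(name, len(s)))
            rows["t_seconds"].append(s.timestamps)
            rows["value"].append(s.values)
    if not rows["patient_id"]:
        return pd.DataFrame(columns=list(REQUIRED_COLUMNS))
    return pd.DataFrame({k: np.concatenate(v) for k, v in rows.items()})


def write_cohort(cohort: Cohort, path, dialect: str = "csv"):
    """Write a cohort to a long-format file re-readable by :func:`read_cohort`.

    CSV floats are printed with shortest round-trip repr, so timestamps and
    values survive a write/read cycle bit-identically.
    """
    frame = cohort_to_frame(cohort)
    if dialect == "csv":
        # shortest round-trip repr keeps values bit-identical through read
        frame.to_csv(path, index=False, float_format=lambda x: repr(float(x)))
    elif dialect == "parquet":
        frame.to_parquet(path, index=False)
    else:
        raise ParameterError(f"unknown dialect {dialect!r}")
    return path


def moving_average(series: ChannelSeries, window_s: float) -> ChannelSeries:
    """Trailing moving average of width ``window_s`` within gap-free runs.

    Each output value is the arithmetic mean of the input samples whose
    timestamps lie in ``(t - window_s, t]`` *within the same gap-free run*;
    the window never spans a gap and output timestamps are unchanged.  With
    ``window_s`` equal to the nominal interval the window holds only the
    sample itself, so the operation is the identity.
    """
    if window_s <= 0:
        raise ParameterError("window_s must be > 0")
    if window_s < series.nominal_interval:
        raise ParameterError("window_s must be >= the nominal sampling interval")
    out = np.empty_like(series.values)
    for a, b in series.gap_runs():
        t = series.timestamps[a:b]
        csum = np.concatenate(([0.0], np.cumsum(series.values[a:b])))
        # first index with timestamp strictly inside the trailing window
        left = np.searchsorted(t, t - window_s, side="right")
        right = np.arange(1, b - a + 1)
        out[a:b] = (csum[right] - csum[left]) / (right - left)
    return replace(series, values=out)
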