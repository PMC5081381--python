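"""Multi-parameter alarm settings and total alarm-burden projection.

A settings profile assigns each vital-sign channel an optional high limit
(threshold + annunciation delay) and an optional low limit; an absent side
simply does not contribute.  The total burden is the sum over configured
channels of the per-channel alarm rates, computed at full precision and
rounded only for presentation — the printed per-channel figures therefore
need not sum exactly to the printed total.

The continual non-invasive blood-pressure (cNIBP) roll-up reported by
:func:`total_burden` combines the SBP and MAP channels, which is how a
high-systolic + low-mean settings pair is conventionally reported as a
single blood-pressure burden line.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import pandas as pd
import yaml

from .alarms import ThresholdSpec, alarm_rate
from .timeseries import Cohort, ParameterError, canonical_channel

__all__ = [
    "AlarmLimit",
    "ChannelSettings",
    "AlarmSettings",
    "BurdenReport",
    "ConfigurationError",
    "total_burden",
]


class ConfigurationError(ValueError):
    """A settings profile references a channel the cohort never monitored."""


@dataclass(frozen=True)
class AlarmLimit:
    threshold: float
    delay_s: float

    def __post_init__(self) -> None:
        if self.delay_s < 0:
            raise ParameterError("annunciation delay must be >= 0")


@dataclass(frozen=True)
class ChannelSettings:
    """High and/or low alarm limit for one channel; None means unused."""

    high: Optional[AlarmLimit] = None
    low: Optional[AlarmLimit] = None

    def __post_init__(self) -> None:
        if self.high is None and self.low is None:
            raise ParameterError("a channel settings entry needs at least one side")
        if (
            self.high is not None
            and self.low is not None
            and not self.low.threshold < self.high.threshold
        ):
            raise ParameterError("low threshold must be below high threshold")


@dataclass(frozen=True)
class AlarmSettings:
    """Per-channel alarm limits; channels absent from the map are unused."""

    channels: Mapping[str, ChannelSettings]

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "channels",
            {canonical_channel(ch): cs for ch, cs in self.channels.items()},
        )

    @classmethod
    def from_dict(cls, data: Mapping) -> "AlarmSettings":
        """Build from the settings-file mapping, e.g.
        ``{"HR": {"high": {"threshold": 150, "delay_s": 5}, "low": null}}``."""
        channels = {}
        for ch, sides in data.items():
            if sides is None:
                continue
            kwargs = {}
            for side in ("high", "low"):
                entry = sides.get(side)
                if entry is not None:
                    kwargs[side] = AlarmLimit(
                        float(entry["threshold"]), float(entry["delay_s"])
                    )
            if kwargs:
                channels[ch] = ChannelSettings(**kwargs)
        return cls(channels)

    @classmethod
    def from_yaml(cls, path) -> "AlarmSettings":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        out: dict = {}
        for ch, cs in self.channels.items():
            out[ch] = {
                side: (
                    None
                    if limit is None
                    else {"threshold": limit.threshold, "delay_s": limit.delay_s}
                )
                for side, limit in (("high", cs.high), ("low", cs.low))
            }
        return out

    def restricted_to(self, channels) -> "AlarmSettings":
        keep = {canonical_channel(c) for c in channels}
        return AlarmSettings({c: s for c, s in self.channels.items() if c in keep})


@dataclass(frozen=True)
class BurdenReport:
    """Per-channel and total projected alarm burden, alarms/patient/day.

    ``total`` is the sum of the unrounded per-channel rates; ``cnibp`` pools
    the SBP and MAP rows when either is configured, else None.
    """

    per_channel: Mapping[str, float]
    total: float
    cnibp: Optional[float] = None

    def to_frame(self, decimals: int | None = None) -> pd.DataFrame:
        rows = dict(self.per_channel)
        if self.cnibp is not None:
            rows["cNIBP"] = self.cnibp
        rows["Total"] = self.total
        frame = pd.DataFrame(
            {"rate_per_patient_day": pd.Series(rows)}
        ).rename_axis("channel")
        return frame.round(decimals) if decimals is not None else frame


def total_burden(cohort: Cohort, settings: AlarmSettings) -> BurdenReport:
    """Project the total multi-parameter alarm burden under a settings profile.

    Per-channel rate = low-side rate + high-side rate (skipping absent
    sides), each an independent pooled cohort rate with its own
    channel-specific monitored-time denominator; a patient who lacks a
    configured channel contributes neither alarms nor monitored time to that
    channel's rate.  A configured channel carried by no session at all is a
    configuration error.
    """
    per_channel: dict[str, float] = {}
    for ch, cs in settings.channels.items():
        if not cohort.sessions_with(ch):
            raise ConfigurationError(
                f"settings configure channel {ch} but no session in the cohort carries it"
            )
        rate = 0.0
        for direction, limit in (("low", cs.low), ("high", cs.high)):
            if limit is not None:
                rate += alarm_rate(
                    cohort, ThresholdSpec(ch, direction, limit.threshold), limit.delay_s
                )
        per_channel[ch] = rate
    cnibp = None
    if "SBP" in per_channel or "MAP" in per_channel:
        cnibp = per_channel.get("SBP", 0.0) + per_channel.get("MAP", 0.0)
    return BurdenReport(per_channel, float(sum(per_channel.values())), cnibp)
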