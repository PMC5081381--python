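"""Synthetic general-care-unit vital-sign cohort generator.

No public accession exists for a continual general-ward numeric database, so
this module synthesizes cohorts that pin exactly the two observables the
published record determines:

* **marginal distributions** — per-channel percentile anchors define a
  piecewise-linear quantile function (inverse CDF); per-patient baselines
  are drawn from it by inverse-transform sampling, so the pooled marginal
  reproduces the anchors up to the within-patient fluctuation;
* **excursion-duration structure** — transient threshold excursions arrive
  as a Poisson process and last a log-normal time whose two parameters are
  calibrated in closed form to two quantile constraints (by default 71 % of
  excursions resolve within 30 s and 95 % within 120 s).

Everything else is deliberately minimal: within-patient variability is a
stationary AR(1) (Ornstein-Uhlenbeck-like) fluctuation around the baseline,
channels are independent, and there is no circadian or disease structure.
During an excursion the value is held a fixed depth beyond the excursion's
reference threshold, so excursions are detectable by construction.

Reproducibility: one global seed drives a per-patient, per-channel
counter-based substream (numpy ``SeedSequence`` spawn keys), so identical
configurations yield bit-identical cohorts regardless of generation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml
from scipy import signal, stats

from . import reference
from .timeseries import (
    ChannelSeries,
    Cohort,
    MonitoringSession,
    ParameterError,
    canonical_channel,
)

__all__ = [
    "QuantileCurve",
    "fit_quantile_curve",
    "DurationModel",
    "calibrate_duration_model",
    "ExcursionModel",
    "ChannelModel",
    "GeneratorConfig",
    "generate_cohort",
    "default_generator_config",
    "excursion_study_config",
    "config_from_yaml",
]


# ---------------------------------------------------------------------------
# Quantile curves (piecewise-linear inverse CDF through percentile anchors)


@dataclass(frozen=True)
class QuantileCurve:
    """Piecewise-linear inverse CDF through (rank %, value) anchors.

    ``tail`` controls behaviour beyond the outermost anchors: ``flat`` holds
    the end anchor values constant (conservative extremes — the published
    tables give no data beyond the 1 % and 99 % ranks), ``linear`` continues
    the end segments' slopes to ranks 0 and 100.
    """

    channel: str
    ranks: tuple[float, ...]
    values: tuple[float, ...]
    tail: str = "flat"

    def __post_init__(self) -> None:
        object.__setattr__(self, "channel", canonical_channel(self.channel))
        ranks = tuple(float(r) for r in self.ranks)
        values = tuple(float(v) for v in self.values)
        if len(ranks) != len(values) or len(ranks) < 2:
            raise ParameterError("need >= 2 anchors with matching values")
        if any(not 0 <= r <= 100 for r in ranks):
            raise ParameterError("anchor ranks must lie in [0, 100]")
        if any(b <= a for a, b in zip(ranks, ranks[1:])):
            raise ParameterError("anchor ranks must be strictly increasing")
        if any(b < a for a, b in zip(values, values[1:])):
            raise ParameterError("anchor values must be non-decreasing")
        if self.tail not in ("flat", "linear"):
            raise ParameterError("tail must be 'flat' or 'linear'")
        object.__setattr__(self, "ranks", ranks)
        object.__setattr__(self, "values", values)

    def _knots(self) -> tuple[np.ndarray, np.ndarray]:
        """Probability/value knots covering the full [0, 1] domain."""
        p = np.asarray(self.ranks) / 100.0
        v = np.asarray(self.values, dtype=float)
        if p[0] > 0:
            v0 = v[0] if self.tail == "flat" else v[0] - (v[1] - v[0]) / (p[1] - p[0]) * p[0]
            p, v = np.concatenate(([0.0], p)), np.concatenate(([min(v0, v[0])], v))
        if p[-1] < 1:
            if self.tail == "flat":
                vn = v[-1]
            else:
                vn = v[-1] + (v[-1] - v[-2]) / (p[-1] - p[-2]) * (1 - p[-1])
            p, v = np.concatenate((p, [1.0])), np.concatenate((v, [max(vn, v[-1])]))
        return p, v

    def ppf(self, u) -> np.ndarray:
        """Evaluate the inverse CDF at probabilities ``u`` in [0, 1]."""
        p, v = self._knots()
        return np.interp(np.asarray(u, dtype=float), p, v)

    def mean(self) -> float:
        """Exact mean of the implied distribution: the integral of the
        piecewise-linear quantile function over [0, 1] (trapezoid on knots)."""
        p, v = self._knots()
        return float(np.sum(np.diff(p) * (v[:-1] + v[1:]) / 2.0))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Inverse-transform sampling of n values."""
        return self.ppf(rng.uniform(0.0, 1.0, size=n))


def fit_quantile_curve(
    anchors: Mapping[float, float], channel: str = "HR", tail: str = "flat"
) -> QuantileCurve:
    """Build a QuantileCurve from a {rank % -> value} anchor map."""
    ranks = sorted(float(r) for r in anchors)
    return QuantileCurve(
        channel, tuple(ranks), tuple(float(anchors[r]) for r in ranks), tail
    )


# ---------------------------------------------------------------------------
# Log-normal excursion-duration model calibrated to two quantile constraints


@dataclass(frozen=True)
class DurationModel:
    """Log-normal excursion-duration distribution (seconds)."""

    log_mean: float
    log_sd: float

    def cdf(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return stats.norm.cdf((np.log(t) - self.log_mean) / self.log_sd)

    def quantile(self, p) -> np.ndarray:
        return np.exp(self.log_mean + self.log_sd * stats.norm.ppf(p))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.lognormal(self.log_mean, self.log_sd, size=n)

    @property
    def mean_s(self) -> float:
        return math.exp(self.log_mean + self.log_sd**2 / 2.0)


def calibrate_duration_model(
    q1: tuple[float, float], q2: tuple[float, float]
) -> DurationModel:
    """Solve the two-parameter log-normal hitting two quantile constraints.

    Each constraint is ``(t_seconds, probability)``: the CDF at ``t`` must
    equal ``probability`` exactly.  Closed form:
    ``log_sd = (ln t2 - ln t1) / (z2 - z1)`` and
    ``log_mean = ln t1 - z1 * log_sd`` with z the standard-normal quantiles.
    """
    (t1, p1), (t2, p2) = q1, q2
    if not (0 < p1 < 1 and 0 < p2 < 1):
        raise ParameterError("constraint probabilities must lie in (0, 1)")
    if p1 == p2:
        raise ParameterError("constraint probabilities must differ")
    if not (t1 < t2 and p1 < p2):
        raise ParameterError("constraints must be increasing in both coordinates")
    z1, z2 = stats.norm.ppf([p1, p2])
    log_sd = (math.log(t2) - math.log(t1)) / (z2 - z1)
    log_mean = math.log(t1) - z1 * log_sd
    return DurationModel(log_mean, log_sd)


# ---------------------------------------------------------------------------
# Generator configuration


@dataclass(frozen=True)
class ExcursionModel:
    """One stream of transient threshold excursions on a channel.

    Excursions arrive as a Poisson process at ``rate_per_hour``; each lasts a
    time drawn from ``duration`` and drives the value to a fixed level a
    ``depth`` beyond ``reference`` on the given side (reference - depth for
    ``low``, reference + depth for ``high``), guaranteeing detectability at
    any threshold at or inside the reference.
    """

    direction: str
    reference: float
    depth: float
    rate_per_hour: float
    duration: DurationModel

    def __post_init__(self) -> None:
        if self.direction not in ("low", "high"):
            raise ParameterError("excursion direction must be 'low' or 'high'")
        if self.depth <= 0 or self.rate_per_hour < 0:
            raise ParameterError("depth must be > 0 and rate_per_hour >= 0")

    @property
    def level(self) -> float:
        return (
            self.reference - self.depth
            if self.direction == "low"
            else self.reference + self.depth
        )


@dataclass(frozen=True)
class ChannelModel:
    """Generative model for one channel: baseline quantile curve,
    stationary AR(1) within-patient fluctuation, excursion streams and
    physical clipping bounds."""

    curve: QuantileCurve
    noise_sd: float = 0.0
    noise_tau_s: float = 300.0
    excursions: tuple[ExcursionModel, ...] = ()
    clip: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.noise_tau_s <= 0:
            raise ParameterError("noise_sd must be >= 0 and noise_tau_s > 0")
        object.__setattr__(self, "excursions", tuple(self.excursions))


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort-level generator settings.

    ``gap_rate_per_hour``/``gap_duration_s`` optionally delete sample spans
    to emulate monitoring dropouts (off by default).  Identical seeds yield
    bit-identical cohorts.
    """

    channels: Mapping[str, ChannelModel]
    n_patients: int
    hours: float
    nominal_interval: float = 1.0
    seed: int = 0
    gap_rate_per_hour: float = 0.0
    gap_duration_s: float = 60.0
    #: Stratify baseline quantile ranks across the cohort (patient p draws
    #: uniformly within [p/n, (p+1)/n]): the pooled marginal then matches the
    #: quantile curve to O(1/n) instead of the O(1/sqrt(n)) of iid draws.
    stratify_baselines: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "channels",
            {canonical_channel(ch): m for ch, m in self.channels.items()},
        )


# ---------------------------------------------------------------------------
# Generation

#: Dead time between excursion events; two nominal intervals so that
#: consecutive excursions can never merge into one detected episode.
_EVENT_GUARD_INTERVALS = 2


def _substream(seed: int, patient: int, channel_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(patient, channel_index))
    )


def _ar1_noise(rng, n: int, sd: float, tau_s: float, dt: float) -> np.ndarray:
    """Stationary zero-mean AR(1) with marginal sd and correlation time tau."""
    if sd == 0.0 or n == 0:
        return np.zeros(n)
    rho = math.exp(-dt / tau_s)
    eps = rng.standard_normal(n)
    drive = eps * (sd * math.sqrt(1.0 - rho * rho))
    drive[0] = eps[0] * sd  # stationary start
    return signal.lfilter([1.0], [1.0, -rho], drive)


def _event_times(
    rng, model: ExcursionModel, total_s: float, guard_s: float
) -> tuple[np.ndarray, np.ndarray]:
    """Poisson arrivals thinned to non-overlapping (start, duration) pairs."""
    if model.rate_per_hour == 0:
        return np.empty(0), np.empty(0)
    mean_gap = 3600.0 / model.rate_per_hour
    starts, durations = [], []
    t = rng.exponential(mean_gap)
    while t < total_s:
        d = float(model.duration.sample(rng, 1)[0])
        starts.append(t)
        durations.append(d)
        t = t + d + guard_s + rng.exponential(mean_gap)
    return np.asarray(starts), np.asarray(durations)


def _generate_channel(
    rng, name: str, model: ChannelModel, hours: float, dt: float,
    baseline_stratum: tuple[int, int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    n = int(round(hours * 3600.0 / dt))
    if n == 0:
        raise ParameterError("monitored duration shorter than one sample")
    t = np.arange(n) * dt
    u = rng.uniform()
    if baseline_stratum is not None:
        p, n_pat = baseline_stratum
        u = (p + u) / n_pat
    baseline = float(model.curve.ppf(u))
    values = baseline + _ar1_noise(rng, n, model.noise_sd, model.noise_tau_s, dt)
    guard = _EVENT_GUARD_INTERVALS * dt
    for exc in model.excursions:
        starts, durations = _event_times(rng, exc, n * dt, guard)
        for s, d in zip(starts, durations):
            i0 = int(math.ceil(s / dt))
            i1 = min(int(math.ceil((s + d) / dt)), n)
            values[i0:i1] = exc.level
    if model.clip is not None:
        np.clip(values, model.clip[0], model.clip[1], out=values)
    return t, values


def _inject_gaps(rng, t, v, rate_per_hour: float, gap_s: float) -> tuple:
    if rate_per_hour <= 0 or t.size == 0:
        return t, v
    keep = np.ones(t.size, dtype=bool)
    total = t[-1] + (t[1] - t[0] if t.size > 1 else 0.0)
    s = rng.exponential(3600.0 / rate_per_hour)
    while s < total:
        keep &= ~((t >= s) & (t < s + gap_s))
        s += gap_s + rng.exponential(3600.0 / rate_per_hour)
    return t[keep], v[keep]


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Generate a fully reproducible synthetic cohort from a configuration."""
    if config.n_patients <= 0 or config.hours <= 0:
        raise ParameterError("n_patients and hours must be positive")
    if not config.channels:
        raise ParameterError("at least one channel model is required")
    names = sorted(config.channels)
    sessions = []
    for p in range(config.n_patients):
        series = []
        for ci, name in enumerate(names):
            rng = _substream(config.seed, p, ci)
            t, v = _generate_channel(
                rng, name, config.channels[name], config.hours,
                config.nominal_interval,
                baseline_stratum=(p, config.n_patients)
                if config.stratify_baselines
                else None,
            )
            t, v = _inject_gaps(
                rng, t, v, config.gap_rate_per_hour, config.gap_duration_s
            )
            series.append(
                ChannelSeries(name, t, v, nominal_interval=config.nominal_interval)
            )
        sessions.append(MonitoringSession.from_series(f"SYN{p:05d}", series))
    return Cohort(tuple(sessions))


# ---------------------------------------------------------------------------
# Default configuration: published percentile anchors + calibrated durations

#: Synthetic MAP percentile anchors (mmHg).  The published distribution
#: tables carry no MAP row, but the default multi-parameter settings profile
#: alarms on low MAP; these anchors are this package's own plausible
#: general-care-unit profile, not published data.
SYNTHETIC_MAP_ANCHORS: dict[float, float] = {
    1: 55, 5: 62, 10: 66, 50: 85, 90: 104, 95: 110, 99: 122,
}

#: Within-patient fluctuation scale (channel units) and excursion streams
#: (direction, reference threshold, depth beyond it) for the default config.
_DEFAULT_NOISE_SD = {"HR": 1.5, "RR": 0.75, "SPO2": 0.5, "SBP": 2.5, "MAP": 2.0}
_DEFAULT_EXCURSIONS = {
    "HR": (("low", 30.0, 5.0), ("high", 150.0, 10.0)),
    "RR": (("low", 4.0, 2.0), ("high", 35.0, 5.0)),
    "SPO2": (("low", 85.0, 5.0),),
    "SBP": (("high", 190.0, 10.0),),
    "MAP": (("low", 60.0, 5.0),),
}
_DEFAULT_CLIP = {"SPO2": (1.0, 100.0)}
#: Excursion arrival rate, events/hour per stream (artifact default — the
#: published record reports no excursion frequency).
DEFAULT_EXCURSION_RATE_PER_HOUR = 0.2


def default_duration_model() -> DurationModel:
    """Log-normal durations calibrated to the published excursion quantiles
    (71 % resolve within 30 s, 95 % within 120 s)."""
    q1, q2 = reference.EXCURSION_DURATION_QUANTILES
    return calibrate_duration_model(q1, q2)


def default_generator_config(
    n_patients: int = 100,
    hours: float = 24.0,
    nominal_interval: float = 1.0,
    seed: int = 0,
    channels: Sequence[str] | None = None,
    excursion_rate_per_hour: float = DEFAULT_EXCURSION_RATE_PER_HOUR,
) -> GeneratorConfig:
    """Default cohort configuration: baselines anchored to the published
    cloud-database percentile rows (plus the synthetic MAP anchors),
    AR(1) fluctuation, and excursion streams aimed at the default alarm
    thresholds with log-normal durations calibrated to the published
    resolution quantiles."""
    duration = default_duration_model()
    anchor_sets: dict[str, Mapping[float, float]] = dict(reference.CLOUD_PERCENTILES)
    anchor_sets["MAP"] = SYNTHETIC_MAP_ANCHORS
    names = [canonical_channel(c) for c in channels] if channels else sorted(anchor_sets)
    models = {}
    for name in names:
        if name not in anchor_sets:
            raise ParameterError(f"no default anchors for channel {name}")
        excs = tuple(
            ExcursionModel(direction, ref, depth, excursion_rate_per_hour, duration)
            for direction, ref, depth in _DEFAULT_EXCURSIONS.get(name, ())
        )
        models[name] = ChannelModel(
            curve=fit_quantile_curve(anchor_sets[name], channel=name, tail="flat"),
            noise_sd=_DEFAULT_NOISE_SD.get(name, 0.0),
            noise_tau_s=300.0,
            excursions=excs,
            clip=_DEFAULT_CLIP.get(name),
        )
    return GeneratorConfig(
        channels=models,
        n_patients=n_patients,
        hours=hours,
        nominal_interval=nominal_interval,
        seed=seed,
    )


def excursion_study_config(
    n_patients: int = 150,
    hours: float = 24.0,
    seed: int = 0,
    rate_per_hour: float = 1.5,
) -> GeneratorConfig:
    """Single-channel configuration for measuring excursion-duration recovery
    end to end (generate -> detect -> annunciate).

    Heart-rate baselines come from the published percentile anchors, with a
    single low-excursion stream against the default low-HR alarm threshold
    (30 beats/min); the baseline floor (50 beats/min) and small fluctuation
    guarantee that every detected episode is an excursion, so the measured
    duration distribution isolates the calibrated log-normal model.  The
    arrival rate is sized so a desk-scale cohort yields several thousand
    episodes, the scale at which the published resolution fractions are
    quoted to percentage-point precision.
    """
    duration = default_duration_model()
    curve = fit_quantile_curve(reference.CLOUD_PERCENTILES["HR"], channel="HR")
    model = ChannelModel(
        curve=curve,
        noise_sd=_DEFAULT_NOISE_SD["HR"],
        noise_tau_s=300.0,
        excursions=(ExcursionModel("low", 30.0, 5.0, rate_per_hour, duration),),
    )
    return GeneratorConfig(
        channels={"HR": model}, n_patients=n_patients, hours=hours, seed=seed
    )


# ---------------------------------------------------------------------------
# YAML configuration loading (CLI support)


def config_from_yaml(path, **overrides) -> GeneratorConfig:
    """Load a GeneratorConfig from a YAML file.

    Schema mirrors the dataclasses::

        n_patients: 100
        hours: 24
        nominal_interval: 1.0
        seed: 0
        channels:
          HR:
            anchors: {1: 50, 5: 58, 50: 81, 99: 128}
            tail: flat
            noise_sd: 3.0
            noise_tau_s: 300.0
            clip: null
            excursions:
              - {direction: low, reference: 30, depth: 5, rate_per_hour: 0.2}

    An excursion entry may carry ``duration: {log_mean: ..., log_sd: ...}``
    or ``duration_quantiles: [[30, 0.71], [120, 0.95]]``; it defaults to the
    published-quantile calibration.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    models = {}
    for name, spec in (raw.get("channels") or {}).items():
        curve = fit_quantile_curve(
            {float(r): float(v) for r, v in spec["anchors"].items()},
            channel=name,
            tail=spec.get("tail", "flat"),
        )
        excs = []
        for e in spec.get("excursions") or []:
            if "duration" in e:
                dur = DurationModel(
                    float(e["duration"]["log_mean"]), float(e["duration"]["log_sd"])
                )
            elif "duration_quantiles" in e:
                (t1, p1), (t2, p2) = e["duration_quantiles"]
                dur = calibrate_duration_model((float(t1), float(p1)), (float(t2), float(p2)))
            else:
                dur = default_duration_model()
            excs.append(
                ExcursionModel(
                    e["direction"], float(e["reference"]), float(e["depth"]),
                    float(e["rate_per_hour"]), dur,
                )
            )
        clip = spec.get("clip")
        models[name] = ChannelModel(
            curve=curve,
            noise_sd=float(spec.get("noise_sd", 0.0)),
            noise_tau_s=float(spec.get("noise_tau_s", 300.0)),
            excursions=tuple(excs),
            clip=tuple(map(float, clip)) if clip else None,
        )
    kwargs = dict(
        channels=models,
        n_patients=int(raw.get("n_patients", 100)),
        hours=float(raw.get("hours", 24.0)),
        nominal_interval=float(raw.get("nominal_interval", 1.0)),
        seed=int(raw.get("seed", 0)),
        gap_rate_per_hour=float(raw.get("gap_rate_per_hour", 0.0)),
        gap_duration_s=float(raw.get("gap_duration_s", 60.0)),
    )
    kwargs.update(overrides)
    return GeneratorConfig(**kwargs)
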