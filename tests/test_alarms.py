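"""Episode detection, annunciation-delay filtering and rate grids."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from alarmsim import (
    AlarmEpisode,
    ChannelSeries,
    Cohort,
    MonitoringSession,
    ParameterError,
    ThresholdSpec,
    UndefinedRateError,
    alarm_rate,
    annunciate,
    cohort_episodes,
    detect_episodes,
    duration_distribution,
    rate_grid,
)

from conftest import make_cohort, make_series


def naive_scan(values, spec, interval=1.0):
    """Per-sample reference scan over a gap-free series: (duration, censored)."""
    episodes, run = [], 0
    for v in values:
        hit = (v < spec.threshold) if spec.direction == "low" else (v > spec.threshold)
        if spec.inclusive:
            hit = (v <= spec.threshold) if spec.direction == "low" else (v >= spec.threshold)
        if hit:
            run += 1
        elif run:
            episodes.append((run * interval, False))
            run = 0
    if run:
        episodes.append((run * interval, True))
    return episodes


class TestDetectEpisodes:
    def test_never_violating_series_has_no_episodes(self):
        s = make_series(np.full(100, 95.0), channel="SPO2")
        assert detect_episodes(s, ThresholdSpec("SPO2", "low", 85)) == []

    def test_always_violating_series_is_one_censored_episode(self):
        s = make_series(np.full(600, 80.0), channel="SPO2")
        (ep,) = detect_episodes(s, ThresholdSpec("SPO2", "low", 85))
        assert ep.duration_s == 600.0
        assert ep.censored

    def test_two_episode_example(self, toy_spo2_cohort):
        eps = cohort_episodes(toy_spo2_cohort, ThresholdSpec("SPO2", "low", 85))
        assert [(e.start_s, e.duration_s, e.censored) for e in eps] == [
            (2.0, 3.0, False),
            (6.0, 1.0, False),
        ]

    def test_threshold_itself_is_acceptable_unless_inclusive(self):
        s = make_series([85.0, 85.0], channel="SPO2")
        assert detect_episodes(s, ThresholdSpec("SPO2", "low", 85)) == []
        eps = detect_episodes(s, ThresholdSpec("SPO2", "low", 85, inclusive=True))
        assert [e.duration_s for e in eps] == [2.0]

    def test_episode_censored_at_gap_and_never_spans_it(self):
        t = np.array([0, 1, 2, 50, 51], float)
        v = np.array([80, 80, 80, 80, 95], float)
        eps = detect_episodes(
            ChannelSeries("SPO2", t, v), ThresholdSpec("SPO2", "low", 85)
        )
        assert [(e.duration_s, e.censored) for e in eps] == [(3.0, True), (1.0, False)]

    def test_channel_mismatch_rejected(self):
        with pytest.raises(ParameterError, match="mismatch"):
            detect_episodes(make_series([60.0]), ThresholdSpec("SPO2", "low", 85))

    @given(
        values=st.lists(
            st.sampled_from([83.0, 84.9, 85.0, 85.1, 90.0]), min_size=1, max_size=1000
        ),
        direction=st.sampled_from(["low", "high"]),
        inclusive=st.booleans(),
    )
    def test_matches_naive_scan(self, values, direction, inclusive):
        """Vectorized detection agrees with a per-sample scan, both directions
        and both boundary conventions, on values straddling the threshold."""
        spec = ThresholdSpec("SPO2", direction, 85.0, inclusive=inclusive)
        s = make_series(values, channel="SPO2")
        got = [(e.duration_s, e.censored) for e in detect_episodes(s, spec)]
        assert got == naive_scan(values, spec)


def _episodes(durations, censored=False):
    return [
        AlarmEpisode("P", "SPO2", "low", float(i * 1000), float(d), censored)
        for i, d in enumerate(durations)
    ]


class TestAnnunciate:
    def test_zero_delay_returns_everything(self):
        eps = _episodes([1, 5, 600])
        assert annunciate(eps, 0.0) == eps

    def test_duration_filter_example(self):
        eps = _episodes([3.0, 1.0])
        assert [e.duration_s for e in annunciate(eps, 2.0)] == [3.0]

    def test_all_short_episodes_fully_suppressed(self):
        assert annunciate(_episodes([5, 10, 30]), 120.0) == []

    def test_censored_episode_needs_observed_duration_to_reach_delay(self):
        eps = _episodes([100.0], censored=True)
        assert annunciate(eps, 120.0) == []
        assert annunciate(eps, 100.0) == eps

    def test_negative_delay_rejected(self):
        with pytest.raises(ParameterError):
            annunciate([], -1.0)

    @given(
        durations=st.lists(st.floats(0.5, 500.0), max_size=30),
        d1=st.floats(0, 200),
        d2=st.floats(0, 200),
    )
    def test_composition_is_max_of_delays(self, durations, d1, d2):
        eps = _episodes(durations)
        assert annunciate(annunciate(eps, d1), d2) == annunciate(eps, max(d1, d2))


class TestAlarmRate:
    def test_no_violations_is_zero_rate(self):
        cohort = make_cohort({"P1": [make_series(np.full(50, 97.0), channel="SPO2")]})
        assert alarm_rate(cohort, ThresholdSpec("SPO2", "low", 85), 30.0) == 0.0

    def test_unit_denominator(self):
        """2 annunciated alarms over exactly 24 h -> 2.0 alarms/patient/day."""
        v = np.full(86400, 95.0)
        v[100:160] = 80.0
        v[5000:5030] = 80.0
        cohort = make_cohort({"P1": [make_series(v, channel="SPO2")]})
        assert alarm_rate(cohort, ThresholdSpec("SPO2", "low", 85), 10.0) == pytest.approx(2.0)

    def test_pooled_patient_time(self):
        """3 alarms over 36 h pooled across 2 patients -> 3/1.5 = 2.0."""
        v1 = np.full(86400, 95.0)
        v1[0:60] = 80.0
        v1[1000:1060] = 80.0
        v2 = np.full(43200, 95.0)
        v2[500:560] = 80.0
        cohort = make_cohort(
            {
                "P1": [make_series(v1, channel="SPO2")],
                "P2": [make_series(v2, channel="SPO2")],
            }
        )
        assert alarm_rate(cohort, ThresholdSpec("SPO2", "low", 85), 30.0) == pytest.approx(2.0)

    def test_zero_monitored_time_is_undefined(self):
        cohort = make_cohort({"P1": [make_series([70.0], channel="HR")]})
        with pytest.raises(UndefinedRateError):
            alarm_rate(cohort, ThresholdSpec("SPO2", "low", 85), 0.0)

    def test_invariant_under_session_split_at_gap(self, rng):
        v = rng.uniform(80, 100, size=400)
        t = np.concatenate([np.arange(200.0), 1000 + np.arange(200.0)])
        whole = make_cohort({"P1": [ChannelSeries("SPO2", t, v)]})
        split = Cohort(
            (
                MonitoringSession.from_series(
                    "P1", [ChannelSeries("SPO2", t[:200], v[:200])]
                ),
                MonitoringSession.from_series(
                    "P1", [ChannelSeries("SPO2", t[200:], v[200:])]
                ),
            )
        )
        spec = ThresholdSpec("SPO2", "low", 90)
        for delay in (0.0, 5.0, 30.0):
            assert alarm_rate(whole, spec, delay) == pytest.approx(
                alarm_rate(split, spec, delay)
            )


class TestRateGrid:
    def test_cells_match_standalone_alarm_rate(self, rng):
        v = rng.uniform(75, 100, size=3000)
        cohort = make_cohort({"P1": [make_series(v, channel="SPO2")]})
        thresholds, delays = [85.0, 90.0], [0.0, 3.0]
        g = rate_grid(cohort, "SPO2", "low", thresholds, delays)
        for d in delays:
            for t in thresholds:
                assert g.cell(d, t) == pytest.approx(
                    alarm_rate(cohort, ThresholdSpec("SPO2", "low", t), d)
                )

    def test_no_violations_gives_all_zero_grid(self):
        cohort = make_cohort({"P1": [make_series(np.full(100, 99.0), channel="SPO2")]})
        g = rate_grid(cohort, "SPO2", "low", [85, 90], [0, 30])
        assert not g.rates.any()

    def test_unsorted_inputs_rejected(self, toy_spo2_cohort):
        with pytest.raises(ParameterError):
            rate_grid(toy_spo2_cohort, "SPO2", "low", [90, 85], [0])
        with pytest.raises(ParameterError):
            rate_grid(toy_spo2_cohort, "SPO2", "low", [85], [])

    @pytest.mark.parametrize("direction", ["low", "high"])
    def test_monotone_in_delay_and_threshold(self, rng, direction):
        """Columns fall as delay grows; with thresholds in the distribution
        tail (where settings live), low-direction rates rise with the
        threshold and high-direction rates fall as the threshold rises."""
        v = 93 + 3 * rng.standard_normal(20000)
        cohort = make_cohort({"P1": [make_series(np.clip(v, 1, 100), channel="SPO2")]})
        thresholds = (
            [78.0, 82.0, 86.0] if direction == "low" else [96.0, 98.0, 99.5]
        )
        g = rate_grid(cohort, "SPO2", direction, thresholds, [0.0, 2.0, 5.0, 10.0])
        assert (np.diff(g.rates, axis=0) <= 1e-12).all()
        by_threshold = np.diff(g.rates, axis=1)
        if direction == "low":
            assert (by_threshold >= -1e-12).all()
        else:
            assert (by_threshold <= 1e-12).all()


class TestDurationDistribution:
    def test_suppressed_fraction_examples(self):
        hist = duration_distribution(_episodes([10, 50, 200]), [0, 60, 300], 120.0)
        assert hist.suppressed_fraction == pytest.approx(2 / 3)
        assert hist.counts == (2, 1)
        # only bins entirely at/above the delay are flagged annunciated
        assert hist.annunciated_bins == (False, False)
        aligned = duration_distribution(_episodes([10, 50, 200]), [0, 120, 600], 120.0)
        assert aligned.annunciated_bins == (False, True)

        all_short = duration_distribution(_episodes([10.0] * 7), [0, 30], 120.0)
        assert all_short.suppressed_fraction == 1.0

    def test_empty_episode_list_flagged_undefined(self):
        hist = duration_distribution([], [0, 60], 120.0)
        assert hist.suppressed_fraction is None
        assert hist.counts == (0,)

    def test_bad_bin_edges_rejected(self):
        with pytest.raises(ParameterError):
            duration_distribution([], [60, 0], 120.0)
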