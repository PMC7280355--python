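"""Stimulus-duration pipeline: event detection, matching, frame statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from _oracles import percent_exact_recount
from chronobench.emulator import DeviceProfile, FrameDist, build_profile, generate_presentation_schedule, render_trace
from chronobench.exp1 import (
    detect_events,
    frame_difference_histogram,
    internal_agreement,
    match_trials,
    percent_exact,
    to_frames,
)

FRAME_MS = 1000.0 / 60.0


class TestDetectEvents:
    def test_single_square_pulse(self, make_trace):
        trace = make_trace([(100.0, 250.0)], total_ms=600.0)
        events = detect_events(trace)
        assert len(events) == 1
        period = 1000.0 / trace.sample_hz
        assert events.loc[0, "duration_ms"] == pytest.approx(250.0, abs=period + 1e-9)

    def test_all_zero_trace_has_no_events(self, make_trace):
        assert detect_events(make_trace([], total_ms=200.0)).empty

    def test_two_pulses_are_ordered(self, make_trace):
        trace = make_trace([(50.0, 100.0), (300.0, 50.0)], total_ms=500.0)
        events = detect_events(trace)
        assert len(events) == 2
        assert events["onset_ms"].is_monotonic_increasing
        assert (events["offset_ms"] > events["onset_ms"]).all()

    def test_single_sample_glitch_is_suppressed(self, make_trace):
        trace = make_trace([(100.0, 0.3), (200.0, 50.0)], total_ms=400.0)
        events = detect_events(trace)
        assert len(events) == 1
        assert events.loc[0, "onset_ms"] == pytest.approx(200.0, abs=0.5)

    def test_empty_trace_rejected(self, make_trace):
        from chronobench.emulator import SensorTrace

        with pytest.raises(ValueError):
            detect_events(SensorTrace(np.array([]), np.array([]), 3000.0))


class TestToFrames:
    @pytest.mark.parametrize(
        "duration,expected",
        [(16.9, 1), (33.33, 2), (0.0, 0), (250.0, 15), (25.0, 2)],  # 25 ms = 1.5 frames, half rounds up
    )
    def test_quantization(self, duration, expected):
        assert to_frames(duration, 60.0) == expected

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError):
            to_frames(-1.0, 60.0)

    @given(st.integers(min_value=0, max_value=100))
    def test_exact_frame_multiples_round_trip(self, k):
        assert to_frames(k * FRAME_MS, 60.0) == k


@pytest.fixture(scope="module")
def perfect_matched():
    sched = generate_presentation_schedule(0)
    trace, log = render_trace(sched, build_profile("perfect"), seed=0,
                              sequences=range(4))
    return match_trials(detect_events(trace), log)


class TestMatchTrials:
    def test_perfect_rendering_fully_valid_with_zero_differences(self, perfect_matched):
        m = perfect_matched
        assert m["valid"].all()
        assert (m["frame_diff"] == 0).all()

    def test_conservation_valid_plus_flagged_equals_scheduled(self):
        profile = DeviceProfile(name="omit", omit_prob=0.1)
        sched = generate_presentation_schedule(0)
        trace, log = render_trace(sched, profile, seed=4, sequences=range(4))
        m = match_trials(detect_events(trace), log)
        assert len(m) == len(log)
        assert m["valid"].sum() + (~m["valid"]).sum() == len(log)

    def test_omitted_stimuli_flagged_as_missing(self):
        profile = DeviceProfile(name="omit", omit_prob=0.08)
        sched = generate_presentation_schedule(0)
        trace, log = render_trace(sched, profile, seed=11, sequences=range(4))
        m = match_trials(detect_events(trace), log)
        omitted = m["true_omitted"].astype(bool)
        assert omitted.any()
        assert (m.loc[omitted, "reason"] == "stimulus_missing").all()
        assert m.loc[~omitted, "valid"].all()

    def test_shortened_intertrial_pulse_flags_whole_sequence(self, make_trace):
        # two-trial log; the second trial's marker pulse is implausibly short
        log = pd.DataFrame(
            {
                "sequence": [0, 0],
                "trial": [0, 1],
                "timing": ["raf", "raf"],
                "presentation": ["opacity", "opacity"],
                "requested_frames": [15, 15],
                "raf_before_created": [250.0, 250.0],
            }
        )
        epochs = [
            (400.0, 400.0), (1200.0, 250.0),          # trial 0: marker + stimulus
            (2250.0, 100.0), (2750.0, 250.0),         # trial 1: short marker + stimulus
        ]
        trace = make_trace(epochs, total_ms=3600.0)
        m = match_trials(detect_events(trace), log)
        assert not m["valid"].any()
        assert set(m["reason"]) <= {"implausible_demarcation", "alignment_failed"}
        assert "implausible_demarcation" in set(m["reason"])


class TestSummaries:
    def test_percent_exact_simple_counts(self):
        trials = pd.DataFrame(
            {"timing": "raf", "presentation": "opacity", "frame_diff": [0, 0, 1, 0]}
        )
        out = percent_exact(trials)
        assert out.loc[0, "percent_exact"] == pytest.approx(75.0)
        all_zero = percent_exact(trials.assign(frame_diff=0))
        assert all_zero.loc[0, "percent_exact"] == pytest.approx(100.0)

    @given(
        st.lists(
            st.tuples(st.sampled_from(["css", "raf"]), st.integers(-2, 2)),
            min_size=1,
            max_size=60,
        )
    )
    def test_percent_exact_matches_brute_force_recount(self, rows):
        trials = pd.DataFrame(
            {"timing": [t for t, _ in rows], "frame_diff": [d for _, d in rows]}
        )
        out = percent_exact(trials, groupby=("timing",))
        expected = percent_exact_recount(trials, ("timing",))
        assert len(out) == len(expected)
        for _, row in out.iterrows():
            assert row["percent_exact"] == pytest.approx(expected[(row["timing"],)])

    def test_internal_agreement_identity_and_offset(self):
        trials = pd.DataFrame(
            {
                "timing": "raf",
                "presentation": "opacity",
                "realized_frames": [1.0, 3.0, 6.0, 15.0],
                "raf_before_created": [f * FRAME_MS for f in (1, 3, 6, 15)],
            }
        )
        perfect = internal_agreement(trials)
        assert perfect.loc[0, "percent_agree"] == pytest.approx(100.0)
        shifted = trials.assign(
            raf_before_created=trials["raf_before_created"] + FRAME_MS
        )
        assert internal_agreement(shifted).loc[0, "percent_agree"] == pytest.approx(0.0)

    def test_internal_agreement_unknown_measure_rejected(self):
        with pytest.raises(KeyError, match="raf_before_created"):
            internal_agreement(pd.DataFrame(), measure="wall_clock")

    def test_internal_agreement_recovers_programmed_error_rate(self):
        profile = DeviceProfile(
            name="fuzzy_internal",
            internal_error_dists={
                "raf_before_created": FrameDist.from_dict({-1: 0.1, 0: 0.8, 1: 0.1})
            },
        )
        sched = generate_presentation_schedule(0)
        trace, log = render_trace(sched, profile, seed=6, sequences=range(10))
        m = match_trials(detect_events(trace), log)
        out = internal_agreement(m[m["valid"]], groupby=())
        # binomial 99% band around 80% at n=250
        n = out.loc[0, "n"]
        half = 100 * 2.576 * np.sqrt(0.8 * 0.2 / n)
        assert abs(out.loc[0, "percent_agree"] - 80.0) < half

    def test_histogram_conserves_counts_and_pools_extremes(self):
        trials = pd.DataFrame(
            {
                "timing": "raf",
                "presentation": "opacity",
                "frame_diff": [-7, -2, 0, 0, 1, 9],
            }
        )
        hist = frame_difference_histogram(trials)
        row = hist.iloc[0]
        assert sum(row[c] for c in range(-4, 5)) == len(trials)
        assert row[-4] == 1 and row[4] == 1  # pooled open-ended bins
        assert row[-2] == 1 and row[0] == 2 and row[1] == 1

    def test_css_plus_one_mass_concentrates_at_plus_one(self):
        sched = generate_presentation_schedule(0)
        trace, log = render_trace(sched, build_profile("css_plus_one"), seed=7,
                                  sequences=range(4))
        m = match_trials(detect_events(trace), log)
        hist = frame_difference_histogram(m[m["valid"]], groupby=("timing",))
        css = hist[hist["timing"] == "css"].iloc[0]
        assert css[1] == sum(css[c] for c in range(-4, 5))
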