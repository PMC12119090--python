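"""Event-to-series conversion: alternation, masking, histograms."""

import numpy as np
import pytest

from dyadtheta.behavior import (
    binary_attention_series,
    duration_histogram,
    duration_series,
    events_from_binary,
)
from dyadtheta.events import LookEvent, frame_to_events, events_to_frame


def ev(onset, offset, category="object1", actor="infant"):
    return LookEvent(actor, onset, offset, category)


class TestBinaryAttention:
    def test_alternation_pattern_forced_by_convention(self):
        events = [ev(0, 1.0), ev(1.0, 1.5, "partner"), ev(1.5, 3.0, "offtask")]
        series = binary_attention_series(events, 3.0)
        assert np.all(series.values[0:50] == 0)
        assert np.all(series.values[50:75] == 1)
        assert np.all(series.values[75:150] == 0)

    def test_uncodable_masks_itself_and_both_neighbours(self):
        events = [
            ev(0, 1.0), ev(1.0, 2.0, "uncodable"), ev(2.0, 3.0), ev(3.0, 4.0),
        ]
        series = binary_attention_series(events, 4.0)
        assert np.all(np.isnan(series.values[:150]))  # first three looks
        assert np.all(np.isfinite(series.values[150:200]))

    def test_alternation_skips_uncodable_but_not_parity(self):
        # codable looks alternate in sequence order irrespective of masking
        events = [ev(0, 1.0), ev(1.0, 2.0, "uncodable"), ev(2.0, 3.0), ev(3.0, 4.0)]
        series = binary_attention_series(events, 4.0)
        assert set(np.unique(series.values[150:200])) == {0.0}

    def test_empty_events_all_missing(self):
        series = binary_attention_series([], 2.0)
        assert series.n == 100
        assert np.all(np.isnan(series.values))

    def test_overlap_rejected_with_actor_and_time(self):
        events = [ev(0, 2.0), ev(1.5, 3.0)]
        with pytest.raises(ValueError, match="infant.*t=1.5"):
            binary_attention_series(events, 3.0)

    def test_successive_runs_never_repeat_value(self):
        rng = np.random.default_rng(3)
        t, events = 0.0, []
        for _ in range(60):
            d = rng.uniform(0.2, 2.0)
            events.append(ev(t, t + d))
            t += d
        series = binary_attention_series(events, t)
        bounds = events_from_binary(series)
        vals = [series.values[int(round(b[0] * 50))] for b in bounds]
        assert all(a != b for a, b in zip(vals, vals[1:]))

    def test_round_trip_recovers_boundaries_to_one_sample(self):
        rng = np.random.default_rng(4)
        t, events = 0.0, []
        for _ in range(40):
            d = rng.uniform(0.3, 2.5)
            events.append(ev(t, t + d))
            t += d
        series = binary_attention_series(events, t)
        bounds = events_from_binary(series)
        assert len(bounds) == len(events)
        for (on, off), e in zip(bounds, events):
            assert abs(on - e.onset) <= 1 / 50 + 1e-9
            assert abs(off - e.offset) <= 1 / 50 + 1e-9


class TestDurationSeries:
    def test_each_sample_carries_total_look_duration(self):
        events = [ev(0, 2.0), ev(2.0, 2.5, "partner")]
        series = duration_series(events, session_length=2.5)
        assert np.allclose(series.values[:100], 2.0)
        assert np.allclose(series.values[100:125], 0.5)

    def test_duration_equals_offset_minus_onset_exactly(self):
        events = [ev(0.0, 1.23456789), ev(1.23456789, 3.0, "offtask")]
        series = duration_series(events, session_length=3.0)
        assert abs(series.values[0] - 1.23456789) < 1e-9

    def test_category_filter_masks_excluded_looks_only(self):
        events = [ev(0, 1.0), ev(1.0, 2.0, "partner"), ev(2.0, 3.0, "offtask")]
        series = duration_series(events, include_categories={"object1"}, session_length=3.0)
        assert np.all(np.isfinite(series.values[:50]))
        assert np.all(np.isnan(series.values[50:150]))

    def test_missingness_monotone_under_category_inclusion(self):
        events = [ev(0, 1.0), ev(1.0, 2.0, "partner"), ev(2.0, 3.0, "offtask")]
        small = duration_series(events, {"object1"}, session_length=3.0)
        large = duration_series(events, {"object1", "partner", "offtask"}, session_length=3.0)
        assert large.missing.sum() <= small.missing.sum()
        # full inclusion of codable categories leaves no category-induced gaps
        assert large.missing.sum() == 0


class TestDurationHistogram:
    def test_single_look_lands_in_its_bin(self):
        table, overflow = duration_histogram([ev(0, 1.25)])
        row = table.loc[[i for i in table.index if i.left == 1.2][0]]
        assert row["object1"] == 1
        assert table.to_numpy().sum() == 1
        assert overflow == {"object1": 0}

    def test_deterministic_durations_concentrate_in_one_bin(self):
        events = [ev(i, i + 1.0) for i in range(100)]
        table, _ = duration_histogram(events)
        assert table["object1"].max() == 100

    def test_long_episodes_reported_as_overflow(self):
        table, overflow = duration_histogram([ev(0, 12.0)], max_duration=10.0)
        assert table.to_numpy().sum() == 0
        assert overflow["object1"] == 1

    def test_synthetic_infant_mode_between_one_and_two_seconds(self, small_study):
        sessions, _ = small_study
        events = [e for s in sessions for e in s.infant_events]
        table, _ = duration_histogram(events, bin_width=0.5)
        counts = table.sum(axis=1)
        mode_bin = counts.index[np.argmax(counts.to_numpy())]
        assert 1.0 <= mode_bin.left <= 2.0


def test_event_table_round_trip(tmp_path):
    events = [ev(0, 1.0), ev(1.0, 2.5, "partner")]
    frame = events_to_frame(events)
    assert list(frame.columns) == ["actor", "onset_s", "offset_s", "category"]
    path = tmp_path / "events.csv"
    frame.to_csv(path, index=False)
    import pandas as pd

    back = frame_to_events(pd.read_csv(path), actor="infant")
    assert back == events


# ------------------------------------------------------ property tests

from hypothesis import given, settings, strategies as st


@settings(max_examples=50, derandomize=True)
@given(
    st.lists(st.floats(min_value=0.1, max_value=5.0, allow_nan=False), min_size=2, max_size=40)
)
def test_alternation_holds_for_arbitrary_tilings(durations):
    """Any gap-free tiling yields a strictly alternating 0/1 series."""
    t, events = 0.0, []
    for k, d in enumerate(durations):
        events.append(ev(t, t + d, "object1" if k % 2 else "offtask"))
        t += d
    series = binary_attention_series(events, t)
    v = series.values
    finite = np.isfinite(v)
    # within each look the value is constant; across looks it flips
    for k, e in enumerate(events):
        i0 = int(np.ceil(e.onset * 50 - 1e-9))
        i1 = int(np.ceil(e.offset * 50 - 1e-9))
        chunk = v[i0:i1]
        if chunk.size:
            assert np.all(chunk == k % 2)


@settings(max_examples=50, derandomize=True)
@given(
    st.lists(st.floats(min_value=0.2, max_value=4.0, allow_nan=False), min_size=3, max_size=30),
    st.integers(min_value=0, max_value=2**16),
)
def test_duration_series_round_trip(durations, salt):
    """Every sample of a look carries exactly that look's duration."""
    rng = np.random.default_rng(salt)
    cats = rng.choice(["object1", "partner", "offtask"], size=len(durations))
    t, events = 0.0, []
    for d, c in zip(durations, cats):
        events.append(ev(t, t + d, str(c)))
        t += d
    series = duration_series(events, session_length=t)
    for e in events:
        i0 = int(np.ceil(e.onset * 50 - 1e-9))
        i1 = int(np.ceil(e.offset * 50 - 1e-9))
        chunk = series.values[i0:i1]
        if chunk.size:
            np.testing.assert_allclose(chunk, e.duration, atol=1e-9)
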