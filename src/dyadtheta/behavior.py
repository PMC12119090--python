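"""Convert coded gaze events into 50 Hz analysis series.

Two representations are used downstream: a *binary attention* series that
labels consecutive looks alternately 0/1 (encoding only the timing of
attention shifts), and a *continuous duration* series in which every sample
of a look carries that look's total duration in seconds.

Uncodable periods are treated as missing, and so are the looks immediately
before and after each uncodable period, because the true extent of those
neighbouring looks is unknown.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .events import CODABLE_CATEGORIES, LookEvent, validate_events
from .series import BEHAVIOUR_RATE, BehaviourSeries

__all__ = [
    "binary_attention_series",
    "duration_series",
    "duration_histogram",
    "events_from_binary",
]


def _grid(session_length: float, rate: float) -> int:
    return int(math.ceil(session_length * rate))


def _sample_slice(ev: LookEvent, rate: float, n: int) -> slice:
    """Samples whose time t satisfies onset <= t < offset (half-open)."""
    i0 = int(math.ceil(ev.onset * rate - 1e-9))
    i1 = int(math.ceil(ev.offset * rate - 1e-9))
    return slice(max(i0, 0), min(i1, n))


def _neighbours_of_uncodable(events: Sequence[LookEvent]) -> set[int]:
    """Indices of looks adjacent to (or themselves) uncodable periods."""
    bad: set[int] = set()
    for i, ev in enumerate(events):
        if ev.category == "uncodable":
            bad.add(i)
            if i > 0:
                bad.add(i - 1)
            if i + 1 < len(events):
                bad.add(i + 1)
    return bad


def binary_attention_series(
    events: Sequence[LookEvent],
    session_length: float | None = None,
    rate: float = BEHAVIOUR_RATE,
) -> BehaviourSeries:
    """Alternating 0/1 attention series, irrespective of look target.

    The first codable look takes value 0 (an arbitrary but fixed convention;
    lagged correlations are invariant to a joint global flip). Uncodable
    periods and their neighbouring looks are missing, as is any time not
    covered by an event.
    """
    events = sorted(events, key=lambda e: e.onset)
    validate_events(events)
    if session_length is None:
        session_length = max((e.offset for e in events), default=0.0)
    n = _grid(session_length, rate)
    values = np.full(n, np.nan)
    if not events:
        return BehaviourSeries(values, rate, None, "binary_attention")
    masked = _neighbours_of_uncodable(events)
    bit = 0
    for i, ev in enumerate(events):
        if ev.category == "uncodable":
            continue
        if i not in masked:
            values[_sample_slice(ev, rate, n)] = bit
        bit = 1 - bit
    return BehaviourSeries(values, rate, events[0].actor, "binary_attention")


def duration_series(
    events: Sequence[LookEvent],
    include_categories: Iterable[str] | None = None,
    session_length: float | None = None,
    rate: float = BEHAVIOUR_RATE,
) -> BehaviourSeries:
    """Continuous look-duration series: each sample carries its look's length.

    ``include_categories`` restricts which look targets contribute (e.g.
    objects only); by default all codable categories -- objects, partner and
    off-task -- are included, matching the continuous attention variable used
    for the lagged analyses. The uncodable masking rule is as for
    :func:`binary_attention_series`.
    """
    events = sorted(events, key=lambda e: e.onset)
    validate_events(events)
    include = (
        CODABLE_CATEGORIES if include_categories is None else set(include_categories)
    )
    if session_length is None:
        session_length = max((e.offset for e in events), default=0.0)
    n = _grid(session_length, rate)
    values = np.full(n, np.nan)
    masked = _neighbours_of_uncodable(events)
    for i, ev in enumerate(events):
        if ev.category == "uncodable" or i in masked:
            continue
        if ev.category in include:
            values[_sample_slice(ev, rate, n)] = ev.duration
    actor = events[0].actor if events else None
    return BehaviourSeries(values, rate, actor, "look_duration")


def duration_histogram(
    events: Sequence[LookEvent],
    bin_width: float = 0.1,
    max_duration: float = 10.0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Stacked per-category counts of look durations in ``bin_width`` bins.

    Episodes longer than ``max_duration`` are excluded from the table and
    returned separately as overflow counts per category.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    edges = np.arange(0.0, max_duration + bin_width / 2, bin_width)
    cats = sorted({e.category for e in events if e.category != "uncodable"})
    table = pd.DataFrame(
        0,
        index=pd.IntervalIndex.from_breaks(np.round(edges, 10), closed="left"),
        columns=cats,
        dtype=int,
    )
    overflow: dict[str, int] = {c: 0 for c in cats}
    for ev in events:
        if ev.category == "uncodable":
            continue
        if ev.duration >= max_duration:
            overflow[ev.category] += 1
            continue
        k = int(ev.duration / bin_width)
        table.iloc[k, table.columns.get_loc(ev.category)] += 1
    return table, overflow


def events_from_binary(series: BehaviourSeries) -> list[tuple[float, float]]:
    """Recover (onset, offset) episode boundaries from a binary series.

    Inverse of :func:`binary_attention_series` up to one sample and up to the
    masked (missing) episodes; used for round-trip checks.
    """
    v = series.values
    bounds: list[tuple[float, float]] = []
    start = None
    for i in range(v.size):
        if not np.isfinite(v[i]):
            if start is not None:
                bounds.append((start / series.rate, i / series.rate))
                start = None
            continue
        if start is None:
            start = i
        elif v[i] != v[i - 1]:
            bounds.append((start / series.rate, i / series.rate))
            start = i
    if start is not None:
        bounds.append((start / series.rate, v.size / series.rate))
    return bounds
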