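"""Event-related analysis of continuous variables around infant look onsets.

For every qualifying infant object-look onset, a window of the continuous
variable spanning five seconds either side of the onset is extracted.
Because the question is how the variable changes *around the onset of that
particular episode*, samples after the locked look ends are set to missing.
Windows are averaged over looks, then sections, then participants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import nanmean_quiet, nanstd_quiet
from .cluster import ClusterResult, NullDistribution, cluster_significance, derangement_null
from .events import OBJECT_CATEGORIES, LookEvent
from .series import BEHAVIOUR_RATE, BehaviourSeries

__all__ = [
    "EventLockedCurve",
    "session_event_curve",
    "lock_to_onsets",
    "log_spaced_bins",
    "duration_binned_lock",
    "event_locked_significance",
]


@dataclass
class EventLockedCurve:
    """Group event-locked signal on a symmetric time grid around onset."""

    times: np.ndarray  # seconds, symmetric about 0
    group_mean: np.ndarray
    group_sem: np.ndarray
    n_events: int
    per_participant: dict = field(default_factory=dict)
    bin_label: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times,
                "mean": self.group_mean,
                "sem": self.group_sem,
                "bin": self.bin_label,
            }
        )


def _qualifying_looks(
    events: Sequence[LookEvent],
    categories: frozenset | set = OBJECT_CATEGORIES,
    duration_range: tuple[float, float] | None = None,
) -> list[LookEvent]:
    looks = [e for e in events if e.category in categories]
    if duration_range is not None:
        lo, hi = duration_range
        looks = [e for e in looks if lo <= e.duration <= hi]
    return looks


def session_event_curve(
    variable: BehaviourSeries,
    events: Sequence[LookEvent],
    categories: frozenset | set = OBJECT_CATEGORIES,
    window: float = 5.0,
    duration_range: tuple[float, float] | None = None,
) -> tuple[np.ndarray, int]:
    """Mean event-locked window for one session: (curve, n_onsets).

    Onsets near the session edges contribute partial windows padded with
    missing values; samples after the locked look's offset are missing.
    """
    rate = variable.rate
    half = int(round(window * rate))
    width = 2 * half + 1
    v = variable.values
    looks = _qualifying_looks(events, categories, duration_range)
    if not looks:
        return np.full(width, np.nan), 0
    windows = np.full((len(looks), width), np.nan)
    for li, look in enumerate(looks):
        onset_i = int(round(look.onset * rate))
        end_i = int(round(look.offset * rate))
        i0, i1 = onset_i - half, onset_i + half + 1
        s0, s1 = max(i0, 0), min(i1, v.size)
        windows[li, s0 - i0: s1 - i0] = v[s0:s1]
        # mask samples after the locked look ends (gaze shifted again)
        post_end = end_i - i0
        if post_end < width:
            windows[li, max(post_end, 0):] = np.nan
    curve = nanmean_quiet(windows, axis=0)
    return curve, len(looks)


def lock_to_onsets(
    inputs: Mapping[str, Sequence[tuple[BehaviourSeries, Sequence[LookEvent]]]],
    categories: frozenset | set = OBJECT_CATEGORIES,
    window: float = 5.0,
    duration_range: tuple[float, float] | None = None,
    bin_label: str = "",
) -> EventLockedCurve:
    """Group event-locked curve from per-participant (variable, events) sections."""
    rate = next(iter(inputs.values()))[0][0].rate
    half = int(round(window * rate))
    times = np.arange(-half, half + 1) / rate
    per_participant = {}
    n_events = 0
    for pid, sections in inputs.items():
        curves = []
        for variable, events in sections:
            curve, n = session_event_curve(
                variable, events, categories, window, duration_range
            )
            n_events += n
            if n:
                curves.append(curve)
        if curves:
            per_participant[pid] = nanmean_quiet(np.vstack(curves), axis=0)
    if n_events == 0:
        raise ValueError("no qualifying onsets found (0 events)")
    stack = np.vstack(list(per_participant.values()))
    n_valid = np.sum(np.isfinite(stack), axis=0)
    mean = nanmean_quiet(stack, axis=0)
    sd = nanstd_quiet(stack, axis=0, ddof=1)
    sem = np.where(n_valid > 1, sd / np.sqrt(np.maximum(n_valid, 1)), np.nan)
    return EventLockedCurve(times, mean, sem, n_events, per_participant, bin_label)


def log_spaced_bins(durations: np.ndarray, n_bins: int = 5) -> np.ndarray:
    """Log-spaced bin edges from the shortest to the longest observed look.

    A lower edge of zero is impossible on a log scale, so the minimum
    observed duration is used instead.
    """
    durations = np.asarray(durations, float)
    durations = durations[durations > 0]
    if durations.size == 0:
        raise ValueError("no positive durations to bin")
    lo, hi = durations.min(), durations.max()
    if lo == hi:
        return np.array([lo, hi])
    return np.geomspace(lo, hi, n_bins + 1)


def duration_binned_lock(
    inputs: Mapping[str, Sequence[tuple[BehaviourSeries, Sequence[LookEvent]]]],
    n_bins: int = 5,
    categories: frozenset | set = OBJECT_CATEGORIES,
    window: float = 5.0,
) -> list[EventLockedCurve]:
    """Event-locked curves split by log-spaced look-duration bin.

    Empty bins are reported as curves with ``n_events == 0``, not errors.
    """
    all_durs = np.array(
        [
            e.duration
            for sections in inputs.values()
            for _, events in sections
            for e in events
            if e.category in categories
        ]
    )
    edges = log_spaced_bins(all_durs, n_bins)
    out = []
    rate = next(iter(inputs.values()))[0][0].rate
    half = int(round(window * rate))
    times = np.arange(-half, half + 1) / rate
    for b in range(len(edges) - 1):
        lo, hi = edges[b], edges[b + 1]
        # upper bin closes at the maximum so the longest look is included
        hi_edge = hi if b == len(edges) - 2 else np.nextafter(hi, -np.inf)
        label = f"{lo:.2f}-{hi:.2f}s"
        try:
            out.append(
                lock_to_onsets(
                    inputs, categories, window,
                    duration_range=(lo, hi_edge), bin_label=label,
                )
            )
        except ValueError:
            width = 2 * half + 1
            out.append(
                EventLockedCurve(
                    times, np.full(width, np.nan), np.full(width, np.nan),
                    0, {}, label,
                )
            )
    return out


def event_locked_significance(
    inputs: Mapping[str, Sequence[tuple[BehaviourSeries, Sequence[LookEvent]]]],
    rng: np.random.Generator,
    n_perm: int = 1000,
    alpha: float = 0.05,
    categories: frozenset | set = OBJECT_CATEGORIES,
    window: float = 5.0,
) -> tuple[EventLockedCurve, ClusterResult]:
    """Derangement-null cluster test of the event-locked curve.

    Each surrogate applies participant ``i``'s onset times to participant
    ``d(i)``'s continuous variable under the same masking and averaging as
    the observed curve.
    """
    observed = lock_to_onsets(inputs, categories, window)
    onset_inputs = {pid: [events for _, events in secs] for pid, secs in inputs.items()}
    var_inputs = {pid: [var for var, _ in secs] for pid, secs in inputs.items()}

    def pair_curve(events, variable):
        curve, _ = session_event_curve(variable, events, categories, window)
        return curve

    null = derangement_null(
        onset_inputs, var_inputs, pair_curve, observed.times, rng, n_perm
    )
    null.generator = "derangement-eventlocked"
    result = cluster_significance(observed.group_mean, null, alpha)
    return observed, result
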