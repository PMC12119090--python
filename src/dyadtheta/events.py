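"""Coded gaze events and their tabular representation.

A *look* (attention episode) is a maximal interval during which an actor's
gaze stays on one target: one of three play objects, the partner's face, or
off-task. Periods where gaze could not be coded are carried as events with
category ``"uncodable"``. Each actor's events tile the session without gaps
or overlaps, on half-open intervals ``[onset, offset)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

ACTORS = ("infant", "caregiver")
OBJECT_CATEGORIES = frozenset({"object1", "object2", "object3"})
CODABLE_CATEGORIES = OBJECT_CATEGORIES | {"partner", "offtask"}
CATEGORIES = CODABLE_CATEGORIES | {"uncodable"}

#: CSV column names for event tables (times are seconds from session start).
EVENT_COLUMNS = ("actor", "onset_s", "offset_s", "category")


@dataclass(frozen=True)
class LookEvent:
    """One coded attention episode on the half-open interval [onset, offset)."""

    actor: str
    onset: float
    offset: float
    category: str

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise ValueError(
                f"look offset must exceed onset: got [{self.onset}, {self.offset}) "
                f"for actor {self.actor!r}"
            )
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown look category {self.category!r}")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


def validate_events(
    events: Sequence[LookEvent],
    session_length: float | None = None,
    require_tiling: bool = False,
    tol: float = 1e-9,
) -> None:
    """Check time order and non-overlap (and optionally gap-free tiling).

    Raises ``ValueError`` naming the actor and time of the first violation.
    """
    prev: LookEvent | None = None
    for ev in events:
        if prev is not None:
            if ev.onset < prev.offset - tol:
                raise ValueError(
                    f"overlapping events for actor {ev.actor!r} at t={ev.onset:.3f} s"
                )
            if require_tiling and ev.onset > prev.offset + tol:
                raise ValueError(
                    f"gap in event tiling for actor {ev.actor!r} at t={prev.offset:.3f} s"
                )
        prev = ev
    if require_tiling and events:
        if abs(events[0].onset) > tol:
            raise ValueError(
                f"events for actor {events[0].actor!r} do not start at 0"
            )
        if session_length is not None and abs(events[-1].offset - session_length) > tol:
            raise ValueError(
                f"events for actor {events[-1].actor!r} end at "
                f"{events[-1].offset:.3f} s, not session length {session_length:.3f} s"
            )


def events_to_frame(events: Iterable[LookEvent]) -> pd.DataFrame:
    """Serialise events to the standard table (actor, onset_s, offset_s, category)."""
    return pd.DataFrame(
        [(e.actor, e.onset, e.offset, e.category) for e in events],
        columns=list(EVENT_COLUMNS),
    )


def frame_to_events(frame: pd.DataFrame, actor: str | None = None) -> list[LookEvent]:
    """Read events from a table, optionally filtering to one actor."""
    missing = set(EVENT_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"event table missing columns: {sorted(missing)}")
    if actor is not None:
        frame = frame[frame["actor"] == actor]
    frame = frame.sort_values("onset_s")
    return [
        LookEvent(r.actor, float(r.onset_s), float(r.offset_s), r.category)
        for r in frame.itertuples(index=False)
    ]


def session_length_of(events: Sequence[LookEvent]) -> float:
    if not events:
        raise ValueError("no events")
    return max(e.offset for e in events)
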