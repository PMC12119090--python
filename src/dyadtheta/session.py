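"""A single recorded (or simulated) play section of one caregiver-infant dyad."""

from __future__ import annotations

from dataclasses import dataclass, field

from .events import LookEvent
from .series import BehaviourSeries, EEGRecording, F0Track


@dataclass
class DyadSession:
    """Everything the pipeline needs for one dyad x play-section.

    ``theta`` is the 50 Hz relative theta power series; it may be supplied
    directly (simulated, or precomputed) or derived from ``eeg`` via
    :mod:`dyadtheta.eeg`. ``f0`` is the caregiver voiced-F0 track.
    """

    participant: str
    section: int
    session_length: float
    infant_events: list[LookEvent]
    caregiver_events: list[LookEvent]
    theta: BehaviourSeries | None = None
    eeg: EEGRecording | None = None
    f0: F0Track | None = None
    meta: dict = field(default_factory=dict)
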