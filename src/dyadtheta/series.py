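"""Sampled time-series containers shared across the pipeline.

Missingness is encoded as NaN in ``values``; the boolean ``missing`` view is
derived from it, so a sample is either finite or missing, never both.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

BEHAVIOUR_RATE = 50.0  # Hz, the video-coding frame rate
EEG_RATE = 512.0  # Hz


@dataclass
class BehaviourSeries:
    """A uniformly sampled behavioural or neural variable with missing data.

    Parameters
    ----------
    values : float array, NaN where missing.
    rate : sampling rate in Hz (50 for behaviour-aligned variables).
    actor, label : provenance tags ("infant"/"caregiver", e.g. "theta").
    """

    values: np.ndarray
    rate: float = BEHAVIOUR_RATE
    actor: str | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("BehaviourSeries values must be 1-D")
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    @property
    def missing(self) -> np.ndarray:
        return ~np.isfinite(self.values)

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n) / self.rate

    @property
    def duration(self) -> float:
        return self.n / self.rate

    def copy_with(self, values: np.ndarray) -> "BehaviourSeries":
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass
class F0Track:
    """A voiced-F0 contour with speaker and clipping annotations.

    ``f0`` is NaN wherever ``voiced`` is False. ``speaker`` holds
    "caregiver", "infant", "both" (co-vocalisation) or "" for silence.
    """

    times: np.ndarray
    f0: np.ndarray
    voiced: np.ndarray
    speaker: np.ndarray
    clipped: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.f0 = np.asarray(self.f0, dtype=float)
        self.voiced = np.asarray(self.voiced, dtype=bool)
        self.speaker = np.asarray(self.speaker, dtype=object)
        self.clipped = np.asarray(self.clipped, dtype=bool)
        n = self.times.size
        for name in ("f0", "voiced", "speaker", "clipped"):
            if getattr(self, name).size != n:
                raise ValueError(f"F0Track field {name} has wrong length")
        if n > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("F0Track times must be strictly increasing")
        if np.any(np.isfinite(self.f0) & ~self.voiced):
            raise ValueError("f0 present at unvoiced samples")

    @property
    def rate(self) -> float:
        dt = np.diff(self.times)
        if dt.size == 0:
            raise ValueError("cannot infer rate from a single sample")
        return 1.0 / float(np.median(dt))


@dataclass
class EEGRecording:
    """Pre-cleaned multichannel EEG in microvolts, channels x samples."""

    rate: float
    channels: Sequence[str]
    data: np.ndarray
    missing_segments: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise ValueError("data must be channels x samples matching channel names")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate
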