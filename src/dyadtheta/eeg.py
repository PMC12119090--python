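"""Relative theta power over fronto-central channels from pre-cleaned EEG.

The chain is: Morlet wavelet decomposition on a 1-16 Hz grid (7-cycle
Gaussian envelope), power expressed as *relative* power (share of total
power across the grid at each time point and channel), averaging over the
3-6 Hz band and the fronto-central channel set, then a bespoke 512 -> 50 Hz
downsampling in which each second is covered by 50 median windows of 10 or
11 samples whose positions are shuffled per second.

Artifact rejection is upstream of this module: it consumes pre-cleaned EEG
plus a list of missing segments, and applies only the amplitude-based
exclusion rule (any fronto-central channel above 100 uV for more than 15%
of the interaction) and edge/missing-data guards of 500 ms.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .series import BEHAVIOUR_RATE, BehaviourSeries, EEGRecording

__all__ = [
    "FRONTOCENTRAL_CHANNELS",
    "THETA_BAND",
    "TimeFreqPower",
    "exclude_noisy_theta",
    "morlet_relative_power",
    "theta_band_series",
    "downsample_512_to_50",
    "theta_pipeline",
]

FRONTOCENTRAL_CHANNELS = ("AF3", "AF4", "FC1", "FC2", "F3", "F4", "Fz")
THETA_BAND = (3.0, 6.0)
EDGE_GUARD = 0.5  # seconds masked at series edges and around missing segments


def _match_channels(
    available: list[str], wanted: tuple[str, ...] | list[str]
) -> list[int]:
    """Case-insensitive channel lookup; raises listing any missing name."""
    lookup = {name.lower(): i for i, name in enumerate(available)}
    idx, missing = [], []
    for name in wanted:
        i = lookup.get(name.lower())
        (idx.append(i) if i is not None else missing.append(name))
    if missing:
        raise ValueError(f"channels not present in recording: {missing}")
    return idx


def exclude_noisy_theta(
    recording: EEGRecording,
    threshold: float = 100.0,
    max_frac: float = 0.15,
    channel_set: tuple[str, ...] = FRONTOCENTRAL_CHANNELS,
) -> bool:
    """True if the recording should be excluded from the theta analysis.

    Excluded iff any listed channel exceeds ``threshold`` microvolts in
    absolute amplitude on strictly more than ``max_frac`` of its samples.
    """
    idx = _match_channels(list(recording.channels), channel_set)
    frac = np.mean(np.abs(recording.data[idx]) > threshold, axis=1)
    return bool(np.any(frac > max_frac))


@dataclass
class TimeFreqPower:
    """Relative power, frequency x time x channel, with a shared time mask."""

    freqs: np.ndarray
    rel_power: np.ndarray  # (n_freq, n_times, n_channels)
    valid: np.ndarray  # (n_times,) bool
    rate: float
    channels: list[str]


def _morlet_kernel(freq: float, rate: float, cycles: float) -> np.ndarray:
    """Complex Morlet wavelet: Gaussian-windowed complex exponential.

    The Gaussian sd is ``cycles / (2 pi f)`` so the envelope spans the
    requested number of cycles; the kernel extends to +-5 sd.
    """
    sd = cycles / (2.0 * math.pi * freq)
    half = int(math.ceil(5.0 * sd * rate))
    t = np.arange(-half, half + 1) / rate
    kernel = np.exp(2j * math.pi * freq * t) * np.exp(-(t**2) / (2.0 * sd**2))
    # unit-energy normalisation keeps power comparable across frequencies
    kernel /= np.sqrt(np.sum(np.abs(kernel) ** 2))
    return kernel


def morlet_relative_power(
    recording: EEGRecording,
    freqs: np.ndarray | None = None,
    cycles: float = 7.0,
    channel_set: tuple[str, ...] | None = None,
) -> TimeFreqPower:
    """Wavelet power on a linear frequency grid, normalised to relative power.

    Power at each (time, frequency, channel) is the squared magnitude of the
    convolution with a 7-cycle complex Morlet wavelet; relative power divides
    by the total over the frequency grid, so it sums to 1 at every unmasked
    (time, channel). The first and last 500 ms are masked, as are 500 ms
    guards around every missing segment.
    """
    if freqs is None:
        freqs = np.arange(1.0, 17.0)  # 1..16 Hz at 1 Hz steps
    freqs = np.asarray(freqs, dtype=float)
    channels = list(recording.channels)
    data = recording.data
    if channel_set is not None:
        idx = _match_channels(channels, channel_set)
        channels = [channels[i] for i in idx]
        data = data[idx]
    n = data.shape[1]
    rate = recording.rate
    power = np.empty((freqs.size, n, len(channels)))
    for fi, f in enumerate(freqs):
        kernel = _morlet_kernel(f, rate, cycles)
        conv = fftconvolve(data, kernel[np.newaxis, :], mode="same", axes=1)
        power[fi] = (np.abs(conv) ** 2).T
    total = power.sum(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = power / total
    guard = int(round(EDGE_GUARD * rate))
    valid = np.ones(n, dtype=bool)
    if n <= 2 * guard:
        warnings.warn("recording shorter than the edge guards; all samples masked")
        valid[:] = False
    else:
        valid[:guard] = False
        valid[n - guard:] = False
    for start, end in recording.missing_segments:
        i0 = max(int(math.floor((start - EDGE_GUARD) * rate)), 0)
        i1 = min(int(math.ceil((end + EDGE_GUARD) * rate)), n)
        valid[i0:i1] = False
    return TimeFreqPower(freqs, rel, valid, rate, channels)


def theta_band_series(
    tfp: TimeFreqPower,
    band: tuple[float, float] = THETA_BAND,
    channel_set: tuple[str, ...] = FRONTOCENTRAL_CHANNELS,
) -> BehaviourSeries:
    """Band share averaged over band frequencies, then over channels.

    Returns a series at the EEG rate (512 Hz); masked time points are NaN.
    """
    in_band = (tfp.freqs >= band[0]) & (tfp.freqs <= band[1])
    if not np.any(in_band):
        raise ValueError(f"band {band} outside the frequency grid")
    idx = _match_channels(tfp.channels, channel_set)
    if not idx:
        raise ValueError("empty channel intersection")
    values = tfp.rel_power[np.ix_(np.nonzero(in_band)[0], np.arange(tfp.rel_power.shape[1]), idx)]
    series = values.mean(axis=0).mean(axis=1)
    series = np.where(tfp.valid, series, np.nan)
    return BehaviourSeries(series, tfp.rate, "infant", "theta")


def _window_lengths(
    m: int, k: int, rng: np.random.Generator
) -> np.ndarray:
    """``k`` window lengths summing to ``m``, long windows shuffled in place."""
    base = m // k
    n_long = m - base * k
    lengths = np.full(k, base)
    if n_long:
        pos = rng.choice(k, size=n_long, replace=False)
        lengths[pos] += 1
    return lengths


def downsample_512_to_50(
    series: BehaviourSeries,
    rng: np.random.Generator | int | None = None,
    out_rate: float = BEHAVIOUR_RATE,
) -> BehaviourSeries:
    """Median downsampling from 512 Hz to 50 Hz with shuffled window spacing.

    Each full input second is divided into 50 contiguous windows -- 38 of 10
    samples and 12 of 11 samples (summing to 512) -- whose positions are
    shuffled per second; the output sample is the median of the non-missing
    samples in its window, or missing when more than half the window is
    missing. A trailing partial second is covered by proportionally many
    windows rather than dropped.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    in_rate = series.rate
    per_sec_in = int(round(in_rate))
    per_sec_out = int(round(out_rate))
    v = series.values
    out: list[float] = []
    pos = 0
    while pos < v.size:
        m = min(per_sec_in, v.size - pos)
        k = per_sec_out if m == per_sec_in else max(int(round(m * out_rate / in_rate)), 1)
        for w in _window_lengths(m, k, rng):
            chunk = v[pos:pos + w]
            finite = np.isfinite(chunk)
            if finite.sum() * 2 >= chunk.size:  # missing only when >50% missing
                out.append(float(np.median(chunk[finite])))
            else:
                out.append(np.nan)
            pos += int(w)
    return BehaviourSeries(np.array(out), out_rate, series.actor, series.label)


def theta_pipeline(
    recording: EEGRecording,
    rng: np.random.Generator | int | None = None,
    channel_set: tuple[str, ...] = FRONTOCENTRAL_CHANNELS,
) -> BehaviourSeries | None:
    """Full EEG -> 50 Hz relative-theta chain; None if the recording is excluded."""
    if exclude_noisy_theta(recording, channel_set=channel_set):
        return None
    tfp = morlet_relative_power(recording, channel_set=channel_set)
    theta512 = theta_band_series(tfp, channel_set=channel_set)
    return downsample_512_to_50(theta512, rng)
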