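"""Caregiver F0 rate-of-change: a per-second index of vocal salience.

From a voiced-F0 track (e.g. a Praat pitch export with speaker labels and
clipping flags) the module builds a continuous caregiver F0 series --
excluding infant speech, co-vocalisations and clipped vocalisations,
interpolating across unvoiced gaps, and low-pass filtering at 20 Hz -- then
summarises each 1000 ms interval by the total variation of the contour (sum
of absolute first differences), written to all 50 video frames of that
interval.

The "rate of change" is implemented as total variation rather than a signed
sum of differences: a signed sum telescopes to the interval's net F0 change,
which cannot index vocal modulation. The signed variant remains available
via ``signed=True``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .series import BEHAVIOUR_RATE, BehaviourSeries, F0Track

__all__ = ["F0SeriesResult", "caregiver_f0_series", "f0_rate_of_change"]

#: sessions with more than this fraction of vocalisation time excluded are flagged
EXCLUSION_THRESHOLD = 0.30


@dataclass
class F0SeriesResult:
    """Continuous caregiver F0 plus the session-level exclusion decision."""

    series: BehaviourSeries  # at the track rate; NaN where excluded
    excluded_fraction: float  # share of voiced time removed
    excluded: bool  # True if the session fails the 30% rule


def caregiver_f0_series(
    track: F0Track,
    lowpass_hz: float = 20.0,
    filter_order: int = 9,
    exclusion_threshold: float = EXCLUSION_THRESHOLD,
) -> F0SeriesResult:
    """Continuous, filtered caregiver F0 with exclusion bookkeeping.

    Voiced samples not attributable to the caregiver alone (other speaker,
    co-vocalisation, clipping) are excluded; unvoiced gaps are linearly
    interpolated; the result is low-pass filtered at ``lowpass_hz`` with a
    zero-phase Butterworth filter of the given order, and excluded spans are
    re-inserted as missing.
    """
    rate = track.rate
    voiced = track.voiced
    excluded = voiced & (
        (track.speaker != "caregiver") | track.clipped
    )
    usable = voiced & ~excluded
    n_voiced = int(voiced.sum())
    frac = float(excluded.sum()) / n_voiced if n_voiced else 1.0
    values = np.full(track.times.size, np.nan)
    if usable.sum() >= 2:
        # interpolate across unvoiced gaps (and excluded spans, for filter
        # continuity; those spans are blanked again afterwards)
        interp = np.interp(
            np.arange(values.size), np.nonzero(usable)[0], track.f0[usable]
        )
        if rate > 2 * lowpass_hz:
            sos = butter(filter_order, lowpass_hz, fs=rate, output="sos")
            interp = sosfiltfilt(sos, interp)
        values = interp
        values[excluded] = np.nan
    series = BehaviourSeries(values, rate, "caregiver", "f0")
    return F0SeriesResult(series, frac, frac > exclusion_threshold)


def f0_rate_of_change(
    f0_series: BehaviourSeries,
    out_rate: float = BEHAVIOUR_RATE,
    interval: float = 1.0,
    signed: bool = False,
) -> BehaviourSeries:
    """Per-interval total variation of F0, written to 50 Hz frames.

    For each contiguous ``interval``-second window anchored at the session
    start, the sum of absolute first differences of F0 is computed and
    inserted at every output frame of that window. Windows containing any
    missing input are missing; so is a trailing partial window.
    """
    in_rate = f0_series.rate
    v = f0_series.values
    per_in = int(round(interval * in_rate))
    per_out = int(round(interval * out_rate))
    n_intervals = v.size // per_in
    n_out = int(math.ceil(v.size / in_rate * out_rate))
    out = np.full(n_out, np.nan)
    if n_intervals == 0:
        warnings.warn("session shorter than one rate-of-change interval; all missing")
        return BehaviourSeries(out, out_rate, f0_series.actor, "f0_rate")
    for i in range(n_intervals):
        chunk = v[i * per_in:(i + 1) * per_in]
        if np.any(~np.isfinite(chunk)):
            continue
        d = np.diff(chunk)
        tv = float(d.sum()) if signed else float(np.abs(d).sum())
        out[i * per_out:min((i + 1) * per_out, n_out)] = tv
    return BehaviourSeries(out, out_rate, f0_series.actor, "f0_rate")
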