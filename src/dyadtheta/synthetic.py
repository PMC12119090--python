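"""Synthetic caregiver-infant dyads with known generating structure.

Every downstream stage of the pipeline is validated against sessions drawn
from this module: alternating-renewal gaze sequences for both actors
(log-normal look durations with AR(1) dependence on the log scale), a 50 Hz
relative-theta series lag-coupled to the infant's look durations, an optional
512 Hz EEG surrogate whose 3-6 Hz content tracks that series, a contingent
caregiver response to infant object-look onsets, and a caregiver F0 contour
with sinusoidal modulation.

Default parameters emulate the descriptive regime of naturalistic tabletop
play at ~12 months: infant look durations with a mode of 1.5 s (histogram
mode between 1 and 2 s), caregiver looks with a mode of 0.35 s (200-500 ms),
theta coupled to attention durations at a lag of +1.5 s, and five-minute
play sections.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .events import CODABLE_CATEGORIES, LookEvent, validate_events
from .series import BEHAVIOUR_RATE, EEG_RATE, BehaviourSeries, EEGRecording, F0Track
from .session import DyadSession

__all__ = [
    "ActorParams",
    "SyntheticConfig",
    "SyntheticTruth",
    "simulate_look_sequence",
    "simulate_caregiver_response",
    "simulate_theta_series",
    "simulate_eeg_from_theta",
    "simulate_f0_track",
    "simulate_session",
    "simulate_study",
]

_F0_FLOOR, _F0_CEILING = 75.0, 600.0


@dataclass(frozen=True)
class ActorParams:
    """Look-duration model for one actor.

    Durations are log-normal, parameterised by the *mode* in seconds for
    readability (``mu = log(mode) + sigma**2``), with lag-1 autoregression
    ``ar_rho`` on consecutive log durations. ``target_probs`` are i.i.d.
    categorical probabilities over look targets.
    """

    mode: float
    sigma: float
    ar_rho: float = 0.0
    target_probs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode <= 0 or self.sigma <= 0:
            raise ValueError("mode and sigma must be positive")
        if not 0.0 <= self.ar_rho < 1.0:
            raise ValueError("ar_rho must be in [0, 1)")
        if not self.target_probs:
            object.__setattr__(self, "target_probs", {"object1": 1.0})
        if self.target_probs:
            bad = set(self.target_probs) - CODABLE_CATEGORIES
            if bad:
                raise ValueError(f"unknown target categories: {sorted(bad)}")
            total = sum(self.target_probs.values())
            if abs(total - 1.0) > 1e-8:
                raise ValueError(f"target_probs must sum to 1, got {total}")

    @property
    def mu(self) -> float:
        """Mean of the log-duration distribution."""
        return math.log(self.mode) + self.sigma**2


def _default_infant() -> ActorParams:
    return ActorParams(
        mode=1.5,
        sigma=0.9,
        ar_rho=0.3,
        target_probs={
            "object1": 0.25,
            "object2": 0.20,
            "object3": 0.20,
            "partner": 0.05,
            "offtask": 0.30,
        },
    )


def _default_caregiver() -> ActorParams:
    return ActorParams(
        mode=0.35,
        sigma=0.8,
        ar_rho=0.2,
        target_probs={
            "object1": 0.15,
            "object2": 0.15,
            "object3": 0.15,
            "partner": 0.30,
            "offtask": 0.25,
        },
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Full generating model for one synthetic study.

    theta(t) = theta_baseline + theta_gain * log(duration of the infant look
    active at t - theta_lag) + AR(1) noise, on the 50 Hz grid. Caregiver look
    durations are multiplied by (1 - response_depth) when the look starts
    within response_window seconds after an infant object-look onset.
    """

    session_length: float = 300.0
    infant: ActorParams = field(default_factory=_default_infant)
    caregiver: ActorParams = field(default_factory=_default_caregiver)
    uncodable_rate: float = 0.01  # uncodable segments per second
    uncodable_mean_dur: float = 1.0  # mean uncodable segment length, s
    theta_gain: float = 0.005  # relative-power units per log-second
    theta_lag: float = 1.5  # s; attention leads theta
    theta_baseline: float = 0.30
    theta_noise_sd: float = 0.05  # stationary sd of the AR(1) noise
    theta_noise_rho: float = 0.90
    response_depth: float = 0.0  # 0 = no contingent caregiver response
    response_window: float = 4.0  # s after infant object-look onset
    f0_carrier: float = 220.0  # Hz
    f0_mod_amplitude: float = 40.0  # Hz
    f0_mod_rate: float = 3.0  # Hz
    f0_voiced_fraction: float = 0.5
    eeg_rate: float = EEG_RATE
    behaviour_rate: float = BEHAVIOUR_RATE
    f0_track_rate: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.session_length <= 0:
            raise ValueError("session_length must be positive")
        if not 0.0 <= self.response_depth < 1.0:
            raise ValueError("response_depth must be in [0, 1)")
        if self.theta_lag < 0:
            raise ValueError("theta_lag must be non-negative")
        if not _F0_FLOOR <= self.f0_carrier <= _F0_CEILING:
            raise ValueError(
                f"f0_carrier must lie within [{_F0_FLOOR}, {_F0_CEILING}] Hz"
            )


@dataclass
class SyntheticTruth:
    """The generating parameters and realised durations behind a study."""

    config: SyntheticConfig
    infant_durations: dict = field(default_factory=dict)  # (pid, section) -> array
    caregiver_durations: dict = field(default_factory=dict)
    n_suppressed: dict = field(default_factory=dict)  # caregiver looks in-window


def _draw_log_durations(params: ActorParams, n: int, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) sequence of log durations with marginal sd ``sigma``."""
    eps = rng.standard_normal(n)
    rho = params.ar_rho
    innov_sd = params.sigma * math.sqrt(1.0 - rho**2)
    devs = np.empty(n)
    if rho == 0.0:
        devs = params.sigma * eps
    else:
        from scipy.signal import lfilter

        innov = innov_sd * eps
        innov[0] = params.sigma * eps[0]  # stationary start
        devs = lfilter([1.0], [1.0, -rho], innov)
    return params.mu + devs


def _draw_categories(params: ActorParams, n: int, rng: np.random.Generator) -> list[str]:
    cats = sorted(params.target_probs)
    probs = np.array([params.target_probs[c] for c in cats])
    return [cats[i] for i in rng.choice(len(cats), size=n, p=probs)]


def _tile_events(
    actor: str,
    durations: np.ndarray,
    categories: list[str],
    session_length: float,
) -> list[LookEvent]:
    events: list[LookEvent] = []
    t = 0.0
    for dur, cat in zip(durations, categories):
        end = min(t + dur, session_length)
        if end > t:
            events.append(LookEvent(actor, t, end, cat))
        t = end
        if t >= session_length:
            break
    return events


def _insert_uncodable(
    events: list[LookEvent],
    rate: float,
    mean_dur: float,
    session_length: float,
    rng: np.random.Generator,
    min_piece: float = 1e-6,
) -> list[LookEvent]:
    """Overlay Poisson uncodable segments, truncating the looks they cover.

    The output tiles the same span as the input: every instant keeps its
    original look's category unless it falls inside an uncodable segment.
    """
    n_seg = rng.poisson(rate * session_length)
    if n_seg == 0 or not events:
        return events
    starts = np.sort(rng.uniform(0.0, session_length, size=n_seg))
    durs = rng.exponential(mean_dur, size=n_seg)
    segs: list[list[float]] = []
    for s, d in zip(starts, durs):
        e = min(s + d, session_length)
        if segs and s <= segs[-1][1]:
            segs[-1][1] = max(segs[-1][1], e)
        else:
            segs.append([s, e])
    actor = events[0].actor
    seg_bounds = [b for seg in segs for b in seg]

    def _in_segment(t: float) -> bool:
        for s, e in segs:
            if s <= t < e:
                return True
        return False

    out: list[LookEvent] = []
    for ev in events:
        cuts = sorted(
            {ev.onset, ev.offset}
            | {b for b in seg_bounds if ev.onset < b < ev.offset}
        )
        for a, b in zip(cuts[:-1], cuts[1:]):
            cat = "uncodable" if _in_segment(a) else ev.category
            if out and out[-1].category == cat == "uncodable":
                out[-1] = LookEvent(actor, out[-1].onset, b, cat)
            elif b - a > min_piece:
                out.append(LookEvent(actor, a, b, cat))
            elif out:
                # absorb numerical slivers into the preceding event
                out[-1] = LookEvent(actor, out[-1].onset, b, out[-1].category)
            else:
                out.append(LookEvent(actor, a, b, cat))
    return out


def simulate_look_sequence(
    params: ActorParams,
    session_length: float,
    rng: np.random.Generator,
    actor: str = "infant",
    uncodable_rate: float = 0.0,
    uncodable_mean_dur: float = 1.0,
) -> list[LookEvent]:
    """Draw an alternating, gap-free look sequence tiling [0, session_length).

    Durations are log-normal with AR(1) dependence on the log scale;
    categories are i.i.d. from ``params.target_probs``; uncodable segments
    are overlaid as an independent Poisson process, truncating looks.
    """
    if session_length <= 0:
        raise ValueError("session_length must be positive")
    # expected looks plus slack; extend if the draw falls short
    n_guess = max(8, int(3 * session_length / params.mode))
    logd = _draw_log_durations(params, n_guess, rng)
    durs = np.exp(logd)
    while durs.sum() < session_length:
        more = np.exp(_draw_log_durations(params, n_guess, rng))
        durs = np.concatenate([durs, more])
    cats = _draw_categories(params, durs.size, rng)
    events = _tile_events(actor, durs, cats, session_length)
    if uncodable_rate > 0:
        events = _insert_uncodable(
            events, uncodable_rate, uncodable_mean_dur, session_length, rng
        )
    validate_events(events, session_length, require_tiling=True)
    return events


def object_onsets(events: list[LookEvent]) -> np.ndarray:
    from .events import OBJECT_CATEGORIES

    return np.array([e.onset for e in events if e.category in OBJECT_CATEGORIES])


def simulate_caregiver_response(
    infant_events: list[LookEvent],
    params: ActorParams,
    session_length: float,
    rng: np.random.Generator,
    depth: float = 0.0,
    window: float = 4.0,
    uncodable_rate: float = 0.0,
    uncodable_mean_dur: float = 1.0,
) -> list[LookEvent]:
    """Caregiver look sequence with a contingent response to infant onsets.

    A caregiver look starting within ``window`` seconds after an infant
    object-look onset has its duration multiplied by ``(1 - depth)``;
    all other durations follow ``params`` unchanged.
    """
    if not 0.0 <= depth < 1.0:
        raise ValueError("depth must be in [0, 1)")
    if window < 0:
        raise ValueError("window must be non-negative")
    onsets = object_onsets(infant_events)
    events: list[LookEvent] = []
    t = 0.0
    prev_log: float | None = None
    innov_sd = params.sigma * math.sqrt(1.0 - params.ar_rho**2)
    cats = sorted(params.target_probs)
    probs = np.array([params.target_probs[c] for c in cats])
    while t < session_length:
        if prev_log is None:
            logd = params.mu + params.sigma * rng.standard_normal()
        else:
            logd = (
                params.mu
                + params.ar_rho * (prev_log - params.mu)
                + innov_sd * rng.standard_normal()
            )
        prev_log = logd  # AR state follows the base (unsuppressed) chain
        dur = math.exp(logd)
        if depth > 0 and onsets.size:
            idx = np.searchsorted(onsets, t, side="right") - 1
            if idx >= 0 and t - onsets[idx] < window:
                dur *= 1.0 - depth
        cat = cats[rng.choice(len(cats), p=probs)]
        end = min(t + dur, session_length)
        events.append(LookEvent("caregiver", t, end, cat))
        t = end
    if uncodable_rate > 0:
        events = _insert_uncodable(
            events, uncodable_rate, uncodable_mean_dur, session_length, rng
        )
    validate_events(events, session_length, require_tiling=True)
    return events


def simulate_theta_series(
    infant_events: list[LookEvent],
    rng: np.random.Generator,
    gain: float = 0.05,
    lag: float = 1.5,
    baseline: float = 0.30,
    noise_sd: float = 0.05,
    noise_rho: float = 0.90,
    session_length: float | None = None,
    rate: float = BEHAVIOUR_RATE,
) -> BehaviourSeries:
    """Relative-theta series coupled to infant look durations at a fixed lag.

    theta(t) = baseline + gain * log(duration of the look active at t - lag)
    + AR(1) noise. Samples with t - lag < 0, or whose source time falls in an
    uncodable segment, are missing. Values are clipped to (0, 1), the range
    of a relative power share.
    """
    if lag < 0:
        raise ValueError("lag must be non-negative")
    if session_length is None:
        session_length = max(e.offset for e in infant_events)
    n = int(math.ceil(session_length * rate))
    if lag >= session_length:
        warnings.warn("theta lag exceeds session length; series is all-missing")
        return BehaviourSeries(np.full(n, np.nan), rate, "infant", "theta")
    t = np.arange(n) / rate
    src = t - lag
    onsets = np.array([e.onset for e in infant_events])
    idx = np.searchsorted(onsets, src, side="right") - 1
    # AR(1) noise with stationary sd noise_sd
    from scipy.signal import lfilter

    eps = rng.standard_normal(n)
    innov = noise_sd * math.sqrt(1.0 - noise_rho**2) * eps
    innov[0] = noise_sd * eps[0]
    noise = lfilter([1.0], [1.0, -noise_rho], innov)
    log_dur = np.array(
        [math.log(e.duration) if e.category != "uncodable" else np.nan
         for e in infant_events]
    )
    values = baseline + gain * log_dur[np.clip(idx, 0, None)] + noise
    values[src < 0] = np.nan
    np.clip(values, 1e-3, 1.0 - 1e-3, out=values)
    return BehaviourSeries(values, rate, "infant", "theta")


def simulate_eeg_from_theta(
    theta_target: BehaviourSeries,
    rng: np.random.Generator,
    eeg_rate: float = EEG_RATE,
    channels: tuple[str, ...] | None = None,
    noise_sd: float = 0.0,
) -> EEGRecording:
    """512 Hz EEG surrogate whose 3-6 Hz envelope tracks a target theta share.

    Each channel is a sum of band-limited oscillators: a 4.5 Hz component
    whose instantaneous power is set so that its share of total oscillator
    power equals the target relative theta, plus fixed-amplitude 8 and 12 Hz
    fillers and optional white noise. Channel phases are randomised.
    """
    from .eeg import FRONTOCENTRAL_CHANNELS

    if channels is None:
        channels = tuple(FRONTOCENTRAL_CHANNELS) + ("Cz",)
    n_out = int(round(theta_target.n / theta_target.rate * eeg_rate))
    t = np.arange(n_out) / eeg_rate
    # target share upsampled; missing samples take the nearest finite value
    share = theta_target.values.copy()
    if np.all(~np.isfinite(share)):
        share[:] = 0.3
    finite = np.isfinite(share)
    share = np.interp(
        np.arange(share.size), np.nonzero(finite)[0], share[finite]
    )
    share_hi = np.interp(t * theta_target.rate, np.arange(share.size), share)
    share_hi = np.clip(share_hi, 1e-3, 1 - 1e-3)
    amp_alpha, amp_beta = 10.0, 8.0  # microvolts
    p_other = (amp_alpha**2 + amp_beta**2) / 2.0
    amp_theta = np.sqrt(2.0 * p_other * share_hi / (1.0 - share_hi))
    data = np.empty((len(channels), n_out))
    for c in range(len(channels)):
        ph = rng.uniform(0, 2 * np.pi, size=3)
        sig = (
            amp_theta * np.sin(2 * np.pi * 4.5 * t + ph[0])
            + amp_alpha * np.sin(2 * np.pi * 8.0 * t + ph[1])
            + amp_beta * np.sin(2 * np.pi * 12.0 * t + ph[2])
        )
        if noise_sd > 0:
            sig = sig + noise_sd * rng.standard_normal(n_out)
        data[c] = sig
    return EEGRecording(eeg_rate, list(channels), data)


def simulate_f0_track(
    session_length: float,
    rng: np.random.Generator,
    carrier: float = 220.0,
    mod_amplitude: float = 40.0,
    mod_rate: float = 3.0,
    voiced_fraction: float = 0.5,
    rate: float = 100.0,
    voiced_mean_dur: float = 1.5,
) -> F0Track:
    """Caregiver F0 surrogate: carrier plus sinusoidal modulation when voiced.

    Voiced and silent stretches alternate with exponential durations chosen
    so the expected voiced fraction matches ``voiced_fraction``. No clipped
    or co-vocalisation flags are set.
    """
    if session_length <= 0:
        raise ValueError("session_length must be positive")
    if not _F0_FLOOR <= carrier <= _F0_CEILING:
        raise ValueError(f"carrier must lie within [{_F0_FLOOR}, {_F0_CEILING}] Hz")
    if not 0.0 <= voiced_fraction <= 1.0:
        raise ValueError("voiced_fraction must be in [0, 1]")
    n = int(math.ceil(session_length * rate))
    times = np.arange(n) / rate
    voiced = np.zeros(n, dtype=bool)
    if voiced_fraction > 0:
        if voiced_fraction >= 1.0:
            voiced[:] = True
        else:
            silent_mean = voiced_mean_dur * (1.0 - voiced_fraction) / voiced_fraction
            t, state = 0.0, False  # start silent
            while t < session_length:
                dur = rng.exponential(voiced_mean_dur if state else silent_mean)
                if state:
                    i0, i1 = int(t * rate), min(int((t + dur) * rate), n)
                    voiced[i0:i1] = True
                t += dur
                state = not state
    f0 = np.full(n, np.nan)
    f0[voiced] = carrier + mod_amplitude * np.sin(2 * np.pi * mod_rate * times[voiced])
    speaker = np.where(voiced, "caregiver", "")
    return F0Track(times, f0, voiced, speaker, np.zeros(n, dtype=bool))


def simulate_session(
    config: SyntheticConfig,
    participant: str,
    section: int,
    rng: np.random.Generator,
    with_eeg: bool = False,
    with_f0: bool = True,
    truth: SyntheticTruth | None = None,
) -> DyadSession:
    """One dyad x play-section drawn from the configured generating model."""
    L = config.session_length
    infant_events = simulate_look_sequence(
        config.infant, L, rng, "infant",
        config.uncodable_rate, config.uncodable_mean_dur,
    )
    caregiver_events = simulate_caregiver_response(
        infant_events, config.caregiver, L, rng,
        depth=config.response_depth, window=config.response_window,
        uncodable_rate=config.uncodable_rate,
        uncodable_mean_dur=config.uncodable_mean_dur,
    )
    theta = simulate_theta_series(
        infant_events, rng,
        gain=config.theta_gain, lag=config.theta_lag,
        baseline=config.theta_baseline, noise_sd=config.theta_noise_sd,
        noise_rho=config.theta_noise_rho,
        session_length=L, rate=config.behaviour_rate,
    )
    eeg = None
    if with_eeg:
        eeg = simulate_eeg_from_theta(theta, rng, eeg_rate=config.eeg_rate)
    f0 = None
    if with_f0:
        f0 = simulate_f0_track(
            L, rng,
            carrier=config.f0_carrier,
            mod_amplitude=config.f0_mod_amplitude,
            mod_rate=config.f0_mod_rate,
            voiced_fraction=config.f0_voiced_fraction,
            rate=config.f0_track_rate,
        )
    if truth is not None:
        key = (participant, section)
        truth.infant_durations[key] = np.array(
            [e.duration for e in infant_events if e.category != "uncodable"]
        )
        truth.caregiver_durations[key] = np.array(
            [e.duration for e in caregiver_events if e.category != "uncodable"]
        )
    return DyadSession(
        participant=participant,
        section=section,
        session_length=L,
        infant_events=infant_events,
        caregiver_events=caregiver_events,
        theta=theta,
        eeg=eeg,
        f0=f0,
        meta={"config_seed": config.seed},
    )


def simulate_study(
    config: SyntheticConfig,
    n_dyads: int,
    sections: int = 2,
    with_eeg: bool = False,
    with_f0: bool = True,
) -> tuple[list[DyadSession], SyntheticTruth]:
    """Simulate a full study of ``n_dyads`` participants x ``sections``.

    All randomness flows from ``config.seed``; identical config implies
    byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    truth = SyntheticTruth(config=config)
    sessions: list[DyadSession] = []
    for d in range(n_dyads):
        pid = f"P{d + 1:02d}"
        for s in range(1, sections + 1):
            sessions.append(
                simulate_session(
                    config, pid, s, rng,
                    with_eeg=with_eeg, with_f0=with_f0, truth=truth,
                )
            )
    return sessions, truth


def zero_coupling(config: SyntheticConfig) -> SyntheticConfig:
    """A copy of ``config`` with every cross-signal coupling switched off."""
    return replace(config, theta_gain=0.0, response_depth=0.0)
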