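"""Orchestration of the three analysis parts over a study of dyad sessions.

Part 1: descriptive duration histograms, PACF with shuffled-duration
baselines, and the binary cross-correlation against Poisson surrogates.
Part 2: infant theta -- continuous cross-correlation with attention
durations, event-locked theta, within-look modulation, and the per-look
mixed model. Part 3: the same battery for caregiver gaze durations and for
the caregiver F0 rate-of-change salience series.

Participant-level exclusions (the 100 uV / 15% theta rule and the 30%
missing-vocalisation rule) are enacted here so the analysis modules stay
pure.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import eeg as eeg_mod
from .behavior import binary_attention_series, duration_histogram, duration_series
from .cluster import (
    ClusterResult,
    NullDistribution,
    cluster_significance,
    derangement_null,
    poisson_surrogate_pair,
)
from .eventlocked import (
    EventLockedCurve,
    duration_binned_lock,
    event_locked_significance,
    lock_to_onsets,
)
from .lagged import (
    LaggedCurve,
    group_average,
    lag_correlations,
    pacf_binary,
    preprocess_continuous,
    shuffled_duration_baseline,
    xcorr_binary,
    xcorr_continuous,
)
from .modulation import duration_binned_modulation
from .perlook import LMEResult, build_perlook_table, fit_lme
from .prosody import caregiver_f0_series, f0_rate_of_change
from .series import BehaviourSeries
from .session import DyadSession

__all__ = [
    "AnalysisConfig",
    "Part1Result",
    "Part2Result",
    "Part3Result",
    "run_part1",
    "run_part2",
    "run_part3",
    "log_outlier",
]


@dataclass
class AnalysisConfig:
    """Knobs shared by the three analysis parts."""

    seed: int
    n_shuffle: int = 100  # duration-shuffle PACF baselines
    n_poisson: int = 100  # Poisson surrogate draws
    n_perm: int = 1000  # derangement permutations
    alpha: float = 0.05
    fdr_q: float = 0.05
    pacf_bin_widths: tuple[float, ...] = (0.1, 0.2, 0.5, 1.0)
    pacf_max_lag: float = 10.0
    binary_max_lag: float = 10.0
    continuous_max_lag: float = 30.0
    lag_step: float = 0.5
    n_duration_bins: int = 5
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.n_perm < 20 or self.n_poisson < 20:
            raise ValueError("permutation counts must be at least 20")

    @classmethod
    def smoke(cls, seed: int, **kwargs) -> "AnalysisConfig":
        """Reduced-permutation profile for quick runs."""
        defaults = dict(n_shuffle=20, n_poisson=50, n_perm=50)
        defaults.update(kwargs)
        return cls(seed=seed, **defaults)


def by_participant(sessions: Sequence[DyadSession]) -> dict[str, list[DyadSession]]:
    out: dict[str, list[DyadSession]] = {}
    for s in sorted(sessions, key=lambda s: (s.participant, s.section)):
        out.setdefault(s.participant, []).append(s)
    return out


def log_outlier(series: BehaviourSeries, iqr_mult: float = 2.0) -> BehaviourSeries:
    """Log transform plus 2-IQR outlier masking, without detrending.

    The event-locked and modulation analyses use this lighter preprocessing;
    the cross-correlations add polynomial detrending on top (see
    :func:`dyadtheta.lagged.preprocess_continuous`).
    """
    v = series.values.copy()
    v[np.isfinite(v) & (v <= 0)] = np.nan
    with np.errstate(invalid="ignore"):
        v = np.log(v)
    finite = np.isfinite(v)
    if finite.any():
        q1, q3 = np.percentile(v[finite], [25, 75])
        iqr = q3 - q1
        v[finite & ((v > q3 + iqr_mult * iqr) | (v < q1 - iqr_mult * iqr))] = np.nan
    return series.copy_with(v)


def _session_theta(session: DyadSession, rng: np.random.Generator) -> BehaviourSeries | None:
    """Theta for a session: precomputed, or derived from EEG with exclusions."""
    if session.theta is not None:
        if session.eeg is not None and eeg_mod.exclude_noisy_theta(session.eeg):
            return None
        return session.theta
    if session.eeg is not None:
        return eeg_mod.theta_pipeline(session.eeg, rng)
    return None


# ---------------------------------------------------------------- part 1


@dataclass
class Part1Result:
    histograms: dict  # actor -> (table, overflow)
    pacf: dict  # (actor, bin_width) -> LaggedCurve
    pacf_baseline: dict  # (actor, bin_width) -> group-mean baseline curve
    xcorr: LaggedCurve
    poisson_null: NullDistribution
    clusters: ClusterResult


def run_part1(
    sessions: Sequence[DyadSession], config: AnalysisConfig
) -> Part1Result:
    """Descriptives, PACF + shuffled baselines, binary xcorr vs Poisson."""
    rng = np.random.default_rng(config.seed)
    groups = by_participant(sessions)
    for s in sessions:
        if not s.infant_events or not s.caregiver_events:
            raise ValueError(
                f"session {s.participant}/{s.section} is missing an actor"
            )
    histograms = {
        actor: duration_histogram(
            [e for s in sessions for e in getattr(s, f"{actor}_events")]
        )
        for actor in ("infant", "caregiver")
    }
    pacf_curves: dict = {}
    pacf_baseline: dict = {}
    for actor in ("infant", "caregiver"):
        for bw in config.pacf_bin_widths:
            per_pid: dict[str, list[np.ndarray]] = {}
            base_pid: dict[str, list[np.ndarray]] = {}
            lags = None
            for pid, secs in groups.items():
                for s in secs:
                    events = getattr(s, f"{actor}_events")
                    series = binary_attention_series(events, s.session_length)
                    lags, curve = pacf_binary(series, bw, config.pacf_max_lag)
                    per_pid.setdefault(pid, []).append(curve)
                    baseline = shuffled_duration_baseline(
                        events, rng, config.n_shuffle,
                        session_length=s.session_length,
                        bin_width=bw, max_lag=config.pacf_max_lag,
                    )
                    base_pid.setdefault(pid, []).append(baseline.mean(axis=0))
            pacf_curves[(actor, bw)] = group_average(per_pid, lags)
            pacf_baseline[(actor, bw)] = group_average(base_pid, lags)

    # binary cross-correlation, observed
    per_pid = {}
    lags = None
    session_means: list[tuple[float, float, float]] = []
    for pid, secs in groups.items():
        for s in secs:
            inf = binary_attention_series(s.infant_events, s.session_length)
            care = binary_attention_series(s.caregiver_events, s.session_length)
            lags, r = xcorr_binary(inf, care, config.binary_max_lag, config.lag_step)
            per_pid.setdefault(pid, []).append(r)
            mean_inf = np.mean(
                [e.duration for e in s.infant_events if e.category != "uncodable"]
            )
            mean_care = np.mean(
                [e.duration for e in s.caregiver_events if e.category != "uncodable"]
            )
            session_means.append((mean_inf, mean_care, s.session_length))
    observed = group_average(per_pid, lags)

    # Poisson surrogate null, built through the same averaging pipeline
    null_curves = np.empty((config.n_poisson, lags.size))
    for p in range(config.n_poisson):
        i = 0
        surro_pid: dict[str, list[np.ndarray]] = {}
        for pid, secs in groups.items():
            for s in secs:
                mi, mc, L = session_means[i]
                i += 1
                a, b = poisson_surrogate_pair(mi, mc, L, rng)
                _, r = xcorr_binary(a, b, config.binary_max_lag, config.lag_step)
                surro_pid.setdefault(pid, []).append(r)
        null_curves[p] = group_average(surro_pid, lags).group_mean
    null = NullDistribution(null_curves, lags, generator="poisson", seed=config.seed)
    clusters = cluster_significance(observed.group_mean, null, config.alpha)
    result = Part1Result(histograms, pacf_curves, pacf_baseline, observed, null, clusters)
    _maybe_save_part1(result, config)
    return result


# ---------------------------------------------------------------- part 2


@dataclass
class Part2Result:
    xcorr: LaggedCurve
    null: NullDistribution
    clusters: ClusterResult
    event_locked: EventLockedCurve
    event_clusters: ClusterResult
    binned_locked: list[EventLockedCurve]
    modulation_summaries: list
    modulation_tests: pd.DataFrame
    lme: LMEResult
    excluded_participants: list[str]


def _xcorr_with_derangement(
    x_inputs: Mapping[str, list[BehaviourSeries]],
    y_inputs: Mapping[str, list[BehaviourSeries]],
    config: AnalysisConfig,
    rng: np.random.Generator,
) -> tuple[LaggedCurve, NullDistribution, ClusterResult]:
    """Observed continuous xcorr plus derangement null and cluster test."""
    lags = np.arange(
        -config.continuous_max_lag,
        config.continuous_max_lag + config.lag_step / 2,
        config.lag_step,
    )
    per_pid = {
        pid: [
            xcorr_continuous(x, y, config.continuous_max_lag, config.lag_step)[1]
            for x, y in zip(x_inputs[pid], y_inputs[pid])
        ]
        for pid in x_inputs
    }
    observed = group_average(per_pid, lags)
    rate = next(iter(x_inputs.values()))[0].rate
    lag_samples = np.round(lags * rate).astype(int)

    def pair_curve(x: BehaviourSeries, y: BehaviourSeries) -> np.ndarray:
        n = min(x.n, y.n)  # truncate to the shorter common length
        return lag_correlations(x.values[:n], y.values[:n], lag_samples)

    null = derangement_null(x_inputs, y_inputs, pair_curve, lags, rng, config.n_perm)
    clusters = cluster_significance(observed.group_mean, null, config.alpha)
    return observed, null, clusters


def run_part2(
    sessions: Sequence[DyadSession], config: AnalysisConfig
) -> Part2Result:
    """Infant theta: forwards-prediction, reactive change, per-look model."""
    rng = np.random.default_rng(config.seed + 1)
    groups = by_participant(sessions)
    x_inputs: dict[str, list[BehaviourSeries]] = {}
    y_inputs: dict[str, list[BehaviourSeries]] = {}
    locked_inputs: dict[str, list] = {}
    excluded = []
    raw_inputs: dict[str, list] = {}
    for pid, secs in groups.items():
        xs, ys, locked, raw = [], [], [], []
        for s in secs:
            theta = _session_theta(s, rng)
            if theta is None:
                continue
            dur = duration_series(s.infant_events, session_length=s.session_length)
            xs.append(preprocess_continuous(dur))
            ys.append(preprocess_continuous(theta))
            locked.append((log_outlier(theta), s.infant_events))
            raw.append((theta, s.infant_events))
        if xs:
            x_inputs[pid], y_inputs[pid] = xs, ys
            locked_inputs[pid], raw_inputs[pid] = locked, raw
        else:
            excluded.append(pid)
    if len(x_inputs) < 2:
        raise ValueError("fewer than two participants with usable theta")
    observed, null, clusters = _xcorr_with_derangement(x_inputs, y_inputs, config, rng)
    event_curve, event_clusters = event_locked_significance(
        locked_inputs, rng, config.n_perm, config.alpha
    )
    binned = duration_binned_lock(locked_inputs, config.n_duration_bins)
    summaries, tests = duration_binned_modulation(
        locked_inputs, config.n_duration_bins, q=config.fdr_q
    )
    lme = fit_lme(build_perlook_table(raw_inputs))
    result = Part2Result(
        observed, null, clusters, event_curve, event_clusters, binned,
        summaries, tests, lme, excluded,
    )
    _maybe_save_generic(result, config, "part2")
    return result


# ---------------------------------------------------------------- part 3


@dataclass
class Part3Result:
    gaze_xcorr: LaggedCurve
    gaze_null: NullDistribution
    gaze_clusters: ClusterResult
    gaze_theta_xcorr: LaggedCurve | None
    gaze_theta_clusters: ClusterResult | None
    gaze_event_locked: EventLockedCurve
    gaze_event_clusters: ClusterResult
    gaze_modulation_tests: pd.DataFrame
    gaze_lme: LMEResult
    f0_xcorr: LaggedCurve | None
    f0_clusters: ClusterResult | None
    f0_event_locked: EventLockedCurve | None
    f0_event_clusters: ClusterResult | None
    f0_lme: LMEResult | None
    excluded_vocal: list[str]


def _f0_rate_series(s: DyadSession) -> BehaviourSeries | None:
    if s.f0 is None:
        return None
    res = caregiver_f0_series(s.f0)
    if res.excluded:
        return None
    return f0_rate_of_change(res.series)


def run_part3(
    sessions: Sequence[DyadSession],
    config: AnalysisConfig,
    include_theta: bool = True,
    include_f0: bool = True,
) -> Part3Result:
    """Caregiver gaze and vocal salience versus infant attention."""
    rng = np.random.default_rng(config.seed + 2)
    groups = by_participant(sessions)

    dur_x: dict[str, list[BehaviourSeries]] = {}
    care_y: dict[str, list[BehaviourSeries]] = {}
    locked_gaze: dict[str, list] = {}
    for pid, secs in groups.items():
        xs, ys, locked = [], [], []
        for s in secs:
            inf_dur = duration_series(s.infant_events, session_length=s.session_length)
            care_dur = duration_series(
                s.caregiver_events, session_length=s.session_length
            )
            xs.append(preprocess_continuous(inf_dur))
            ys.append(preprocess_continuous(care_dur))
            locked.append((log_outlier(care_dur), s.infant_events))
        dur_x[pid], care_y[pid], locked_gaze[pid] = xs, ys, locked
    gaze_obs, gaze_null, gaze_clusters = _xcorr_with_derangement(
        dur_x, care_y, config, rng
    )
    gaze_theta_obs = gaze_theta_clusters = None
    if include_theta:
        theta_x: dict[str, list[BehaviourSeries]] = {}
        care_y2: dict[str, list[BehaviourSeries]] = {}
        for pid, secs in groups.items():
            xs, ys = [], []
            for s in secs:
                theta = _session_theta(s, rng)
                if theta is None:
                    continue
                xs.append(preprocess_continuous(theta))
                ys.append(
                    preprocess_continuous(
                        duration_series(
                            s.caregiver_events, session_length=s.session_length
                        )
                    )
                )
            if xs:
                theta_x[pid], care_y2[pid] = xs, ys
        if len(theta_x) >= 2:
            gaze_theta_obs, _, gaze_theta_clusters = _xcorr_with_derangement(
                theta_x, care_y2, config, rng
            )
    gaze_event, gaze_event_clusters = event_locked_significance(
        locked_gaze, rng, config.n_perm, config.alpha
    )
    _, gaze_mod_tests = duration_binned_modulation(
        locked_gaze, config.n_duration_bins, q=config.fdr_q
    )
    gaze_lme = fit_lme(
        build_perlook_table(
            {
                pid: [
                    (
                        duration_series(
                            s.caregiver_events, session_length=s.session_length
                        ),
                        s.infant_events,
                    )
                    for s in groups[pid]
                ]
                for pid in groups
            }
        )
    )

    f0_obs = f0_clusters = f0_event = f0_event_clusters = f0_lme = None
    excluded_vocal: list[str] = []
    if include_f0:
        f0_x: dict[str, list[BehaviourSeries]] = {}
        f0_y: dict[str, list[BehaviourSeries]] = {}
        locked_f0: dict[str, list] = {}
        raw_f0: dict[str, list] = {}
        for pid, secs in groups.items():
            xs, ys, locked, raw = [], [], [], []
            for s in secs:
                rate_series = _f0_rate_series(s)
                if rate_series is None:
                    continue
                xs.append(
                    preprocess_continuous(
                        duration_series(s.infant_events, session_length=s.session_length)
                    )
                )
                ys.append(preprocess_continuous(rate_series))
                locked.append((log_outlier(rate_series), s.infant_events))
                raw.append((rate_series, s.infant_events))
            if xs:
                f0_x[pid], f0_y[pid] = xs, ys
                locked_f0[pid], raw_f0[pid] = locked, raw
            else:
                excluded_vocal.append(pid)
        if len(f0_x) >= 2:
            f0_obs, _, f0_clusters = _xcorr_with_derangement(f0_x, f0_y, config, rng)
            f0_event, f0_event_clusters = event_locked_significance(
                locked_f0, rng, config.n_perm, config.alpha
            )
            f0_lme = fit_lme(build_perlook_table(raw_f0))
    result = Part3Result(
        gaze_obs, gaze_null, gaze_clusters,
        gaze_theta_obs, gaze_theta_clusters,
        gaze_event, gaze_event_clusters, gaze_mod_tests, gaze_lme,
        f0_obs, f0_clusters, f0_event, f0_event_clusters, f0_lme,
        excluded_vocal,
    )
    _maybe_save_generic(result, config, "part3")
    return result


# ---------------------------------------------------------------- output


def _config_hash(config: AnalysisConfig) -> str:
    payload = json.dumps(
        {k: v for k, v in vars(config).items() if k != "out_dir"},
        sort_keys=True, default=str,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _maybe_save_part1(result: Part1Result, config: AnalysisConfig) -> None:
    if config.out_dir is None:
        return
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for actor, (table, overflow) in result.histograms.items():
        table.to_csv(out / f"part1_histogram_{actor}.csv")
    result.xcorr.to_frame().to_csv(out / "part1_binary_xcorr.csv", index=False)
    with open(out / "part1_clusters.json", "w") as fh:
        json.dump(result.clusters.to_dict(), fh, indent=2)
    _write_manifest(out, config)


def _maybe_save_generic(result, config: AnalysisConfig, tag: str) -> None:
    if config.out_dir is None:
        return
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload: dict = {}
    for name, value in vars(result).items():
        if isinstance(value, ClusterResult):
            payload[name] = value.to_dict()
        elif isinstance(value, LMEResult):
            payload[name] = value.to_dict()
        elif isinstance(value, LaggedCurve):
            value.to_frame().to_csv(out / f"{tag}_{name}.csv", index=False)
        elif isinstance(value, EventLockedCurve):
            value.to_frame().to_csv(out / f"{tag}_{name}.csv", index=False)
        elif isinstance(value, pd.DataFrame):
            value.to_csv(out / f"{tag}_{name}.csv", index=False)
    with open(out / f"{tag}_results.json", "w") as fh:
        json.dump(payload, fh, indent=2, default=float)
    _write_manifest(out, config)


def _write_manifest(out: Path, config: AnalysisConfig) -> None:
    manifest = {
        "config": {k: str(v) for k, v in vars(config).items()},
        "config_hash": _config_hash(config),
        "outputs": sorted(p.name for p in out.iterdir() if p.name != "manifest.json"),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
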