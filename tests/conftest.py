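"""Shared fixtures and study-replicate helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

import dyadtheta as dt
from dyadtheta.pipeline import AnalysisConfig, _xcorr_with_derangement, log_outlier
from dyadtheta.synthetic import zero_coupling


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_study():
    """Six dyads, two 120 s sections, default (coupled) generator."""
    cfg = dt.SyntheticConfig(seed=7, session_length=120.0)
    sessions, truth = dt.simulate_study(cfg, 6)
    return sessions, truth


# ---------------------------------------------------------------- replicate
# study builders used by both the calibration/power tests and the
# acceptance suite; one 300 s section per dyad


def replicate_sessions(seed: int, n_dyads: int = 20, coupled: bool = False,
                       sections: int = 1, **config_kwargs):
    cfg = dt.SyntheticConfig(seed=seed, **config_kwargs)
    if not coupled:
        cfg = zero_coupling(cfg)
    sessions, truth = dt.simulate_study(cfg, n_dyads, sections=sections, with_f0=False)
    return sessions, truth


def continuous_xcorr_study(seed: int, n_perm: int = 200, coupled: bool = False,
                           sections: int = 1, **config_kwargs):
    """Observed duration x theta cross-correlation plus derangement cluster test."""
    sessions, _ = replicate_sessions(
        seed, coupled=coupled, sections=sections, **config_kwargs
    )
    x_inputs, y_inputs = {}, {}
    for s in sessions:
        x_inputs.setdefault(s.participant, []).append(
            dt.preprocess_continuous(
                dt.duration_series(s.infant_events, session_length=s.session_length)
            )
        )
        y_inputs.setdefault(s.participant, []).append(dt.preprocess_continuous(s.theta))
    ac = AnalysisConfig(seed=seed, n_perm=n_perm)
    observed, null, clusters = _xcorr_with_derangement(
        x_inputs, y_inputs, ac, np.random.default_rng(seed)
    )
    return observed, clusters


def binary_xcorr_study(seed: int, n_poisson: int = 100, **config_kwargs):
    """Observed binary cross-correlation plus Poisson-surrogate cluster test."""
    from dyadtheta.cluster import (
        NullDistribution,
        cluster_significance,
        poisson_surrogate_pair,
    )
    from dyadtheta.lagged import group_average

    sessions, _ = replicate_sessions(seed, **config_kwargs)
    rng = np.random.default_rng(seed)
    per, means = {}, []
    lags = None
    for s in sessions:
        inf = dt.binary_attention_series(s.infant_events, s.session_length)
        care = dt.binary_attention_series(s.caregiver_events, s.session_length)
        lags, r = dt.xcorr_binary(inf, care)
        per.setdefault(s.participant, []).append(r)
        means.append(
            (
                np.mean([e.duration for e in s.infant_events if e.category != "uncodable"]),
                np.mean([e.duration for e in s.caregiver_events if e.category != "uncodable"]),
                s.session_length,
            )
        )
    observed = group_average(per, lags)
    null_curves = np.empty((n_poisson, lags.size))
    for p in range(n_poisson):
        per_s = {}
        for k, s in enumerate(sessions):
            a, b = poisson_surrogate_pair(means[k][0], means[k][1], means[k][2], rng)
            _, r = dt.xcorr_binary(a, b)
            per_s.setdefault(s.participant, []).append(r)
        null_curves[p] = group_average(per_s, lags).group_mean
    null = NullDistribution(null_curves, lags, generator="poisson")
    return observed, cluster_significance(observed.group_mean, null)


def eventlocked_study(seed: int, n_perm: int = 200, coupled: bool = False,
                      **config_kwargs):
    """Event-locked caregiver-duration curve plus derangement cluster test."""
    from dyadtheta.eventlocked import event_locked_significance

    sessions, truth = replicate_sessions(seed, coupled=coupled, **config_kwargs)
    inputs = {}
    for s in sessions:
        care = log_outlier(
            dt.duration_series(s.caregiver_events, session_length=s.session_length)
        )
        inputs.setdefault(s.participant, []).append((care, s.infant_events))
    curve, result = event_locked_significance(
        inputs, np.random.default_rng(seed), n_perm=n_perm
    )
    return curve, result, truth
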