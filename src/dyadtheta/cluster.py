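"""Null models and cluster-based Monte-Carlo significance.

Three nulls are provided: duration shuffling (in :mod:`dyadtheta.lagged`),
Poisson point-process surrogate dyads, and between-participant derangement
pairing. Significance of a correlation (or event-locked) curve is assessed
by the cluster procedure: pointwise two-sided flags at the per-lag 2.5th and
97.5th centiles of the null, maximal same-sign runs as clusters, and a
max-cluster-size threshold distribution built by a leave-one-out pass over
the surrogates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .series import BEHAVIOUR_RATE, BehaviourSeries

__all__ = [
    "NullDistribution",
    "Cluster",
    "ClusterResult",
    "poisson_surrogate_pair",
    "derangement_pairing",
    "derangement_null",
    "cluster_significance",
]


@dataclass
class NullDistribution:
    """Group-level surrogate curves, one row per permutation."""

    curves: np.ndarray  # (n_perm, n_lags)
    lags: np.ndarray
    generator: str = ""
    seed: int | None = None

    @property
    def n_perm(self) -> int:
        return self.curves.shape[0]


@dataclass
class Cluster:
    start_lag: float
    end_lag: float
    size: int  # count of contiguous significant lags
    sign: int  # +1 or -1
    p: float
    significant: bool


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    pointwise_sig: np.ndarray  # per-lag flags in {-1, 0, +1}
    alpha: float
    max_cluster_null: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def significant_clusters(self) -> list[Cluster]:
        return [c for c in self.clusters if c.significant]

    @property
    def any_significant(self) -> bool:
        return any(c.significant for c in self.clusters)

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "clusters": [
                {
                    "start_lag": c.start_lag,
                    "end_lag": c.end_lag,
                    "size": c.size,
                    "sign": c.sign,
                    "p": c.p,
                    "significant": c.significant,
                }
                for c in self.clusters
            ],
        }


def poisson_surrogate_pair(
    mean_dur_infant: float,
    mean_dur_caregiver: float,
    session_length: float,
    rng: np.random.Generator,
    rate: float = BEHAVIOUR_RATE,
) -> tuple[BehaviourSeries, BehaviourSeries]:
    """Independent memoryless surrogate dyad as alternating binary series.

    Each actor's look durations are i.i.d. exponential with the given mean
    (a Poisson point process of attention shifts), converted to the same
    alternating 0/1 representation as the observed data.
    """
    if mean_dur_infant <= 0 or mean_dur_caregiver <= 0:
        raise ValueError("mean durations must be positive")
    out = []
    for mean in (mean_dur_infant, mean_dur_caregiver):
        n_guess = max(8, int(3 * session_length / mean))
        durs = rng.exponential(mean, size=n_guess)
        while durs.sum() < session_length:
            durs = np.concatenate([durs, rng.exponential(mean, size=n_guess)])
        n = int(math.ceil(session_length * rate))
        # per-look sample counts on the half-open grid, then alternate bits
        bounds = np.minimum(np.cumsum(durs), session_length)
        edges = np.ceil(bounds * rate - 1e-9).astype(int)
        counts = np.diff(np.concatenate([[0], edges]))
        counts[-1] += n - counts.sum()  # absorb rounding at the session end
        bits = np.arange(counts.size) % 2
        out.append(BehaviourSeries(np.repeat(bits, counts).astype(float)[:n], rate))
    return out[0], out[1]


def derangement_pairing(
    ids: Sequence, rng: np.random.Generator, max_tries: int = 100_000
) -> dict:
    """A uniform fixed-point-free pairing by rejection sampling.

    Random permutations are drawn until one has no fixed point (acceptance
    probability ~ 1/e), giving an exactly uniform derangement.
    """
    ids = list(ids)
    n = len(ids)
    if n < 2:
        raise ValueError("derangement needs at least two participants")
    for _ in range(max_tries):
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return {ids[i]: ids[perm[i]] for i in range(n)}
    raise RuntimeError("failed to draw a derangement")  # pragma: no cover


def derangement_null(
    x_inputs: Mapping[str, Sequence],
    y_inputs: Mapping[str, Sequence],
    pair_curve: Callable,
    lags: np.ndarray,
    rng: np.random.Generator,
    n_perm: int = 1000,
) -> NullDistribution:
    """Between-participant derangement null for any paired curve statistic.

    For each permutation, participant ``i``'s x-side sections are paired with
    participant ``d(i)``'s y-side sections (section-wise; ``pair_curve`` is
    responsible for truncating to the common length), curves are averaged
    over sections and then participants -- exactly the observed pipeline.
    Curves for each ordered participant pair are cached, so the cost grows
    with the number of distinct pairs rather than with ``n_perm``.
    """
    pids = sorted(x_inputs)
    if set(pids) != set(y_inputs):
        raise ValueError("x and y inputs must cover the same participants")
    cache: dict[tuple[str, str], np.ndarray] = {}

    import warnings

    def participant_curve(i: str, j: str) -> np.ndarray:
        key = (i, j)
        if key not in cache:
            xs, ys = x_inputs[i], y_inputs[j]
            curves = [pair_curve(x, y) for x, y in zip(xs, ys)]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                cache[key] = np.nanmean(np.vstack(curves), axis=0)
        return cache[key]

    curves = np.empty((n_perm, len(lags)))
    for p in range(n_perm):
        d = derangement_pairing(pids, rng)
        stack = np.vstack([participant_curve(i, d[i]) for i in pids])
        with np.errstate(invalid="ignore"):
            curves[p] = np.nanmean(stack, axis=0)
    return NullDistribution(curves, np.asarray(lags), generator="derangement")


def _pointwise_flags(
    curve: np.ndarray, null_curves: np.ndarray, alpha: float
) -> np.ndarray:
    if np.isnan(null_curves).any():
        lo, hi = np.nanpercentile(
            null_curves, [100 * alpha / 2, 100 * (1 - alpha / 2)], axis=0
        )
    else:
        lo, hi = np.percentile(
            null_curves, [100 * alpha / 2, 100 * (1 - alpha / 2)], axis=0
        )
    flags = np.zeros(curve.size, dtype=int)
    with np.errstate(invalid="ignore"):
        flags[np.isfinite(curve) & (curve > hi)] = 1
        flags[np.isfinite(curve) & (curve < lo)] = -1
    return flags


def _loo_flags(null_curves: np.ndarray, alpha: float) -> np.ndarray:
    """Leave-one-out pointwise flags for every surrogate, vectorised.

    For each surrogate s and lag, s's curve is compared with the percentile
    band of the remaining n-1 surrogates. The reduced-array percentiles are
    read off a single sort per lag: removing the element of rank r from the
    sorted column shifts entries at positions >= r down by one.
    """
    m, n_lags = null_curves.shape
    qs = np.array([alpha / 2, 1 - alpha / 2])
    pos = qs * (m - 2)  # linear-interpolation positions in the reduced array
    lo_i = np.floor(pos).astype(int)
    frac = pos - lo_i
    flags = np.zeros((m, n_lags), dtype=int)
    for c in range(n_lags):
        v = null_curves[:, c]
        if np.isnan(v).any():  # rare: fall back to the direct computation
            for s in range(m):
                rest = np.delete(v, s)
                lo, hi = np.nanpercentile(rest, 100 * qs)
                if np.isfinite(v[s]):
                    flags[s, c] = 1 if v[s] > hi else (-1 if v[s] < lo else 0)
            continue
        order = np.argsort(v, kind="stable")
        S = v[order]
        rank = np.empty(m, dtype=int)
        rank[order] = np.arange(m)
        for qi, sign in ((0, -1), (1, 1)):
            i0, f = lo_i[qi], frac[qi]
            a = np.where(i0 < rank, S[i0], S[min(i0 + 1, m - 1)])
            b = np.where(i0 + 1 < rank, S[i0 + 1], S[min(i0 + 2, m - 1)])
            bound = (1 - f) * a + f * b
            if sign > 0:
                flags[v > bound, c] = 1
            else:
                flags[(v < bound) & (flags[:, c] == 0), c] = -1
    return flags


def _clusters_of(flags: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal same-sign runs as (start_index, end_index_inclusive, sign)."""
    runs = []
    start = None
    for i, f in enumerate(flags):
        if f == 0:
            if start is not None:
                runs.append((start, i - 1, int(flags[start])))
                start = None
        elif start is None:
            start = i
        elif f != flags[start]:  # mixed-sign runs split at sign changes
            runs.append((start, i - 1, int(flags[start])))
            start = i
    if start is not None:
        runs.append((start, flags.size - 1, int(flags[start])))
    return runs


def _max_cluster_size(flags: np.ndarray) -> int:
    runs = _clusters_of(flags)
    return max((r[1] - r[0] + 1 for r in runs), default=0)


def _band(null_curves: np.ndarray, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    if np.isnan(null_curves).any():
        lo, hi = np.nanpercentile(
            null_curves, [100 * alpha / 2, 100 * (1 - alpha / 2)], axis=0
        )
    else:
        lo, hi = np.percentile(
            null_curves, [100 * alpha / 2, 100 * (1 - alpha / 2)], axis=0
        )
    return lo, hi


def _cluster_masses(
    curve: np.ndarray, flags: np.ndarray, lo: np.ndarray, hi: np.ndarray,
    mass: str,
) -> list[float]:
    """Mass of each maximal run: its length, or its summed band exceedance."""
    out = []
    for start, end, sign in _clusters_of(flags):
        if mass == "count":
            out.append(float(end - start + 1))
        else:
            seg = slice(start, end + 1)
            exc = (curve[seg] - hi[seg]) if sign > 0 else (lo[seg] - curve[seg])
            out.append(float(np.nansum(np.clip(exc, 0, None))))
    return out


def cluster_significance(
    observed: np.ndarray,
    null: NullDistribution,
    alpha: float = 0.05,
    mass: str = "count",
) -> ClusterResult:
    """Cluster-based Monte-Carlo test of a curve against a null distribution.

    Pointwise flags use the per-lag ``alpha/2`` and ``1 - alpha/2`` centiles
    of the null. The cluster-mass threshold distribution is built by a
    leave-one-out pass: each surrogate's maximal cluster mass is computed
    against the centiles of the remaining surrogates. An observed cluster is
    significant when its mass exceeds the ``1 - alpha`` centile of that
    distribution; ``p`` is the exceedance proportion.

    ``mass="count"`` (default) scores a cluster by its number of contiguous
    significant lags; ``mass="sum"`` by its summed exceedance beyond the
    pointwise band.
    """
    if mass not in ("count", "sum"):
        raise ValueError("mass must be 'count' or 'sum'")
    observed = np.asarray(observed, float)
    if null.n_perm < 20:
        raise ValueError("need at least 20 surrogates for centile thresholds")
    if observed.size != null.curves.shape[1]:
        raise ValueError("observed curve and null are on different lag grids")
    flags = _pointwise_flags(observed, null.curves, alpha)
    loo = _loo_flags(null.curves, alpha)
    if mass == "count":
        max_masses = np.array(
            [_max_cluster_size(loo[s]) for s in range(null.n_perm)], dtype=float
        )
    else:
        max_masses = np.empty(null.n_perm)
        for s in range(null.n_perm):
            rest = np.delete(null.curves, s, axis=0)
            lo_s, hi_s = _band(rest, alpha)
            masses = _cluster_masses(null.curves[s], loo[s], lo_s, hi_s, mass)
            max_masses[s] = max(masses, default=0.0)
    threshold = np.percentile(max_masses, 100 * (1 - alpha))
    lo_b, hi_b = _band(null.curves, alpha)
    masses = _cluster_masses(observed, flags, lo_b, hi_b, mass)
    clusters = []
    for (start, end, sign), m in zip(_clusters_of(flags), masses):
        p = float(np.mean(max_masses >= m))
        clusters.append(
            Cluster(
                start_lag=float(null.lags[start]),
                end_lag=float(null.lags[end]),
                size=end - start + 1,
                sign=sign,
                p=p,
                significant=bool(m > threshold),
            )
        )
    return ClusterResult(clusters, flags, alpha, max_masses)


def cluster_significance_vs_poisson(
    observed: np.ndarray,
    poisson_null: NullDistribution,
    alpha: float = 0.05,
) -> ClusterResult:
    """Cluster test against the Poisson point-process surrogate distribution.

    Identical machinery to :func:`cluster_significance`; the null is the
    set of (typically 100) Poisson surrogate group curves.
    """
    return cluster_significance(observed, poisson_null, alpha)
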