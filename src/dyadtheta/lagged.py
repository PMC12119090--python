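"""PACF and lagged cross-correlation with the study's averaging conventions.

Lag sign convention: ``r(tau) = corr(x(t), y(t + tau))`` with ``x`` the
infant-side variable throughout, so positive lags mean the second variable
*follows* the first. Curves are computed per session, averaged over the two
play sections of each participant, and then averaged across participants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .behavior import binary_attention_series
from .events import LookEvent
from .series import BehaviourSeries

__all__ = [
    "LaggedCurve",
    "lag_correlations",
    "pacf_binary",
    "shuffled_duration_baseline",
    "xcorr_binary",
    "preprocess_continuous",
    "xcorr_continuous",
    "group_average",
]

MIN_OVERLAP = 100  # samples (2 s at 50 Hz) for a lag to be defined


@dataclass
class LaggedCurve:
    """A correlation-versus-lag curve with per-participant structure."""

    lags: np.ndarray  # seconds, strictly increasing
    per_participant: dict = field(default_factory=dict)  # pid -> curve
    group_mean: np.ndarray | None = None
    group_sem: np.ndarray | None = None
    n_valid: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        """Tidy (lag_s, participant, value) long table plus group rows."""
        rows = [
            {"lag_s": l, "participant": pid, "value": v}
            for pid, curve in self.per_participant.items()
            for l, v in zip(self.lags, curve)
        ]
        if self.group_mean is not None:
            rows += [
                {"lag_s": l, "participant": "__group__", "value": v}
                for l, v in zip(self.lags, self.group_mean)
            ]
        return pd.DataFrame(rows)


def group_average(
    per_participant_section_curves: Mapping[str, Sequence[np.ndarray]],
    lags: np.ndarray,
) -> LaggedCurve:
    """Average curves over sections within participant, then across participants."""
    from ._util import nanmean_quiet, nanstd_quiet

    per_participant = {
        pid: nanmean_quiet(np.vstack(curves), axis=0)
        for pid, curves in per_participant_section_curves.items()
        if len(curves)
    }
    stack = np.vstack(list(per_participant.values()))
    n_valid = np.sum(np.isfinite(stack), axis=0)
    mean = nanmean_quiet(stack, axis=0)
    sd = nanstd_quiet(stack, axis=0, ddof=1)
    sem = np.where(n_valid > 1, sd / np.sqrt(np.maximum(n_valid, 1)), np.nan)
    return LaggedCurve(np.asarray(lags), per_participant, mean, sem, n_valid)


def _corr_from_sums(n, sx, sy, sxx, syy, sxy):
    num = n * sxy - sx * sy
    den = (n * sxx - sx**2) * (n * syy - sy**2)
    with np.errstate(invalid="ignore"):
        return num / math.sqrt(den) if den > 0 else np.nan


def lag_correlations(
    x: np.ndarray,
    y: np.ndarray,
    lag_samples: np.ndarray,
    method: str = "pearson",
    min_overlap: int = MIN_OVERLAP,
) -> np.ndarray:
    """``corr(x(t), y(t + k))`` for each integer lag ``k``, NaN-aware.

    Sums over the jointly non-missing overlap are accumulated with dot
    products so each lag equals the plain correlation of the explicitly
    shifted arrays. Spearman ranks each overlap; for dichotomous data the
    rank transform is affine, so Pearson is used directly there.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = min(x.size, y.size)
    x, y = x[:n], y[:n]
    mx, my = np.isfinite(x), np.isfinite(y)
    if method == "spearman":
        xf, yf = x[mx], y[my]

        def _dichotomous(v: np.ndarray) -> bool:
            if v.size == 0:
                return True
            lo, hi = v.min(), v.max()
            return lo == hi or bool(np.all((v == lo) | (v == hi)))

        if _dichotomous(xf) and _dichotomous(yf):
            method = "pearson"  # ranks are affine in a two-valued variable
    out = np.empty(lag_samples.size)
    if method == "pearson":
        if mx.all() and my.all():
            # no missing data: marginal sums come from prefix sums, so only
            # the cross-product needs a dot per lag
            cx, cxx = np.concatenate([[0], np.cumsum(x)]), np.concatenate([[0], np.cumsum(x * x)])
            cy, cyy = np.concatenate([[0], np.cumsum(y)]), np.concatenate([[0], np.cumsum(y * y)])
            for i, k in enumerate(lag_samples):
                k = int(k)
                if n - abs(k) < min_overlap:
                    out[i] = np.nan
                    continue
                m = n - abs(k)
                if k >= 0:
                    sx, sxx = cx[m] - cx[0], cxx[m] - cxx[0]
                    sy, syy = cy[n] - cy[k], cyy[n] - cyy[k]
                    sxy = x[:m] @ y[k:]
                else:
                    sx, sxx = cx[n] - cx[-k], cxx[n] - cxx[-k]
                    sy, syy = cy[m] - cy[0], cyy[m] - cyy[0]
                    sxy = x[-k:] @ y[:m]
                out[i] = _corr_from_sums(m, sx, sy, sxx, syy, sxy)
            return out
        xv = np.where(mx, x, 0.0)
        yv = np.where(my, y, 0.0)
        x2, y2 = xv * xv, yv * yv
        fmx, fmy = mx.astype(float), my.astype(float)
        for i, k in enumerate(lag_samples):
            k = int(k)
            if abs(k) >= n:
                out[i] = np.nan
                continue
            if k >= 0:
                a, a2, ma = xv[: n - k], x2[: n - k], fmx[: n - k]
                b, b2, mb = yv[k:], y2[k:], fmy[k:]
            else:
                a, a2, ma = xv[-k:], x2[-k:], fmx[-k:]
                b, b2, mb = yv[: n + k], y2[: n + k], fmy[: n + k]
            nn = ma @ mb
            if nn < min_overlap:
                out[i] = np.nan
                continue
            out[i] = _corr_from_sums(nn, a @ mb, ma @ b, a2 @ mb, ma @ b2, a @ b)
        return out
    # generic Spearman: rank within each overlap
    for i, k in enumerate(lag_samples):
        k = int(k)
        if abs(k) >= n:
            out[i] = np.nan
            continue
        if k >= 0:
            a, b = x[: n - k], y[k:]
        else:
            a, b = x[-k:], y[: n + k]
        m = np.isfinite(a) & np.isfinite(b)
        if m.sum() < min_overlap:
            out[i] = np.nan
            continue
        ra, rb = rankdata(a[m]), rankdata(b[m])
        out[i] = _corr_from_sums(
            ra.size, ra.sum(), rb.sum(), ra @ ra, rb @ rb, ra @ rb
        )
    return out


def _rebin_binary(series: BehaviourSeries, bin_width: float) -> np.ndarray:
    """Majority-vote re-binning of a binary 50 Hz series (ties -> bin start)."""
    per_bin = bin_width * series.rate
    if abs(per_bin - round(per_bin)) > 1e-9:
        raise ValueError("bin_width must be a multiple of the sample interval")
    per_bin = int(round(per_bin))
    v = series.values
    if per_bin == 1:
        return v.copy()
    n_bins = v.size // per_bin
    out = np.full(n_bins, np.nan)
    for i in range(n_bins):
        chunk = v[i * per_bin:(i + 1) * per_bin]
        finite = np.isfinite(chunk)
        if finite.sum() * 2 < chunk.size:
            continue
        ones = np.sum(chunk[finite] == 1)
        zeros = finite.sum() - ones
        if ones > zeros:
            out[i] = 1.0
        elif zeros > ones:
            out[i] = 0.0
        else:
            out[i] = chunk[finite][0]  # tie: bin-start value
    return out


def pacf_binary(
    series: BehaviourSeries,
    bin_width: float = 0.1,
    max_lag: float = 10.0,
    min_cases: int = 30,
) -> tuple[np.ndarray, np.ndarray]:
    """Partial autocorrelation of a binary attention series by OLS.

    PACF(k) is the coefficient of ``x(t-k)`` in the least-squares regression
    (with intercept) of ``x(t)`` on ``x(t-1) .. x(t-k)`` over complete cases,
    after re-binning to ``bin_width`` seconds. Lags with fewer than
    ``min_cases`` complete cases are missing.
    """
    x = _rebin_binary(series, bin_width)
    n_lags = int(round(max_lag / bin_width))
    lags = np.arange(1, n_lags + 1) * bin_width
    out = np.full(n_lags, np.nan)
    n = x.size
    finite = np.isfinite(x)
    for k in range(1, n_lags + 1):
        if n <= k:
            break
        # windows[t] = [x(t-k), ..., x(t-1), x(t)] for t = k .. n-1
        windows = np.lib.stride_tricks.sliding_window_view(x, k + 1)
        cases = np.all(
            np.lib.stride_tricks.sliding_window_view(finite, k + 1), axis=1
        )
        if cases.sum() < min_cases:
            continue
        w = windows[cases]
        design = np.empty((w.shape[0], k + 1))
        design[:, 0] = 1.0
        design[:, 1:] = w[:, k - 1:: -1]  # x(t-1) .. x(t-k)
        resp = w[:, k]
        gram = design.T @ design
        rhs = design.T @ resp
        try:
            beta = np.linalg.solve(gram, rhs)
        except np.linalg.LinAlgError:
            beta, *_ = np.linalg.lstsq(design, resp, rcond=None)
        out[k - 1] = beta[-1]
    return lags, out


def shuffled_duration_baseline(
    events: Sequence[LookEvent],
    rng: np.random.Generator,
    n_perm: int = 100,
    session_length: float | None = None,
    rate: float | None = None,
    **pacf_kwargs,
) -> np.ndarray:
    """PACF distribution after randomly shuffling look durations in time.

    Look durations (of codable looks) are permuted uniformly, the alternating
    binary series rebuilt from the shuffled sequence, and the PACF recomputed.
    Returns an (n_perm, n_lags) array; the caller averages over permutations
    per participant.
    """
    codable = [e for e in events if e.category != "uncodable"]
    if len(codable) < 2:
        raise ValueError("need at least two codable looks to shuffle")
    durations = np.array([e.duration for e in codable])
    cats = [e.category for e in codable]
    actor = codable[0].actor
    if session_length is None:
        session_length = max(e.offset for e in events)
    curves = []
    for _ in range(n_perm):
        perm = rng.permutation(durations.size)
        t = 0.0
        shuffled = []
        for j in perm:
            shuffled.append(LookEvent(actor, t, t + durations[j], cats[j]))
            t += durations[j]
        series = binary_attention_series(
            shuffled, session_length=session_length,
            **({"rate": rate} if rate else {}),
        )
        _, pacf = pacf_binary(series, **pacf_kwargs)
        curves.append(pacf)
    return np.vstack(curves)


def xcorr_binary(
    infant: BehaviourSeries,
    caregiver: BehaviourSeries,
    max_lag: float = 10.0,
    step: float = 0.5,
    min_overlap: int = MIN_OVERLAP,
) -> tuple[np.ndarray, np.ndarray]:
    """Rank cross-correlation of the two binary attention series, lags 0..+max.

    ``r(tau) = corr(infant(t), caregiver(t + tau))`` over jointly non-missing
    samples, by Spearman correlation.
    """
    if infant.rate != caregiver.rate:
        raise ValueError("series rates differ")
    lags = np.arange(0.0, max_lag + step / 2, step)
    lag_samples = np.round(lags * infant.rate).astype(int)
    r = lag_correlations(
        infant.values, caregiver.values, lag_samples, "spearman", min_overlap
    )
    return lags, r


def preprocess_continuous(
    series: BehaviourSeries,
    iqr_mult: float = 2.0,
    min_samples: int = 10,
) -> BehaviourSeries:
    """Log-transform, 2-IQR outlier masking, and polynomial detrending.

    Non-positive values become missing; values beyond ``Q3 + 2 IQR`` or below
    ``Q1 - 2 IQR`` of the session's log values are masked; degree-1 and
    degree-2 polynomials in time are fit by least squares and the residuals
    of the fit with the lower small-sample AIC are returned.
    """
    v = series.values.copy()
    nonpos = np.isfinite(v) & (v <= 0)
    v[nonpos] = np.nan
    with np.errstate(invalid="ignore"):
        v = np.log(v)
    finite = np.isfinite(v)
    if finite.sum() < min_samples:
        raise ValueError(
            f"only {int(finite.sum())} usable samples after log transform"
        )
    q1, q3 = np.percentile(v[finite], [25, 75])
    iqr = q3 - q1
    outlier = finite & ((v > q3 + iqr_mult * iqr) | (v < q1 - iqr_mult * iqr))
    v[outlier] = np.nan
    finite = np.isfinite(v)
    t = np.arange(v.size) / series.rate
    tc = t - t.mean()
    best_resid, best_aicc = None, np.inf
    nn = int(finite.sum())
    for degree in (1, 2):
        coef = np.polyfit(tc[finite], v[finite], degree)
        fitted = np.polyval(coef, tc)
        resid = v - fitted
        rss = float(np.nansum(resid[finite] ** 2))
        k = degree + 2  # coefficients + error variance
        aicc = nn * math.log(max(rss / nn, 1e-300)) + 2 * k
        if nn - k - 1 > 0:
            aicc += 2 * k * (k + 1) / (nn - k - 1)
        if aicc < best_aicc:
            best_aicc, best_resid = aicc, resid
    return series.copy_with(best_resid)


def xcorr_continuous(
    x: BehaviourSeries,
    y: BehaviourSeries,
    max_lag: float = 30.0,
    step: float = 0.5,
    min_overlap: int = MIN_OVERLAP,
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson cross-correlation at signed lags -max..+max.

    Positive lags mean ``y`` follows ``x`` (``x`` is the infant-side
    variable throughout the pipeline).
    """
    if x.rate != y.rate:
        raise ValueError("series rates differ")
    lags = np.arange(-max_lag, max_lag + step / 2, step)
    lag_samples = np.round(lags * x.rate).astype(int)
    r = lag_correlations(x.values, y.values, lag_samples, "pearson", min_overlap)
    return lags, r
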