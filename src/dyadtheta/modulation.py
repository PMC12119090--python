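"""Within-look modulation: three chunks per look, Wilcoxon tests, FDR.

Each infant object look is split into three equal chunks by time; the
continuous variable over the *first half* of each chunk is averaged per
look, then over looks, sections and participants, giving three paired chunk
values per participant. Pairwise chunk differences are tested with Wilcoxon
signed-rank tests and corrected with the Benjamini-Hochberg step-up rule.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import nanmean_quiet
from .events import OBJECT_CATEGORIES, LookEvent
from .eventlocked import log_spaced_bins
from .series import BehaviourSeries

__all__ = [
    "ChunkSummary",
    "chunk_looks",
    "wilcoxon_signed_rank",
    "benjamini_hochberg",
    "chunk_comparison_table",
    "duration_binned_modulation",
]

N_CHUNKS = 3
MIN_LOOK_SAMPLES = 6  # shorter looks cannot form three non-empty half-chunks


@dataclass
class ChunkSummary:
    """Per-participant chunk means (rows: participant; columns chunk1..3)."""

    table: pd.DataFrame
    n_looks: int
    n_skipped: int
    bin_label: str = ""


def _chunk_values(v: np.ndarray) -> np.ndarray | None:
    """Mean of the first half of each of three chunks of one look's samples.

    Chunk boundaries are ``round(i * n / 3)``; the first half of a chunk is
    its first ``ceil(size / 2)`` samples.
    """
    n = v.size
    if n < MIN_LOOK_SAMPLES:
        return None
    edges = [round(i * n / N_CHUNKS) for i in range(N_CHUNKS + 1)]
    out = np.empty(N_CHUNKS)
    for c in range(N_CHUNKS):
        size = edges[c + 1] - edges[c]
        half = v[edges[c]: edges[c] + math.ceil(size / 2)]
        finite = np.isfinite(half)
        out[c] = float(np.mean(half[finite])) if finite.any() else np.nan
    return out


def chunk_looks(
    inputs: Mapping[str, Sequence[tuple[BehaviourSeries, Sequence[LookEvent]]]],
    categories: frozenset | set = OBJECT_CATEGORIES,
    duration_range: tuple[float, float] | None = None,
    bin_label: str = "",
) -> ChunkSummary:
    """Three chunk means per participant (looks -> sections -> participant).

    The variable is expected to be log-transformed and outlier-masked
    upstream. Looks shorter than six samples are skipped and counted.
    """
    rows = {}
    n_looks = n_skipped = 0
    for pid, sections in inputs.items():
        per_section = []
        for variable, events in sections:
            rate = variable.rate
            per_look = []
            for ev in events:
                if ev.category not in categories:
                    continue
                if duration_range is not None and not (
                    duration_range[0] <= ev.duration <= duration_range[1]
                ):
                    continue
                i0 = int(round(ev.onset * rate))
                i1 = int(round(ev.offset * rate))
                chunks = _chunk_values(variable.values[i0:i1])
                if chunks is None:
                    n_skipped += 1
                    continue
                per_look.append(chunks)
                n_looks += 1
            if per_look:
                per_section.append(nanmean_quiet(np.vstack(per_look), axis=0))
        if per_section:
            rows[pid] = nanmean_quiet(np.vstack(per_section), axis=0)
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"chunk{i + 1}" for i in range(N_CHUNKS)]
    )
    return ChunkSummary(table, n_looks, n_skipped, bin_label)


def _exact_wilcoxon_p(w: float, ranks: np.ndarray) -> float:
    """Two-sided p by enumeration of all sign patterns of the given ranks.

    Ranks may be mid-ranks (half-integral under ties); doubling makes them
    integral so the distribution of W+ is built by subset-sum counting.
    """
    r2 = np.round(2 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(2 * w))
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(
    a: np.ndarray, b: np.ndarray, exact_n: int = 12
) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test: returns (W+, two-sided p).

    Zero differences are dropped and ties get mid-ranks. The null
    distribution is enumerated exactly for n <= ``exact_n`` non-zero pairs;
    above that a normal approximation with tie correction and a 0.5
    continuity correction is used.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    keep = np.isfinite(a) & np.isfinite(b)
    d = a[keep] - b[keep]
    d = d[d != 0]
    n = d.size
    if n == 0:
        warnings.warn("all paired differences are zero")
        return 0.0, 1.0
    order = np.abs(d)
    # mid-ranks of |d|
    from scipy.stats import rankdata

    ranks = rankdata(order)
    w = float(ranks[d > 0].sum())
    if n <= exact_n:
        return w, _exact_wilcoxon_p(w, ranks)
    mean = float(ranks.sum()) / 2.0
    var = float(np.sum(ranks**2)) / 4.0  # Var(sum r_i I_i), I_i ~ Bern(1/2)
    # Edgeworth tail with the (negative) kurtosis of the null distribution;
    # the distribution is symmetric so there is no skewness term
    kurt = -float(np.sum(ranks**4)) / 8.0 / var**2
    from scipy.stats import norm

    z = (abs(w - mean) - 0.5) / math.sqrt(var)
    tail = norm.sf(z) + kurt / 24.0 * (z**3 - 3 * z) * norm.pdf(z)
    return w, float(min(1.0, max(0.0, 2.0 * tail)))


def benjamini_hochberg(pvalues: Sequence[float], q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags, in the input order.

    Reject hypotheses 1..k (by ascending p) where ``k`` is the largest index
    with ``p(k) <= k * q / m``.
    """
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    thresholds = (np.arange(1, m + 1) * q) / m
    below = p[order] <= thresholds
    reject = np.zeros(m, dtype=bool)
    if below.any():
        k = int(np.max(np.nonzero(below)[0]))
        reject[order[: k + 1]] = True
    return reject


def chunk_comparison_table(
    summaries: Sequence[ChunkSummary], q: float = 0.05, min_pairs: int = 5
) -> pd.DataFrame:
    """Pairwise Wilcoxon chunk comparisons with BH correction across the family.

    The family is all chunk pairs across all duration bins of one analysis
    run. Comparisons with fewer than ``min_pairs`` complete participants are
    reported with NaN p and never rejected.
    """
    rows = []
    for summary in summaries:
        for i, j in combinations(range(N_CHUNKS), 2):
            a = summary.table.iloc[:, i].to_numpy(dtype=float)
            b = summary.table.iloc[:, j].to_numpy(dtype=float)
            ok = np.isfinite(a) & np.isfinite(b)
            if ok.sum() >= min_pairs:
                stat, p = wilcoxon_signed_rank(a[ok], b[ok])
            else:
                stat, p = np.nan, np.nan
            rows.append(
                {
                    "bin": summary.bin_label or "all",
                    "chunk_pair": f"{i + 1}v{j + 1}",
                    "n": int(ok.sum()),
                    "statistic": stat,
                    "p_raw": p,
                }
            )
    table = pd.DataFrame(rows)
    testable = table["p_raw"].notna()
    reject = np.zeros(len(table), dtype=bool)
    if testable.any():
        reject[testable.to_numpy()] = benjamini_hochberg(
            table.loc[testable, "p_raw"].to_numpy(), q
        )
    table["rejected"] = reject
    return table


def duration_binned_modulation(
    inputs: Mapping[str, Sequence[tuple[BehaviourSeries, Sequence[LookEvent]]]],
    n_bins: int = 5,
    categories: frozenset | set = OBJECT_CATEGORIES,
    q: float = 0.05,
) -> tuple[list[ChunkSummary], pd.DataFrame]:
    """Per-duration-bin chunk summaries plus the corrected comparison table."""
    all_durs = np.array(
        [
            e.duration
            for sections in inputs.values()
            for _, events in sections
            for e in events
            if e.category in categories
        ]
    )
    edges = log_spaced_bins(all_durs, n_bins)
    summaries = []
    for b in range(len(edges) - 1):
        lo, hi = edges[b], edges[b + 1]
        hi_edge = hi if b == len(edges) - 2 else np.nextafter(hi, -np.inf)
        summaries.append(
            chunk_looks(
                inputs, categories,
                duration_range=(lo, hi_edge),
                bin_label=f"{lo:.2f}-{hi:.2f}s",
            )
        )
    return summaries, chunk_comparison_table(summaries, q)
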