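"""Within-look chunking, Wilcoxon signed-rank, and Benjamini-Hochberg."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from dyadtheta.events import LookEvent
from dyadtheta.modulation import (
    _chunk_values,
    benjamini_hochberg,
    chunk_comparison_table,
    chunk_looks,
    duration_binned_modulation,
    wilcoxon_signed_rank,
)
from dyadtheta.series import BehaviourSeries


def look(onset, offset, cat="object1"):
    return LookEvent("infant", onset, offset, cat)


class TestChunkValues:
    def test_two_second_look_index_arithmetic(self):
        # 100 samples: chunks 0-32, 33-66, 67-99; halves 0-16, 33-49, 67-83
        v = np.arange(100, dtype=float)
        chunks = _chunk_values(v)
        assert chunks[0] == pytest.approx(np.mean(v[0:17]))
        assert chunks[1] == pytest.approx(np.mean(v[33:50]))
        assert chunks[2] == pytest.approx(np.mean(v[67:84]))

    def test_constant_variable_equal_chunks(self):
        chunks = _chunk_values(np.full(50, 3.0))
        np.testing.assert_allclose(chunks, 3.0)

    def test_monotone_ramp_orders_chunks(self):
        chunks = _chunk_values(np.linspace(0, 1, 75))
        assert chunks[0] < chunks[1] < chunks[2]

    @pytest.mark.parametrize("n", range(6, 40))
    def test_partition_exact_and_balanced(self, n):
        edges = [round(i * n / 3) for i in range(4)]
        sizes = np.diff(edges)
        assert edges[0] == 0 and edges[-1] == n
        assert sizes.max() - sizes.min() <= 1

    def test_looks_shorter_than_six_samples_skipped(self):
        assert _chunk_values(np.arange(5, dtype=float)) is None


class TestChunkLooks:
    def test_ramp_within_looks_orders_participant_chunks(self):
        n = 500
        values = np.zeros(n)
        events = []
        for i in range(5):
            onset = i * 2.0
            events.append(look(onset, onset + 2.0))
            values[i * 100:(i + 1) * 100] = np.linspace(0, 1, 100)
        inputs = {"p1": [(BehaviourSeries(values, rate=50.0), events)]}
        summary = chunk_looks(inputs)
        row = summary.table.loc["p1"]
        assert row["chunk1"] < row["chunk2"] < row["chunk3"]
        assert summary.n_looks == 5

    def test_short_looks_counted_as_skipped(self):
        values = np.zeros(100)
        events = [look(0.0, 0.05), look(0.05, 2.0)]
        inputs = {"p1": [(BehaviourSeries(values, rate=50.0), events)]}
        summary = chunk_looks(inputs)
        assert summary.n_skipped == 1
        assert summary.n_looks == 1


class TestWilcoxon:
    def test_five_positive_differences_exact(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = a - 1.0
        w, p = wilcoxon_signed_rank(a, b)
        assert w == 15.0
        assert p == pytest.approx(0.0625)

    def test_identical_samples_p_one_with_warning(self):
        a = np.ones(8)
        with pytest.warns(UserWarning, match="zero"):
            w, p = wilcoxon_signed_rank(a, a)
        assert p == 1.0

    def test_exact_branch_matches_full_enumeration(self, rng):
        for _ in range(20):
            d = rng.standard_normal(9)
            d = d[d != 0]
            a, b = d, np.zeros_like(d)
            w, p = wilcoxon_signed_rank(a, b)
            ranks = stats.rankdata(np.abs(d))
            ws = [
                np.sum(ranks[np.array(signs) > 0])
                for signs in itertools.product([-1, 1], repeat=d.size)
            ]
            ws = np.array(ws)
            p_oracle = min(1.0, 2 * min(np.mean(ws <= w), np.mean(ws >= w)))
            assert p == pytest.approx(p_oracle, abs=1e-12)

    def test_exact_matches_scipy_without_ties(self, rng):
        d = rng.standard_normal(11)
        w, p = wilcoxon_signed_rank(d, np.zeros_like(d))
        ref = stats.wilcoxon(d, mode="exact")
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_exact_and_normal_branches_agree_at_boundary(self, rng):
        worst = 0.0
        for _ in range(50):
            d = rng.standard_normal(12)
            _, p_exact = wilcoxon_signed_rank(d, np.zeros_like(d), exact_n=12)
            _, p_approx = wilcoxon_signed_rank(d, np.zeros_like(d), exact_n=0)
            worst = max(worst, abs(p_exact - p_approx))
        assert worst < 0.01

    def test_null_p_values_uniform(self, rng):
        ps = []
        for _ in range(1000):
            a = rng.standard_normal(20)
            b = rng.standard_normal(20)
            ps.append(wilcoxon_signed_rank(a, b)[1])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestBenjaminiHochberg:
    def test_worked_example_all_rejected(self):
        reject = benjamini_hochberg([0.01, 0.02, 0.04], q=0.05)
        assert reject.all()  # 0.04 <= 3 * 0.05 / 3

    def test_large_ps_not_rejected(self):
        assert not benjamini_hochberg([0.5, 0.6]).any()

    def test_empty_input(self):
        assert benjamini_hochberg([]).size == 0

    def test_matches_statsmodels_oracle_on_random_vectors(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 12))
            mine = benjamini_hochberg(p, q=0.05)
            ref = multipletests(p, alpha=0.05, method="fdr_bh")[0]
            np.testing.assert_array_equal(mine, ref)

    def test_rejections_monotone_in_q(self, rng):
        p = rng.uniform(size=20)
        prev = benjamini_hochberg(p, q=0.01)
        for q in (0.05, 0.1, 0.3):
            cur = benjamini_hochberg(p, q=q)
            assert np.all(cur | ~prev)  # rejections only grow
            prev = cur

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError, match="p-values"):
            benjamini_hochberg([0.5, 1.5])


class TestBinnedModulation:
    @staticmethod
    def _study_with_long_look_effect(rng, n_participants=8):
        """Variable ramps within looks longer than 4 s, flat in short looks."""
        inputs = {}
        for p in range(n_participants):
            events, values = [], []
            t = 0.0
            for _ in range(40):
                d = float(rng.choice([1.0, 8.0]))
                n = int(d * 50)
                base = rng.standard_normal() * 0.05
                if d > 4.0:
                    values.append(base + np.linspace(0, 1.0, n))
                else:
                    values.append(np.full(n, base))
                events.append(look(t, t + d))
                t += d
            inputs[f"p{p}"] = [(BehaviourSeries(np.concatenate(values), rate=50.0), events)]
        return inputs

    def test_effect_only_in_long_duration_bins(self, rng):
        inputs = self._study_with_long_look_effect(rng)
        summaries, table = duration_binned_modulation(inputs, n_bins=2)
        short = table[(table["bin"] == summaries[0].bin_label) & (table["chunk_pair"] == "1v3")]
        long_ = table[(table["bin"] == summaries[1].bin_label) & (table["chunk_pair"] == "1v3")]
        assert bool(long_["rejected"].iloc[0])
        assert not bool(short["rejected"].iloc[0])

    def test_single_bin_matches_unbinned(self):
        values = np.tile(np.linspace(0, 1, 100), 10)
        events = [look(i * 2.0, (i + 1) * 2.0) for i in range(10)]
        inputs = {
            f"p{k}": [(BehaviourSeries(values + k * 0.01, rate=50.0), events)]
            for k in range(6)
        }
        summaries, _ = duration_binned_modulation(inputs, n_bins=3)
        occupied = [s for s in summaries if len(s.table)]
        assert len(occupied) == 1
        unbinned = chunk_looks(inputs)
        np.testing.assert_allclose(
            occupied[0].table.to_numpy(), unbinned.table.to_numpy(), atol=1e-12
        )
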