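"""GC matching and Fisher-exact motif enrichment against brute-force oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from atacfoot import synthetic as syn
from atacfoot.enrichment import (
    fisher_motif_enrichment,
    gc_content,
    gc_matched_sample,
    peaks_with_motif,
)
from atacfoot.intervals import GenomicInterval
from atacfoot.stats import bh_adjust, fisher_greater, odds_ratio, trimmed_mean


def hypergeom_tail_exact(a, b, c, d):
    """P(X >= a) by integer-exact summation of hypergeometric terms."""
    N, K, n = a + b + c + d, a + c, a + b
    denom = math.comb(N, n)
    num = sum(
        math.comb(K, x) * math.comb(N - K, n - x)
        for x in range(a, min(K, n) + 1)
    )
    return num / denom


class TestGcContent:
    def test_pure_gc_and_pure_at(self):
        genome = "GGCCAATT"
        peaks = [GenomicInterval("chrS", 0, 4), GenomicInterval("chrS", 4, 8)]
        np.testing.assert_allclose(gc_content(peaks, genome), [1.0, 0.0])

    def test_matches_generator_gc(self):
        genome = syn.make_genome(100_000, 0.6, seed=3)
        peaks = [GenomicInterval("chrS", s, s + 500) for s in range(0, 50_000, 5000)]
        gc = gc_content(peaks, genome)
        assert ((gc > 0.5) & (gc < 0.7)).all()

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            gc_content([GenomicInterval("chrS", 0, 100)], "ACGT")


class TestGcMatchedSample:
    def test_same_distribution_selects_uniformly(self):
        rng = np.random.default_rng(0)
        diff = rng.normal(0.45, 0.05, 1000)
        pool = rng.normal(0.45, 0.05, 10_000)
        idx = gc_matched_sample(diff, pool, n=2000, bins=20, seed=1)
        edges = np.quantile(pool, np.linspace(0, 1, 11))
        pool_prop, _ = np.histogram(pool, edges)
        sel_prop, _ = np.histogram(pool[idx], edges)
        pool_prop = pool_prop / len(pool)
        sel_prop = sel_prop / len(idx)
        # the matched draw tracks the differential sample's empirical bin
        # proportions, so both its own and the differential's binomial
        # noise contribute
        se = np.sqrt(pool_prop * (1 - pool_prop) * (1 / len(idx) + 1 / len(diff)))
        assert (np.abs(sel_prop - pool_prop) <= 3 * se + 1e-9).all()

    def test_degenerate_single_bin_differential(self):
        rng = np.random.default_rng(0)
        pool = rng.uniform(0.2, 0.8, 5000)
        diff = np.full(50, 0.75)
        idx = gc_matched_sample(diff, pool, n=100, bins=20, seed=1)
        # all selected peaks must come from the top GC bin containing 0.75
        edges = np.quantile(np.concatenate([diff, pool]), np.linspace(0, 1, 21))
        target_bin = np.searchsorted(edges, 0.75, side="right") - 1
        sel_bins = np.clip(np.searchsorted(edges, pool[idx], side="right") - 1, 0, 19)
        assert (sel_bins == target_bin).all()

    def test_seed_reproducible_and_no_repeats(self):
        rng = np.random.default_rng(0)
        diff = rng.normal(0.5, 0.05, 300)
        pool = rng.normal(0.45, 0.06, 5000)
        a = gc_matched_sample(diff, pool, n=1000, seed=42)
        b = gc_matched_sample(diff, pool, n=1000, seed=42)
        np.testing.assert_array_equal(a, b)
        assert len(np.unique(a)) == len(a)

    def test_small_pool_returns_everything(self):
        idx = gc_matched_sample(np.array([0.5]), np.array([0.4, 0.5]), n=10)
        np.testing.assert_array_equal(idx, [0, 1])

    def test_matching_beats_naive_on_planted_confound(self):
        """Chi-square distance of matched background beats naive in >=95/100 seeds."""
        wins = 0
        root = np.random.default_rng(7)
        for _ in range(100):
            s = int(root.integers(2**31))
            diff_gc, pool_gc, _, _ = syn.simulate_gc_presence_confound(400, 8000, s)
            both = np.concatenate([diff_gc, pool_gc])
            edges = np.quantile(both, np.linspace(0, 1, 21))

            def props(values):
                h = np.histogram(values, edges)[0].astype(float)
                return h / h.sum()

            p_diff = props(diff_gc)
            matched = gc_matched_sample(diff_gc, pool_gc, n=2000, seed=s + 1)
            naive = np.random.default_rng(s + 2).choice(8000, 2000, replace=False)

            def chi2_dist(q):
                ok = p_diff > 0
                return float(np.sum((q[ok] - p_diff[ok]) ** 2 / p_diff[ok]))

            if chi2_dist(props(pool_gc[matched])) < chi2_dist(props(pool_gc[naive])):
                wins += 1
        assert wins >= 95


class TestFisher:
    def test_textbook_table(self):
        assert odds_ratio(30, 20, 10, 40) == pytest.approx(6.0)
        assert fisher_greater(30, 20, 10, 40) == pytest.approx(
            hypergeom_tail_exact(30, 20, 10, 40), rel=1e-10
        )

    @settings(deadline=None, max_examples=80, derandomize=True)
    @given(st.integers(0, 12), st.integers(0, 12), st.integers(0, 12), st.integers(0, 12))
    def test_matches_exact_summation(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        assert fisher_greater(a, b, c, d) == pytest.approx(
            hypergeom_tail_exact(a, b, c, d), rel=1e-9, abs=1e-12
        )

    def test_motif_everywhere_gives_p_one(self):
        peaks_d = [GenomicInterval("chrS", i * 100, i * 100 + 50) for i in range(5)]
        peaks_b = [GenomicInterval("chrS", i * 100 + 5000, i * 100 + 5050) for i in range(5)]
        inst = pd.DataFrame(
            {
                "motif": "m",
                "chrom": "chrS",
                "start": [p.start for p in peaks_d + peaks_b],
                "end": [p.start + 6 for p in peaks_d + peaks_b],
                "strand": "+",
            }
        )
        res = fisher_motif_enrichment(peaks_d, peaks_b, inst)
        assert res.loc[0, "p"] == pytest.approx(1.0)
        assert not np.isfinite(res.loc[0, "odds_ratio"]) or res.loc[0, "odds_ratio"] == 0

    def test_presence_is_any_overlap(self):
        peaks = [GenomicInterval("chrS", 100, 200)]
        inst = pd.DataFrame(
            {"motif": ["m"], "chrom": ["chrS"], "start": [195], "end": [205], "strand": ["+"]}
        )
        assert peaks_with_motif(peaks, inst).tolist() == [True]
        inst2 = inst.assign(start=200, end=210)
        assert peaks_with_motif(peaks, inst2).tolist() == [False]

    def test_empty_differential_untestable(self):
        peaks_b = [GenomicInterval("chrS", 0, 100)]
        inst = pd.DataFrame(
            {"motif": ["m"], "chrom": ["chrS"], "start": [10], "end": [16], "strand": ["+"]}
        )
        res = fisher_motif_enrichment([], peaks_b, inst)
        assert np.isnan(res.loc[0, "p"])


class TestSharedStats:
    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=200))
    def test_bh_matches_brute_force(self, pvals):
        p = np.array(pvals)
        got = bh_adjust(p)
        n = len(p)
        expected = np.empty(n)
        for i in range(n):
            rank_p = p[i]
            # step-up: min over thresholds t >= p_i of t * n / rank(t)
            candidates = [
                pj * n / (np.sum(p <= pj)) for pj in p if pj >= rank_p
            ]
            expected[i] = min(1.0, min(candidates))
        np.testing.assert_allclose(got, expected, rtol=1e-12, atol=1e-12)

    def test_trimmed_mean_drops_ten_percent_tails(self):
        values = np.arange(1, 11)
        assert trimmed_mean(values, 0.10) == pytest.approx(np.mean(np.arange(2, 10)))
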