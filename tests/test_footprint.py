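"""Hexamer models, expected profiles, footprint scores, FA/FPD regions."""

import numpy as np
import pandas as pd
import pytest

from atacfoot import seq
from atacfoot import synthetic as syn
from atacfoot.footprint import (
    FootprintProfile,
    FootprintRegions,
    GenomeTracks,
    compute_fa_fpd,
    cut_hexamer_factors,
    differential_footprint,
    expected_cut_profile,
    footprint_score,
    genome_hexamer_freq,
    observed_cut_profile,
    positional_hexamer_freq,
)
from atacfoot.intervals import GenomicInterval


def instances_frame(rows):
    return pd.DataFrame(rows, columns=["motif", "chrom", "start", "end", "strand"])


class TestGenomeHexamerFreq:
    def test_homopolymer(self):
        freq = genome_hexamer_freq("A" * 8)
        assert freq[seq.kmer_to_index("AAAAAA")] == 1.0
        assert freq.sum() == 1.0

    def test_blacklist_matches_hand_enumeration(self):
        genome = "ACGTACGTACGTAAATTTCCCGGGACGTAC"  # 30 bases
        blacklist = [GenomicInterval("chrS", 10, 16)]
        freq = genome_hexamer_freq(genome, blacklist)
        expected = np.zeros(4096)
        for i in range(len(genome) - 5):
            window = range(i, i + 6)
            if any(10 <= p < 16 for p in window):
                continue
            expected[seq.kmer_to_index(genome[i : i + 6])] += 1
        expected /= expected.sum()
        np.testing.assert_allclose(freq, expected)

    def test_uniform_genome_concentration(self):
        genome = syn.make_genome(2_000_000, 0.5, seed=1)
        freq = genome_hexamer_freq(genome)
        assert freq.max() < 2 / 4096

    def test_fully_blacklisted_rejected(self):
        with pytest.raises(ValueError):
            genome_hexamer_freq("ACGTACGTAC", [GenomicInterval("chrS", 0, 10)])


class TestPositionalHexamerFreq:
    def test_single_plus_instance_matches_direct_tabulation(self):
        genome = syn.make_genome(1200, 0.5, seed=2)
        inst = instances_frame([("m", "chrS", 597, 603, "+")])  # center 600
        tracks = GenomeTracks.from_genome(genome)
        mat = positional_hexamer_freq(inst, tracks, flank=100)
        codes = seq.encode(genome)
        for d in (-100, -7, 0, 42, 100):
            g = 600 + d
            h = seq.kmer_to_index(seq.decode(codes[g - 3 : g + 3]))
            row = np.zeros(4096)
            row[h] = 4096.0  # one count, normalised to row mean 1
            np.testing.assert_allclose(mat[d + 100], row)

    def test_rows_have_mean_one(self):
        genome = syn.make_genome(50_000, 0.5, seed=3)
        starts = np.arange(500, 40_000, 800)
        inst = instances_frame(
            [("m", "chrS", int(s), int(s) + 6, "+") for s in starts]
        )
        tracks = GenomeTracks.from_genome(genome)
        mat = positional_hexamer_freq(inst, tracks)
        np.testing.assert_allclose(mat.mean(axis=1), 1.0, atol=1e-6)

    def test_opposite_strand_mirror_context_identical_profile(self):
        """A '-' instance in the duplex-mirrored context reproduces the '+' profile."""
        rng = np.random.default_rng(4)
        block = rng.integers(0, 4, size=601).astype(np.uint8)
        spacer = rng.integers(0, 4, size=400).astype(np.uint8)
        rc_block = block[::-1].copy()
        rc_block = (3 - rc_block).astype(np.uint8)
        codes = np.concatenate([spacer, block, spacer, rc_block, spacer])
        genome = seq.decode(codes)
        c1 = 400 + 300  # center of block
        # base c1 + k in block maps to comp at mirrored index; center base of
        # the reverse-complemented copy sits at the mirror of c1 about the
        # insertion bond, i.e. offset len(block)-1-300 shifted by +1
        c2 = 400 + 601 + 400 + (601 - 1 - 300) + 1
        tracks = GenomeTracks.from_genome(genome)
        mat1 = positional_hexamer_freq(
            instances_frame([("m", "chrS", c1 - 3, c1 + 3, "+")]), tracks, flank=100
        )
        mat2 = positional_hexamer_freq(
            instances_frame([("m", "chrS", c2 - 3, c2 + 3, "-")]), tracks, flank=100
        )
        np.testing.assert_allclose(mat1, mat2)

    def test_no_usable_instance_rejected(self):
        genome = syn.make_genome(1000, 0.5, seed=3)
        inst = instances_frame([("m", "chrS", 5, 11, "+")])  # no 250bp flank
        tracks = GenomeTracks.from_genome(genome)
        with pytest.raises(ValueError):
            positional_hexamer_freq(inst, tracks)


class TestCutHexamerFactors:
    def test_unbiased_cuts_give_flat_factors(self):
        genome = syn.make_genome(500_000, 0.5, seed=5)
        bias = np.ones(4096)
        truth = syn.SyntheticTruth(bias_table=bias)
        cuts = syn.simulate_cut_sites(genome, bias, truth, 1_000_000, seed=6)
        tracks = GenomeTracks.from_genome(genome)
        gfreq = genome_hexamer_freq(genome)
        factors = cut_hexamer_factors(cuts, tracks, gfreq)
        scaled = factors * 4096
        assert abs(scaled.mean() - 1) < 0.01
        assert np.abs(scaled - 1).mean() < 0.1
        assert np.abs(scaled - 1).max() < 0.6

    def test_hot_hexamer_closed_form(self):
        """One palindromic hexamer weighted 10x -> factor 10/(4095+10)."""
        hot = seq.kmer_to_index("ACGCGT")
        assert seq.revcomp_kmer_table()[hot] == hot
        genome = syn.make_genome(500_000, 0.5, seed=7)
        bias = np.ones(4096)
        bias[hot] = 10.0
        bias /= bias.mean()
        truth = syn.SyntheticTruth(bias_table=bias)
        cuts = syn.simulate_cut_sites(genome, bias, truth, 1_000_000, seed=8)
        tracks = GenomeTracks.from_genome(genome)
        factors = cut_hexamer_factors(cuts, tracks, genome_hexamer_freq(genome))
        assert factors[hot] == pytest.approx(10 / 4105, rel=0.1)

    def test_identical_tracks_identical_factors(self):
        genome = syn.make_genome(50_000, 0.5, seed=9)
        bias = syn.random_bias_table(1)
        truth = syn.SyntheticTruth(bias_table=bias)
        cuts = syn.simulate_cut_sites(genome, bias, truth, 100_000, seed=10)
        tracks = GenomeTracks.from_genome(genome)
        gfreq = genome_hexamer_freq(genome)
        f1 = cut_hexamer_factors(cuts, tracks, gfreq)
        f2 = cut_hexamer_factors(cuts, tracks, gfreq)
        np.testing.assert_array_equal(f1, f2)
        assert abs(f1.sum() - 1) < 1e-9


class TestExpectedProfile:
    def test_uniform_factors_give_flat_profile(self):
        genome = syn.make_genome(20_000, 0.5, seed=11)
        starts = np.arange(500, 19_000, 700)
        inst = instances_frame([("m", "chrS", int(s), int(s) + 6, "+") for s in starts])
        tracks = GenomeTracks.from_genome(genome)
        mat = positional_hexamer_freq(inst, tracks)
        e = expected_cut_profile(mat, np.full(4096, 1 / 4096))
        np.testing.assert_allclose(e, 1 / 501, atol=1e-12)

    def test_small_case_matches_hand_dot_product(self):
        positional = np.zeros((3, 4096))
        positional[0, 5] = 4096
        positional[1, [5, 9]] = 2048
        positional[2, 9] = 4096
        factors = np.zeros(4096)
        factors[5], factors[9] = 0.75, 0.25
        e = expected_cut_profile(positional, factors)
        raw = np.array([4096 * 0.75, 2048 * 0.75 + 2048 * 0.25, 4096 * 0.25])
        np.testing.assert_allclose(e, raw / raw.sum())
        assert e.sum() == pytest.approx(1.0)


class TestFootprintScore:
    def test_observed_proportional_to_expected_scores_zero(self):
        expected = np.linspace(1, 3, 501)
        expected /= expected.sum()
        observed = expected * 12345
        prof = footprint_score(observed, expected, width=6)
        np.testing.assert_allclose(prof.score, 0.0, atol=1e-12)
        fa, fpd = compute_fa_fpd(prof)
        assert fa == pytest.approx(0.0, abs=1e-12)
        assert fpd == pytest.approx(0.0, abs=1e-12)

    def test_depth_scaling_invariance(self):
        rng = np.random.default_rng(12)
        expected = rng.uniform(0.5, 2, 501)
        expected /= expected.sum()
        observed = rng.poisson(1000, 501).astype(float)
        s1 = footprint_score(observed, expected, width=6).score
        s2 = footprint_score(observed * 2, expected, width=6).score
        np.testing.assert_allclose(s1, s2, atol=1e-12)

    def test_zero_observed_flags_empty(self):
        prof = footprint_score(np.zeros(501), np.full(501, 1 / 501), width=6)
        assert prof.empty


class TestRegions:
    def test_width_six_region_bounds(self):
        r = FootprintRegions(6)
        pos = r.positions()
        assert set(pos[r.base_mask()]) == set(range(-8, 9))
        flank = pos[r.flank_mask()]
        assert flank.min() == -50 and flank.max() == 50
        assert np.abs(flank).min() == 13
        bg = pos[r.background_mask()]
        assert len(bg) == 102
        assert np.abs(bg).min() == 200 and np.abs(bg).max() == 250

    def test_wide_motif_flank_edge_literal_min(self):
        r = FootprintRegions(30)
        assert r.flank_inner == 18.0  # min(18, 25) -- base region overlaps flank
        r2 = FootprintRegions(30, widest_inner=True)
        assert r2.flank_inner == 25.0

    def test_step_function_profile_fa_fpd(self):
        """base -1, flank +0.5, background 0 for W=12 -> fa 0.5, fpd -1.5."""
        r = FootprintRegions(12)
        score = np.full(501, 0.25)
        score[r.base_mask()] = -1.0
        score[r.flank_mask()] = 0.5
        score[r.background_mask()] = 0.0
        prof = FootprintProfile(
            "m", "s", r.positions(), np.ones(501), np.ones(501), score, width=12
        )
        fa, fpd = compute_fa_fpd(prof)
        assert fa == pytest.approx(0.5)
        assert fpd == pytest.approx(-1.5)

    def test_masked_positions_excluded_from_region_means(self):
        r = FootprintRegions(6)
        score = np.zeros(501)
        score[r.background_mask()] = np.nan
        score[r.flank_mask()] = 0.3
        prof = FootprintProfile("m", "s", r.positions(), None, None, score, width=6)
        fa, fpd = compute_fa_fpd(prof)
        assert np.isnan(fa)  # background fully masked
        assert fpd == pytest.approx(0.0 - 0.3)


class TestDifferentialFootprint:
    def make_summary(self, deltas):
        return pd.DataFrame(
            {
                "motif": list(deltas),
                "fa": [v[0] for v in deltas.values()],
                "fpd": [v[1] for v in deltas.values()],
            }
        )

    def test_identical_conditions_zero_deltas(self):
        s = self.make_summary({"a": (0.1, -0.5), "b": (0.2, -0.1)})
        diff = differential_footprint(s, s.copy())
        assert (diff["delta_fa"] == 0).all() and (diff["delta_fpd"] == 0).all()

    def test_swapping_conditions_negates_deltas(self):
        a = self.make_summary({"a": (0.1, -0.5), "b": (0.2, -0.1)})
        b = self.make_summary({"a": (0.3, -0.2), "b": (0.1, 0.4)})
        d1 = differential_footprint(a, b).set_index("motif").sort_index()
        d2 = differential_footprint(b, a).set_index("motif").sort_index()
        np.testing.assert_allclose(d1["delta_fpd"], -d2["delta_fpd"])
        np.testing.assert_allclose(d1["delta_fa"], -d2["delta_fa"])

    def test_missing_motif_dropped(self):
        a = self.make_summary({"a": (0.1, -0.5), "b": (0.2, -0.1)})
        b = self.make_summary({"a": (0.3, -0.2)})
        diff = differential_footprint(a, b)
        assert diff["motif"].tolist() == ["a"]


def test_observed_profile_orients_by_instance_strand():
    genome = syn.make_genome(3000, 0.5, seed=13)
    tracks = GenomeTracks.from_genome(genome)
    pos = np.array([900, 1100])  # asymmetric cuts around center 1000
    cuts = syn.CutTrack({"chrS": (pos, np.zeros(2, dtype=np.uint8))})
    plus = observed_cut_profile(
        cuts, instances_frame([("m", "chrS", 997, 1003, "+")]), tracks, flank=250
    )
    minus = observed_cut_profile(cuts, instances_frame([("m", "chrS", 997, 1003, "-")]), tracks, flank=250)
    assert plus[250 - 100] == 1 and plus[250 + 100] == 1
    np.testing.assert_array_equal(plus, minus[::-1])
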