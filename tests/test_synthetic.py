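"""Generator contracts: genomes, planted motifs, biased cuts, count matrices."""

import numpy as np
import pytest
from scipy.stats import chisquare

from atacfoot import seq
from atacfoot import synthetic as syn
from atacfoot.motifs import consensus_pwm


class TestMakeGenome:
    def test_length_and_alphabet(self):
        g = syn.make_genome(4000, 0.5, seed=1)
        assert len(g) == 4000
        assert set(g) <= set("ACGT")

    def test_gc_content_controlled(self):
        g = syn.make_genome(100_000, 0.6, seed=7)
        gc = (g.count("G") + g.count("C")) / len(g)
        assert 0.59 <= gc <= 0.61

    def test_deterministic_under_seed(self):
        assert syn.make_genome(2000, 0.4, seed=3) == syn.make_genome(2000, 0.4, seed=3)
        assert syn.make_genome(2000, 0.4, seed=3) != syn.make_genome(2000, 0.4, seed=4)

    def test_rejects_bad_args(self):
        with pytest.raises(ValueError):
            syn.make_genome(10, 0.5, 0)
        with pytest.raises(ValueError):
            syn.make_genome(5000, 1.0, 0)


class TestBiasTable:
    def test_invariants(self):
        bt = syn.random_bias_table(5)
        assert bt.shape == (4096,)
        assert (bt > 0).all()
        assert abs(bt.mean() - 1.0) < 1e-9

    def test_revcomp_symmetric(self):
        bt = syn.random_bias_table(5)
        rc = seq.revcomp_kmer_table()
        np.testing.assert_allclose(bt, bt[rc])


class TestPlantMotifInstances:
    def test_consensus_written_at_recorded_coordinate(self):
        pwm = consensus_pwm("half", "TGCCAA")
        g = syn.make_genome(5000, 0.5, seed=2)
        g2, entries = syn.plant_motif_instances(g, pwm, 1, seed=3)
        (motif, interval, strand, protected) = entries[0]
        word = g2[interval.start : interval.end]
        assert word == ("TGCCAA" if strand == "+" else "TTGGCA")

    def test_zero_placements_leave_genome_unchanged(self):
        pwm = consensus_pwm("half", "TGCCAA")
        g = syn.make_genome(2000, 0.5, seed=2)
        g2, entries = syn.plant_motif_instances(g, pwm, 0, seed=3)
        assert g2 == g and entries == []

    def test_exact_protected_count(self):
        pwm = consensus_pwm("half", "TGCCAA")
        g = syn.make_genome(200_000, 0.5, seed=2)
        _, entries = syn.plant_motif_instances(g, pwm, 50, 0.5, seed=3)
        assert sum(e[3] for e in entries) == 25

    def test_placements_never_overlap(self):
        pwm = consensus_pwm("wide", "ACGTACGTAC")
        g = syn.make_genome(20_000, 0.5, seed=2)
        _, entries = syn.plant_motif_instances(g, pwm, 200, seed=3)
        spans = sorted((e[1].start, e[1].end) for e in entries)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2

    def test_impossible_packing_raises(self):
        pwm = consensus_pwm("wide", "ACGTACGTAC")
        g = syn.make_genome(1200, 0.5, seed=2)
        with pytest.raises(RuntimeError):
            syn.plant_motif_instances(g, pwm, 500, seed=3, min_flank=100)


class TestSimulateCutSites:
    def test_uniform_bias_gives_uniform_positions(self):
        g = syn.make_genome(10_000, 0.5, seed=4)
        bias = np.ones(4096)
        truth = syn.SyntheticTruth(bias_table=bias)
        cuts = syn.simulate_cut_sites(g, bias, truth, depth=1_000_000, seed=5)
        pos, _ = cuts.chroms["chrS"]
        counts = np.bincount(pos, minlength=10_000)[5 : 10_000 - 5]
        stat = chisquare(counts)
        assert stat.pvalue > 0.01

    def test_full_protection_blocks_all_cuts_inside(self):
        pwm = consensus_pwm("half", "TGCCAA")
        g = syn.make_genome(20_000, 0.5, seed=6)
        g, entries = syn.plant_motif_instances(g, pwm, 10, protected_fraction=1.0, seed=7)
        bias = np.ones(4096)
        truth = syn.SyntheticTruth(
            planted_motif_instances=entries, bias_table=bias, protection_factor=0.0
        )
        cuts = syn.simulate_cut_sites(g, bias, truth, depth=200_000, seed=8)
        pos, _ = cuts.chroms["chrS"]
        for _, ivl, _, _ in entries:
            assert not ((pos >= ivl.start) & (pos < ivl.end)).any()

    def test_single_hot_hexamer_cut_share(self):
        """A hexamer weighted 10x should collect ~10x its genomic share of cuts."""
        g = syn.make_genome(100_000, 0.5, seed=9)
        codes = seq.encode(g)
        idx, valid = seq.kmer_index_table(codes)
        hot = seq.kmer_to_index("ACGTAC")
        bias = np.ones(4096)
        bias[hot] = 10.0
        bias /= bias.mean()
        truth = syn.SyntheticTruth(bias_table=bias)
        cuts = syn.simulate_cut_sites(g, bias, truth, depth=1_000_000, seed=10)
        pos, _ = cuts.chroms["chrS"]
        # genomic share of positions whose anchored hexamer is the hot one
        anchored = np.full(len(codes), -1)
        anchored[3 : 3 + len(idx)] = np.where(valid, idx, -1)
        support = anchored[5 : len(codes) - 5]
        genome_share = (support == hot).mean()
        cut_share = (anchored[pos] == hot).mean()
        ratio = cut_share / genome_share
        expected = 10.0 / (1 + 9 * genome_share)  # weights renormalise
        assert abs(ratio - expected) / expected < 0.1

    def test_edge_positions_excluded(self):
        g = syn.make_genome(1000, 0.5, seed=4)
        bias = np.ones(4096)
        truth = syn.SyntheticTruth(bias_table=bias)
        cuts = syn.simulate_cut_sites(g, bias, truth, depth=50_000, seed=5)
        pos, _ = cuts.chroms["chrS"]
        assert pos.min() >= 5 and pos.max() < 995

    def test_bit_reproducible(self):
        g = syn.make_genome(5000, 0.5, seed=4)
        bias = syn.random_bias_table(1)
        truth = syn.SyntheticTruth(bias_table=bias)
        a = syn.simulate_cut_sites(g, bias, truth, 10_000, seed=5)
        b = syn.simulate_cut_sites(g, bias, truth, 10_000, seed=5)
        np.testing.assert_array_equal(a.chroms["chrS"][0], b.chroms["chrS"][0])
        np.testing.assert_array_equal(a.chroms["chrS"][1], b.chroms["chrS"][1])


class TestSimulateCountMatrix:
    def test_poisson_limit_at_small_dispersion(self):
        design = syn.make_design(("BM", "CB"), (1,), replicates=10)
        matrix, _ = syn.simulate_count_matrix(
            500, design, None, dispersion=1e-6, seed=1,
            baseline_range=(500.0, 500.0), size_factor_sd=0.0,
        )
        cv = matrix.counts.std(axis=1) / matrix.counts.mean(axis=1)
        np.testing.assert_allclose(cv.mean(), 1 / np.sqrt(500), rtol=0.1)

    def test_confounded_design_rejected(self):
        import pandas as pd

        design = pd.DataFrame(
            {
                "sample": ["a", "b", "c", "d"],
                "source": ["BM", "BM", "CB", "CB"],
                "population": [1, 1, 2, 2],
            }
        )
        with pytest.raises(ValueError, match="population"):
            syn.simulate_count_matrix(10, design, None, seed=0)

    def test_truth_records_planted_effects(self):
        design = syn.make_design(("BM", "CB"), (1,), replicates=2)
        matrix, truth = syn.simulate_count_matrix(
            100, design, {3: 2.0, 7: -1.0}, seed=0
        )
        assert {(i, lfc) for i, lfc, _ in truth.planted_differential} == {
            (3, 2.0),
            (7, -1.0),
        }
        assert matrix.counts.shape == (100, 4)

    def test_gc_confound_shifts_planted_peaks(self):
        design = syn.make_design(("BM", "CB"), (1,), replicates=2)
        effects = {i: 1.0 for i in range(200)}
        matrix, _ = syn.simulate_count_matrix(
            2000, design, effects, gc_confound=True, seed=0
        )
        assert matrix.gc[:200].mean() > matrix.gc[200:].mean() + 0.03
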