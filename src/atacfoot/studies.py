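"""Reference synthetic experiments exercising the full pipeline.

Each function builds a self-contained in-silico study with planted ground
truth and runs the relevant pipeline stages on it, returning the summary
quantities a reader would check:

* :func:`bias_null_study` — cuts carry hexamer bias but no protein
  protection; a correct bias correction must flatten every footprint
  profile (mean |score| near zero).
* :func:`planted_footprint_study` — NFI motif instances are protected in
  condition A only; the NFI motifs must surface in the extreme tail of the
  per-motif footprint-depth difference among decoys.
* :func:`gc_confound_experiment` — a GC-shifted differential set with a
  GC-tracking motif and no true association; GC-matched background
  sampling must remove the spurious Fisher signal that a naive background
  shows.
* :func:`nb_null_calibration` / :func:`nb_recovery` — type-I error and
  effect recovery of the NB Wald test on simulated count matrices.

Problem sizes follow the generator defaults: megabase-scale genomes,
around 10^6 cuts per track, thousands of peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import footprint as fp
from . import synthetic as syn
from .differential import PopulationWindow, fit_nb_wald
from .enrichment import gc_matched_sample
from .motifs import PWM, consensus_pwm, effective_cutoff, nfi_fixture_pwms, scan_pwm
from .stats import fisher_greater

NFI_IDS = ("NFI_full", "NFI_half_TGCCAA", "NFI_half_GCCAA")


def decoy_pwms(n: int = 20, width: int = 8, seed: int = 987) -> list[PWM]:
    """Fixed panel of random-consensus decoy motifs (seed independent of data)."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        consensus = "".join("ACGT"[b] for b in rng.integers(0, 4, size=width))
        out.append(consensus_pwm(f"decoy{i + 1:02d}_{consensus}", consensus))
    return out


def _truth_to_instances(entries) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "motif": motif,
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "strand": strand,
                "protected": protected,
            }
            for motif, iv, strand, protected in entries
        ]
    )


def _scan_all(genome: str, pwms: list[PWM], scan_p: float = 1e-4) -> pd.DataFrame:
    frames = [
        scan_pwm(genome, pwm, p_cutoff=effective_cutoff(pwm, scan_p)) for pwm in pwms
    ]
    return pd.concat(frames, ignore_index=True)


@dataclass
class FootprintStudyResult:
    genome: str
    pwms: list[PWM]
    instances: pd.DataFrame
    truth: syn.SyntheticTruth
    summaries: dict[str, pd.DataFrame] = field(default_factory=dict)
    profiles: dict[str, dict] = field(default_factory=dict)
    cuts: dict[str, syn.CutTrack] = field(default_factory=dict)


def bias_null_study(
    seed: int,
    genome_length: int = 2_000_000,
    depth: int = 1_000_000,
    n_planted: int = 3000,
    n_decoys: int = 2,
    bias_sd: float = 0.5,
) -> tuple[dict[str, float], FootprintStudyResult]:
    """Hexamer-biased cuts, no protection: footprint scores must be flat.

    Returns (mean |score| per motif, full study result).
    """
    rng = np.random.default_rng(seed)
    genome = syn.make_genome(genome_length, 0.5, int(rng.integers(2**31)))
    pwms = list(nfi_fixture_pwms()) + decoy_pwms(n_decoys)
    occupied = np.zeros(genome_length, dtype=bool)
    entries = []
    for pwm in pwms:
        genome, ent = syn.plant_motif_instances(
            genome, pwm, n_planted, 0.0, int(rng.integers(2**31)), occupied=occupied
        )
        entries.extend(ent)
    bias = syn.random_bias_table(int(rng.integers(2**31)), sd=bias_sd)
    truth = syn.SyntheticTruth(
        planted_motif_instances=entries, bias_table=bias, protection_factor=1.0
    )
    cuts = syn.simulate_cut_sites(genome, bias, truth, depth, int(rng.integers(2**31)))
    instances = _scan_all(genome, pwms)
    summary, profiles = fp.footprint_summary(
        cuts, instances, genome, sample="null",
        motif_widths={p.id: p.width for p in pwms},
    )
    mean_abs = {
        motif: float(np.nanmean(np.abs(prof.score))) for motif, prof in profiles.items()
    }
    result = FootprintStudyResult(
        genome, pwms, instances, truth,
        summaries={"null": summary}, profiles={"null": profiles},
        cuts={"null": cuts},
    )
    return mean_abs, result


def planted_footprint_study(
    seed: int,
    genome_length: int = 400_000,
    depth: int = 4_000_000,
    protection_factor: float = 0.2,
    n_decoys: int = 20,
    n_nfi: dict[str, int] | None = None,
    n_decoy_instances: int = 300,
    bias_sd: float = 0.5,
) -> tuple[pd.DataFrame, FootprintStudyResult]:
    """Protect NFI instances in condition A only; rank motifs by delta FPD.

    Returns (differential footprint table sorted by delta_fpd ascending,
    full study result).  The NFI motifs should occupy the most negative
    delta_fpd ranks: their footprints deepen only in A.
    """
    if n_nfi is None:
        n_nfi = {"NFI_full": 200, "NFI_half_TGCCAA": 300, "NFI_half_GCCAA": 400}
    rng = np.random.default_rng(seed)
    genome = syn.make_genome(genome_length, 0.5, int(rng.integers(2**31)))
    nfi = list(nfi_fixture_pwms())
    decoys = decoy_pwms(n_decoys)
    occupied = np.zeros(genome_length, dtype=bool)
    entries = []
    for pwm in nfi:
        genome, ent = syn.plant_motif_instances(
            genome, pwm, n_nfi[pwm.id], 1.0, int(rng.integers(2**31)), occupied=occupied
        )
        entries.extend(ent)
    for pwm in decoys:
        genome, ent = syn.plant_motif_instances(
            genome, pwm, n_decoy_instances, 0.0, int(rng.integers(2**31)),
            occupied=occupied,
        )
        entries.extend(ent)
    bias = syn.random_bias_table(int(rng.integers(2**31)), sd=bias_sd)
    truth_a = syn.SyntheticTruth(
        planted_motif_instances=entries, bias_table=bias,
        protection_factor=protection_factor,
    )
    entries_free = [(m, iv, s, False) for m, iv, s, _ in entries]
    truth_b = syn.SyntheticTruth(
        planted_motif_instances=entries_free, bias_table=bias, protection_factor=1.0
    )
    cuts_a = syn.simulate_cut_sites(genome, bias, truth_a, depth, int(rng.integers(2**31)))
    cuts_b = syn.simulate_cut_sites(genome, bias, truth_b, depth, int(rng.integers(2**31)))

    pwms = nfi + decoys
    instances = _scan_all(genome, pwms)
    widths = {p.id: p.width for p in pwms}
    tracks = fp.GenomeTracks.from_genome(genome)
    genome_freq = fp.genome_hexamer_freq(genome)
    positional = {
        motif: fp.positional_hexamer_freq(sub, tracks)
        for motif, sub in instances.groupby("motif", sort=True)
    }
    summaries, profiles = {}, {}
    for label, cuts in (("A", cuts_a), ("B", cuts_b)):
        summaries[label], profiles[label] = fp.footprint_summary(
            cuts, instances, genome, sample=label, motif_widths=widths,
            tracks=tracks, genome_freq=genome_freq, positional=positional,
        )
    diff = fp.differential_footprint(summaries["A"], summaries["B"])
    result = FootprintStudyResult(
        genome, pwms, instances, truth_a,
        summaries=summaries, profiles=profiles,
        cuts={"A": cuts_a, "B": cuts_b},
    )
    return diff, result


def nfi_delta_fpd_ranks(diff: pd.DataFrame) -> dict[str, int]:
    """Ascending delta_fpd rank (1 = deepest gain in A) for each NFI motif."""
    ranks = diff.set_index("motif")["rank_delta_fpd"]
    return {m: int(ranks[m]) for m in NFI_IDS if m in ranks.index}


def gc_confound_experiment(
    seed: int,
    n_repeats: int = 100,
    n_differential: int = 800,
    n_pool: int = 20000,
    n_background: int = 2500,
    bins: int = 20,
) -> dict[str, float]:
    """False-positive rates of naive vs GC-matched motif enrichment.

    Each repeat simulates a GC-confounded null (motif presence tracks GC;
    differential peaks are GC-shifted; no true association), then tests
    enrichment once against a uniformly sampled background and once
    against a GC-matched background.  Returns the fraction of repeats with
    Fisher p < 0.05 under each scheme.
    """
    root = np.random.default_rng(seed)
    hits_naive = 0
    hits_matched = 0
    for _ in range(n_repeats):
        s = int(root.integers(2**31))
        diff_gc, pool_gc, diff_present, pool_present = syn.simulate_gc_presence_confound(
            n_differential, n_pool, s
        )
        local = np.random.default_rng(s + 1)
        naive_idx = local.choice(n_pool, size=n_background, replace=False)
        matched_idx = gc_matched_sample(
            diff_gc, pool_gc, n=n_background, bins=bins, seed=s + 2
        )

        def fisher_p(bg_idx: np.ndarray) -> float:
            a = int(diff_present.sum())
            b = len(diff_present) - a
            c = int(pool_present[bg_idx].sum())
            d = len(bg_idx) - c
            return fisher_greater(a, b, c, d)

        hits_naive += fisher_p(naive_idx) < 0.05
        hits_matched += fisher_p(matched_idx) < 0.05
    return {
        "naive_fp_rate": hits_naive / n_repeats,
        "matched_fp_rate": hits_matched / n_repeats,
    }


@dataclass
class SourceComparisonStudy:
    """A full synthetic two-source (BM vs CB) ATAC study written by `simulate`."""

    genome: str
    design: pd.DataFrame
    cuts: dict[str, syn.CutTrack]  # per sample
    pwms: list[PWM]
    truth_instances: pd.DataFrame
    region_truth: pd.DataFrame  # accessible regions with planted source lfc
    bias_table: np.ndarray


def simulate_source_comparison(
    seed: int,
    genome_length: int = 150_000,
    depth_per_sample: int = 300_000,
    n_regions: int = 60,
    n_diff_regions: int = 8,
    region_halfwidth: int = 250,
    region_lfc: float = 1.5,
    instances_per_region: int = 3,
    open_log2: float = 6.0,
    protection_factor: float = 0.2,
    populations: tuple[int, ...] = (3, 4, 5),
    replicates: int = 1,
    n_decoys: int = 10,
    bias_sd: float = 0.5,
) -> SourceComparisonStudy:
    """Two-source erythroid-style study with planted regional accessibility.

    Evenly spaced open regions (2**``open_log2`` more accessible than
    closed chromatin); ``n_diff_regions`` of them are 2**``region_lfc``
    more accessible in BM than CB and as many the other way, applied
    symmetrically (+/- lfc/2 per source) so both directions stand out in
    the cross-sample maximum.  NFI motif instances are planted inside the
    up-in-BM regions and protected in BM samples (bound factor); decoy
    motifs fill the remaining regions.  Per-sample cut tracks carry
    hexamer bias, the regional structure, depth wobble, and the BM-only
    protection.
    """
    rng = np.random.default_rng(seed)
    genome = syn.make_genome(genome_length, 0.5, int(rng.integers(2**31)))
    nfi = list(nfi_fixture_pwms())
    decoys = decoy_pwms(n_decoys)

    spacing = genome_length // (n_regions + 1)
    centers = np.arange(1, n_regions + 1) * spacing
    labels = np.array(["null"] * n_regions, dtype=object)
    order = rng.permutation(n_regions)
    labels[order[:n_diff_regions]] = "up_in_BM"
    labels[order[n_diff_regions : 2 * n_diff_regions]] = "up_in_CB"

    import itertools

    from . import seq as _seq
    from .intervals import GenomicInterval

    entries = []
    nfi_cycle = itertools.cycle(nfi)
    decoy_cycle = itertools.cycle(decoys)
    codes = _seq.encode(genome)
    offsets = np.linspace(-150, 150, instances_per_region).astype(int)
    for center, label in zip(centers, labels):
        for off in offsets:
            if label == "up_in_BM":
                pwm = next(nfi_cycle)
                protected = True
            else:
                pwm = next(decoy_cycle)
                protected = False
            start = int(center + off - pwm.width // 2)
            strand = "+" if rng.random() < 0.5 else "-"
            syn.plant_instance_at(codes, pwm, start, strand)
            entries.append(
                (pwm.id, GenomicInterval("chrS", start, start + pwm.width, strand),
                 strand, protected)
            )
    genome = _seq.decode(codes)

    bias = syn.random_bias_table(int(rng.integers(2**31)), sd=bias_sd)
    design = syn.make_design(("BM", "CB"), populations, replicates=replicates)

    region_lfc_arr = np.where(
        labels == "up_in_BM", region_lfc, np.where(labels == "up_in_CB", -region_lfc, 0.0)
    )
    cuts = {}
    for _, row in design.iterrows():
        sign = 0.5 if row["source"] == "BM" else -0.5
        is_bm = row["source"] == "BM"
        mult = np.ones(genome_length)
        for center, lfc in zip(centers, region_lfc_arr):
            lo = max(0, center - region_halfwidth)
            hi = min(genome_length, center + region_halfwidth)
            mult[lo:hi] *= 2.0 ** (open_log2 + sign * lfc)
        truth = syn.SyntheticTruth(
            planted_motif_instances=entries if is_bm else
            [(m, iv, s, False) for m, iv, s, _ in entries],
            bias_table=bias,
            protection_factor=protection_factor if is_bm else 1.0,
        )
        depth = int(depth_per_sample * rng.uniform(0.85, 1.15))
        cuts[row["sample"]] = syn.simulate_cut_sites(
            genome, bias, truth, depth, int(rng.integers(2**31)),
            weight_multipliers=mult,
        )

    region_truth = pd.DataFrame(
        {
            "chrom": "chrS",
            "start": centers - region_halfwidth,
            "end": centers + region_halfwidth,
            "label": labels,
            "log2fc_bm_vs_cb": region_lfc_arr,
        }
    )
    return SourceComparisonStudy(
        genome=genome,
        design=design,
        cuts=cuts,
        pwms=nfi + decoys,
        truth_instances=_truth_to_instances(entries),
        region_truth=region_truth,
        bias_table=bias,
    )


def nb_null_calibration(
    seed: int,
    n_peaks: int = 2000,
    dispersion: float = 0.02,
) -> dict[str, float]:
    """Type-I error of the NB Wald test on an all-null count matrix.

    Twelve samples (BM/CB x populations 3-5 x 2 replicates), population as
    covariate.  Returns the fraction of peaks with p < 0.05 and the
    KS-uniformity p-value of the p-value distribution.
    """
    from scipy.stats import kstest

    design = syn.make_design(("BM", "CB"), (3, 4, 5), replicates=2)
    matrix, _ = syn.simulate_count_matrix(
        n_peaks, design, None, dispersion=dispersion, seed=seed
    )
    res = fit_nb_wald(matrix, PopulationWindow.mid())
    p = res["p"].dropna().to_numpy()
    return {
        "fraction_p_lt_05": float((p < 0.05).mean()),
        "ks_uniform_p": float(kstest(p, "uniform").pvalue),
    }


def nb_recovery(
    seed: int,
    n_peaks: int = 1000,
    n_planted: int = 300,
    lfc: float = 2.0,
    dispersion: float = 0.02,
) -> dict[str, float]:
    """Recovery of a planted log2 fold-change with 3 vs 3 samples.

    Effects are planted symmetrically (half up in BM, half up in CB) so
    median-of-ratios size factors stay unbiased, as in a real comparison
    where differential peaks go both ways.  Returns the fraction of
    high-coverage planted peaks (base mean >= 100) whose estimate lands
    within +/-0.5 of the signed truth, and the median absolute estimate.
    """
    design = syn.make_design(("BM", "CB"), (1,), replicates=3)
    effects = {i: (lfc if i % 2 == 0 else -lfc) for i in range(n_planted)}
    matrix, truth = syn.simulate_count_matrix(
        n_peaks, design, effects, dispersion=dispersion, seed=seed,
        baseline_range=(100.0, 2000.0),
    )
    res = fit_nb_wald(matrix, window=None, covariates=())
    signed = np.array([lfc if i % 2 == 0 else -lfc for i in range(n_planted)])
    planted = res.iloc[:n_planted]
    high = planted["base_mean"].to_numpy() >= 100
    err = np.abs(planted["log2fc"].to_numpy() - signed)[high]
    return {
        "fraction_within_half": float((err <= 0.5).mean()),
        "median_abs_log2fc": float(planted["log2fc"].abs()[high].median()),
        "n_evaluated": float(high.sum()),
    }
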