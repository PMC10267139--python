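"""End-to-end orchestration: simulate, or chain the analysis stages.

``run_pipeline`` executes atlas -> counts -> VST -> percentile filter ->
differential -> labels -> (GC-matched motif enrichment, bias-corrected
footprinting) and writes one TSV per stage, each carrying a provenance
header with the config hash and seed.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import footprint as fp
from . import io as aio
from . import synthetic as syn
from .atlas import (
    PeakMatrix,
    build_universal_peaks,
    clip_to_contigs,
    count_cuts_in_peaks,
    percentile_filter,
    vst_normalize,
)
from .config import RunConfig
from .differential import PopulationWindow, fit_nb_wald, label_peaks
from .enrichment import fisher_motif_enrichment, gc_content, gc_matched_sample
from .motifs import effective_cutoff, nfi_fixture_pwms, read_pwms, scan_pwm, write_jaspar
from .studies import simulate_source_comparison

logger = logging.getLogger(__name__)


def _write(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    aio.write_tsv(df, path, header=config.provenance())


def simulate(config: RunConfig) -> Path:
    """Write a complete synthetic two-source study into the result directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study = simulate_source_comparison(config.seed)
    aio.write_fasta({"chrS": study.genome}, out / "genome.fa")
    for sample, cuts in study.cuts.items():
        aio.write_cuts(cuts, out / f"cuts_{sample}.tsv", header=config.provenance())
    aio.write_tsv(study.design, out / "samples.tsv", header=config.provenance())
    aio.write_tsv(study.truth_instances, out / "truth_instances.tsv", header=config.provenance())
    aio.write_tsv(study.region_truth, out / "truth_regions.tsv", header=config.provenance())
    write_jaspar(study.pwms, out / "motifs.jaspar")
    logger.info("synthetic study written to %s", out)
    return out


def run_pipeline(config: RunConfig, mode: str = "compare_sources") -> Path:
    """Run the requested analysis mode; returns the result directory.

    Modes: ``simulate`` (generate a synthetic study), ``compare_sources``
    (BM vs CB within a population window), ``compare_conditions`` (same
    machinery with the contrast taken from the config, e.g. knockdown vs
    control with a dataset covariate).
    """
    if mode == "simulate":
        return simulate(config)
    if mode not in {"compare_sources", "compare_conditions"}:
        raise ValueError(f"unknown mode {mode!r}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    contigs = aio.read_fasta(config.genome)
    samples = aio.read_sample_sheet(config.sample_sheet)
    cuts = {s: aio.read_cuts(config.cuts[s]) for s in samples["sample"]}
    genome_len = {c: len(s) for c, s in contigs.items()}

    # ---- atlas
    if config.peaks:
        per_sample = [aio.read_narrow_peak(config.peaks[s]) for s in samples["sample"]]
    else:
        logger.info("no peak calls supplied; using naive summit picking on cuts")
        per_sample = [
            syn.naive_peak_calls(
                cuts[s], genome_len[next(iter(genome_len))], top_k=config.top_k
            )
            for s in samples["sample"]
        ]
    atlas = build_universal_peaks(per_sample, config.top_k, config.halfwidth)
    atlas = clip_to_contigs(atlas, genome_len)
    aio.write_bed(atlas, out / "atlas.bed", header=config.provenance())

    # ---- counts, VST, filter
    counts = np.column_stack(
        [count_cuts_in_peaks(cuts[s], atlas) for s in samples["sample"]]
    )
    matrix = PeakMatrix(peaks=atlas, counts=counts, samples=samples)
    vst_normalize(matrix)
    aio.write_matrix(matrix, out / "matrix.tsv", header=config.provenance())
    filtered = percentile_filter(matrix, config.percentile, config.percentile_channel)

    # ---- differential + labels
    window = None
    if mode == "compare_sources" and config.window:
        window = PopulationWindow.named(config.window)
    result = fit_nb_wald(
        filtered, window=window, contrast=config.contrast, covariates=config.covariates
    )
    labeled = label_peaks(result, config.fdr_max, config.lfc_min, config.bg_p_min)
    _write(labeled, out / "differential.tsv", config)

    # ---- motif scan
    pwms = read_pwms(config.pwms) if config.pwms else nfi_fixture_pwms()
    genome_str = contigs if len(contigs) > 1 else next(iter(contigs.values()))
    instances = pd.concat(
        [
            scan_pwm(
                genome_str, pwm,
                p_cutoff=effective_cutoff(pwm, config.scan_p),
                max_instances=config.max_instances,
            )
            for pwm in pwms
        ],
        ignore_index=True,
    )

    # ---- GC-matched enrichment per direction
    gc = gc_content(filtered.peaks, genome_str)
    label_arr = labeled["label"].to_numpy()
    bg_idx = np.flatnonzero(label_arr == "background")
    for direction, tag in (("differential_up_A", "up_A"), ("differential_up_B", "up_B")):
        diff_idx = np.flatnonzero(label_arr == direction)
        if len(diff_idx) == 0 or len(bg_idx) == 0:
            logger.warning("no peaks for direction %s; enrichment skipped", direction)
            continue
        sel = gc_matched_sample(
            gc[diff_idx], gc[bg_idx],
            n=min(config.n_background, max(1, len(bg_idx) - 1)),
            bins=config.gc_bins, seed=config.seed,
        )
        enr = fisher_motif_enrichment(
            [filtered.peaks[i] for i in diff_idx],
            [filtered.peaks[i] for i in bg_idx[sel]],
            instances, direction=direction,
        )
        _write(enr, out / f"enrichment_{tag}.tsv", config)

    # ---- footprinting per contrast level, then the difference
    if not isinstance(genome_str, str):
        raise NotImplementedError(
            "footprinting currently requires a single-contig genome"
        )
    col, level_a, level_b = config.contrast
    summaries = {}
    for level in (level_a, level_b):
        ids = samples.loc[samples[col] == level, "sample"]
        pooled = _pool_cuts([cuts[s] for s in ids])
        summaries[level], _ = fp.footprint_summary(
            pooled, instances, genome_str, sample=level,
            motif_widths={p.id: p.width for p in pwms},
            flank=config.footprint_flank,
        )
        _write(summaries[level], out / f"footprint_{level}.tsv", config)
    diff_fp = fp.differential_footprint(summaries[level_a], summaries[level_b])
    _write(diff_fp, out / "footprint_diff.tsv", config)
    return out


def _pool_cuts(tracks: list[syn.CutTrack]) -> syn.CutTrack:
    chroms: dict[str, list] = {}
    for t in tracks:
        for chrom, (pos, strand) in t.chroms.items():
            chroms.setdefault(chrom, []).append((pos, strand))
    merged = {}
    for chrom, parts in chroms.items():
        pos = np.concatenate([p for p, _ in parts])
        strand = np.concatenate([s for _, s in parts])
        order = np.argsort(pos, kind="stable")
        merged[chrom] = (pos[order], strand[order])
    return syn.CutTrack(merged)
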