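"""GC-matched background sampling and motif enrichment by Fisher's exact test.

Motif enrichment in differential peaks is confounded by base composition:
differential peak sets often shift in GC content, and GC-rich motifs then
look enriched with no true association.  The remedy implemented here is the
one used throughout regulatory genomics: bin the GC spectrum, then sample
the background so its GC-bin proportions match the differential set, and
only then test per-motif presence with a one-sided Fisher exact test,
BH-corrected across motifs within each direction.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from . import seq
from .intervals import GenomicInterval
from .stats import bh_adjust, fisher_greater, odds_ratio

logger = logging.getLogger(__name__)


def gc_content(peaks: Sequence[GenomicInterval], genome: str | dict[str, str],
               chrom: str = "chrS") -> np.ndarray:
    """(G+C) / (non-N length) per interval; all-N intervals give NaN."""
    contigs = {chrom: genome} if isinstance(genome, str) else genome
    coded = {c: seq.encode(s) for c, s in contigs.items()}
    out = np.empty(len(peaks))
    for i, iv in enumerate(peaks):
        if iv.chrom not in coded:
            raise ValueError(f"interval {iv.name} on unknown contig")
        codes = coded[iv.chrom]
        if iv.end > len(codes):
            raise ValueError(f"interval {iv.name} outside contig bounds")
        out[i] = seq.gc_fraction_of_codes(codes[iv.start : iv.end])
    n_bad = int(np.isnan(out).sum())
    if n_bad:
        logger.info("%d all-N intervals have undefined GC content", n_bad)
    return out


def gc_bin_edges(values: np.ndarray, bins: int = 20, equal_width: bool = False) -> np.ndarray:
    """Bin edges over the pooled GC values: equal-occupancy quantiles by default."""
    values = np.asarray(values, dtype=float)
    if equal_width:
        return np.linspace(values.min(), values.max(), bins + 1)
    return np.quantile(values, np.linspace(0, 1, bins + 1))


def _bin_assign(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(edges, values, side="right") - 1
    return np.clip(idx, 0, len(edges) - 2)


def gc_matched_sample(
    differential_gc: np.ndarray,
    background_pool_gc: np.ndarray,
    n: int = 2500,
    bins: int = 20,
    seed: int = 0,
    equal_width: bool = False,
) -> np.ndarray:
    """Indices into the background pool, GC-matched to the differential set.

    Bin edges are ``bins`` equal-probability quantiles of the pooled
    (differential + background) GC values.  The draw matches the
    differential bin proportions exactly: each bin is allocated
    ``n x (differential proportion)`` slots (largest-remainder rounding)
    filled by a uniform without-replacement draw within the bin.  This is
    the weighted-probability draw conditioned on its target bin counts; an
    unconditioned weighted draw without replacement systematically
    under-fills heavy bins whenever ``n`` is a sizable fraction of the
    pool, leaving residual GC confounding.  Bins whose allocation exceeds
    the pool (or with no background members) are warned about; the excess
    is redistributed proportionally over the remaining bins.  If the pool
    is smaller than ``n`` the whole pool is returned with a warning.
    """
    diff = np.asarray(differential_gc, dtype=float)
    pool = np.asarray(background_pool_gc, dtype=float)
    if len(pool) == 0:
        raise ValueError("background pool is empty")
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(pool) <= n:
        logger.warning("background pool (%d) <= requested n (%d); taking all", len(pool), n)
        return np.arange(len(pool))
    edges = gc_bin_edges(np.concatenate([diff, pool]), bins=bins, equal_width=equal_width)
    diff_bins = _bin_assign(diff, edges)
    pool_bins = _bin_assign(pool, edges)
    diff_count = np.bincount(diff_bins, minlength=bins).astype(float)
    pool_count = np.bincount(pool_bins, minlength=bins)
    if diff_count.sum() == 0:
        raise ValueError("differential set is empty")
    empty = (pool_count == 0) & (diff_count > 0)
    if empty.any():
        logger.warning(
            "GC bins %s have differential mass but no background peaks; "
            "their mass is redistributed proportionally",
            np.flatnonzero(empty).tolist(),
        )
    target = diff_count / diff_count.sum()
    # largest-remainder apportionment of n slots to bins, capped by capacity;
    # overflow redistributed proportionally among bins with spare capacity
    alloc = np.zeros(bins, dtype=np.int64)
    remaining_target = target.copy()
    remaining_target[pool_count == 0] = 0.0
    n_left = n
    for _ in range(bins):
        if n_left == 0 or remaining_target.sum() <= 0:
            break
        share = remaining_target / remaining_target.sum() * n_left
        ideal = np.minimum(alloc + share, pool_count)
        add_float = ideal - alloc
        add = np.floor(add_float).astype(np.int64)
        shortfall = int(n_left - add.sum())
        if shortfall > 0:
            frac = add_float - add
            frac[alloc + add >= pool_count] = -1.0
            order = np.argsort(-frac, kind="stable")
            for b in order[:shortfall]:
                if frac[b] < 0:
                    break
                add[b] += 1
        alloc += add
        overfull = alloc >= pool_count
        if overfull.any():
            logger.warning(
                "GC bins %s exhausted; excess redistributed",
                np.flatnonzero(overfull & (target > 0)).tolist(),
            )
        remaining_target = np.where(overfull, 0.0, target)
        n_left = n - int(alloc.sum())
        if n_left == 0:
            break
    rng = np.random.default_rng(seed)
    chosen = []
    for b in range(bins):
        if alloc[b] == 0:
            continue
        members = np.flatnonzero(pool_bins == b)
        chosen.append(rng.choice(members, size=int(alloc[b]), replace=False))
    return np.sort(np.concatenate(chosen)) if chosen else np.empty(0, dtype=np.int64)


def peaks_with_motif(
    peaks: Sequence[GenomicInterval], instances: pd.DataFrame
) -> np.ndarray:
    """Boolean per peak: does any motif instance overlap it by >= 1 base?"""
    present = np.zeros(len(peaks), dtype=bool)
    if len(instances) == 0:
        return present
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for i, iv in enumerate(peaks):
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, i))
    for chrom, rows in by_chrom.items():
        sub = instances[instances["chrom"] == chrom]
        if len(sub) == 0:
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        order = np.argsort(starts)
        starts, ends = starts[order], ends[order]
        # prefix max of instance ends lets a single searchsorted decide overlap
        cummax_end = np.maximum.accumulate(ends)
        for p_start, p_end, i in rows:
            j = np.searchsorted(starts, p_end, side="left")
            if j > 0 and cummax_end[j - 1] > p_start:
                present[i] = True
    return present


def fisher_motif_enrichment(
    differential: Sequence[GenomicInterval],
    background: Sequence[GenomicInterval],
    instances: pd.DataFrame,
    direction: str = "up_in_A",
) -> pd.DataFrame:
    """Per-motif 2x2 Fisher enrichment of motif presence in differential peaks.

    ``instances`` holds scanned instances for any number of motifs (column
    ``motif``).  Presence is binary: >= 1 instance overlapping the peak.
    Returns one row per motif (a, b, c, d, odds_ratio, p, fdr), BH-corrected
    across motifs.  An empty differential set yields an untestable result
    (p = NaN) rather than an error.
    """
    rows = []
    n_diff, n_bg = len(differential), len(background)
    for motif, sub in instances.groupby("motif", sort=True):
        diff_has = peaks_with_motif(differential, sub)
        bg_has = peaks_with_motif(background, sub)
        a = int(diff_has.sum())
        b = n_diff - a
        c = int(bg_has.sum())
        d = n_bg - c
        if n_diff == 0:
            p = float("nan")
        else:
            p = fisher_greater(a, b, c, d)
        rows.append(
            {
                "motif": motif,
                "direction": direction,
                "a": a,
                "b": b,
                "c": c,
                "d": d,
                "odds_ratio": odds_ratio(a, b, c, d),
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = bh_adjust(out["p"].to_numpy())
    else:
        out["fdr"] = []
    return out
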