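"""Hexamer-bias-corrected transcription factor footprinting.

The transposase used in ATAC-seq inserts with a strong local sequence
preference, so raw cut-site pileups around motif instances mix protein
protection with sequence bias.  The correction models the bias at hexamer
resolution with three ingredients:

* genomic hexamer frequencies (blacklist excluded),
* per-motif positional hexamer frequencies at every offset in −250..+250
  around the motif centers (normalised so the mean over hexamers at each
  position is one), and
* per-sample cut hexamer factors: the hexamer share at observed cut sites
  divided by its genomic share, renormalised to sum one.

The expected cut profile of a motif in a sample is the positional matrix
times the sample's factor vector (normalised to sum one); the footprint
score is log2(observed / expected) after scaling both to mean one.  The
summary statistics are footprint depth (FPD), a 10%-trimmed mean of the
score over the motif base region minus the flank mean, and flanking
accessibility (FA), the flank mean minus the background-region
(200–250 bp) mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import seq
from .intervals import GenomicInterval
from .stats import trimmed_mean

logger = logging.getLogger(__name__)

#: half-width of the footprint window around the motif center
DEFAULT_FLANK = 250
#: hexamer anchor: the window [cut-3, cut+3) on the reference strand,
#: reverse-complemented for '-' strand cuts
ANCHOR_OFFSET = 3


# ---------------------------------------------------------------------------
# hexamer models


def genome_hexamer_freq(
    genome: str, blacklist: Sequence[GenomicInterval] | None = None, chrom: str = "chrS"
) -> np.ndarray:
    """Genome hexamer proportions from sliding windows fully outside blacklist.

    Windows containing a non-ACGT base are dropped.  Returns 4096
    proportions summing to one.
    """
    codes = seq.encode(genome)
    idx, valid = seq.kmer_index_table(codes)
    if blacklist:
        bad = np.zeros(len(codes), dtype=bool)
        for iv in blacklist:
            if iv.chrom == chrom:
                bad[iv.start : iv.end] = True
        bad_window = np.convolve(bad.astype(np.int8), np.ones(6, dtype=np.int8))[5 : 5 + len(idx)]
        valid = valid & (bad_window == 0)
    kept = idx[valid]
    if len(kept) == 0:
        raise ValueError("no hexamer window survives blacklist/N exclusion")
    counts = np.bincount(kept, minlength=seq.N_HEXAMERS).astype(float)
    return counts / counts.sum()


@dataclass
class GenomeTracks:
    """Precomputed per-contig hexamer index tracks for fast lookups.

    ``anchored[g]`` is the hexamer index of the reference window
    [g-3, g+3), or -1 where the window leaves the contig or contains N;
    ``anchored_rc`` is its reverse complement's index.
    """

    length: int
    anchored: np.ndarray
    anchored_rc: np.ndarray

    @classmethod
    def from_genome(cls, genome: str) -> "GenomeTracks":
        codes = seq.encode(genome)
        idx, valid = seq.kmer_index_table(codes)
        anchored = np.full(len(codes), -1, dtype=np.int64)
        n = len(idx)
        anchored[ANCHOR_OFFSET : ANCHOR_OFFSET + n] = np.where(valid, idx, -1)
        rc = seq.revcomp_kmer_table()
        anchored_rc = np.where(anchored >= 0, rc[np.maximum(anchored, 0)], -1)
        return cls(len(codes), anchored, anchored_rc)


def motif_centers(instances: pd.DataFrame) -> np.ndarray:
    """Motif center = start + floor(width / 2), per instance (0-based)."""
    starts = instances["start"].to_numpy(dtype=np.int64)
    ends = instances["end"].to_numpy(dtype=np.int64)
    return starts + (ends - starts) // 2


def _usable(centers: np.ndarray, length: int, flank: int) -> np.ndarray:
    lo = flank + ANCHOR_OFFSET
    hi = length - flank - ANCHOR_OFFSET
    return (centers >= lo) & (centers < hi)


def positional_hexamer_freq(
    instances: pd.DataFrame,
    tracks: GenomeTracks,
    flank: int = DEFAULT_FLANK,
) -> np.ndarray:
    """Per-position hexamer frequencies around the motif centers.

    At each relative position d in −flank..+flank the hexamer anchored at
    the corresponding genomic base is tallied over all instances, with the
    position axis flipped and hexamers reverse-complemented for '-' strand
    instances.  Each position row is scaled so the mean over all 4096
    hexamers is one.  Instances without a full flank inside the contig are
    dropped (logged).
    """
    window = 2 * flank + 1
    centers = motif_centers(instances)
    strands = instances["strand"].to_numpy()
    ok = _usable(centers, tracks.length, flank)
    if not ok.any():
        raise ValueError("no instance has a full flank inside the contig")
    if (~ok).sum():
        logger.info("%d instances dropped (flank outside contig)", int((~ok).sum()))
    centers, strands = centers[ok], strands[ok]
    d = np.arange(-flank, flank + 1)
    counts = np.zeros((window, seq.N_HEXAMERS), dtype=np.int64)
    pos_grid = np.broadcast_to(np.arange(window), (1, window))
    for strand, track, sign in (("+", tracks.anchored, 1), ("-", tracks.anchored_rc, -1)):
        cen = centers[strands == strand]
        if len(cen) == 0:
            continue
        g = cen[:, None] + sign * d[None, :]
        h = track[g]
        valid = h >= 0
        np.add.at(
            counts,
            (np.broadcast_to(pos_grid, h.shape)[valid], h[valid]),
        np.int64(1),
        )
    totals = counts.sum(axis=1, keepdims=True).astype(float)
    if (totals == 0).any():
        raise ValueError("a window position has no valid hexamer context")
    return counts * (seq.N_HEXAMERS / totals)


def cut_hexamer_factors(
    cuts,
    tracks: GenomeTracks,
    genome_freq: np.ndarray,
) -> np.ndarray:
    """Per-sample hexamer cut factors: cut share / genomic share, sum one.

    '+' cuts take the reference hexamer anchored at the cut; '-' cuts its
    reverse complement.  Cuts whose hexamer context is invalid (N or contig
    edge) are skipped and counted in the log.  Hexamers absent from the
    genome get factor 0.
    """
    tallies = np.zeros(seq.N_HEXAMERS, dtype=np.int64)
    n_skipped = 0
    n_total = 0
    for _, (pos, strand) in cuts.chroms.items():
        n_total += len(pos)
        h_plus = tracks.anchored[pos]
        h_minus = tracks.anchored_rc[pos]
        h = np.where(strand == 0, h_plus, h_minus)
        valid = h >= 0
        n_skipped += int((~valid).sum())
        tallies += np.bincount(h[valid], minlength=seq.N_HEXAMERS)
    if n_total < 1000:
        logger.warning("only %d cuts; hexamer factors will be unstable", n_total)
    if n_skipped:
        logger.info("%d cuts skipped (invalid hexamer context)", n_skipped)
    total = tallies.sum()
    if total == 0:
        raise ValueError("no cut has a valid hexamer context")
    share = tallies / total
    with np.errstate(divide="ignore", invalid="ignore"):
        factors = np.where(genome_freq > 0, share / genome_freq, 0.0)
    return factors / factors.sum()


def expected_cut_profile(positional: np.ndarray, factors: np.ndarray) -> np.ndarray:
    """Expected cut distribution over the window: positional @ factors, sum one."""
    e = positional @ factors
    s = e.sum()
    if s <= 0:
        raise ValueError("degenerate expected profile (all zero)")
    return e / s


def observed_cut_profile(
    cuts,
    instances: pd.DataFrame,
    tracks: GenomeTracks,
    flank: int = DEFAULT_FLANK,
    chrom: str = "chrS",
) -> np.ndarray:
    """Cut counts per relative position, pooled over strands and instances.

    The position axis is oriented by instance strand ('-' instances are
    flipped).  Overlapping instances each contribute in full.
    """
    if chrom not in cuts.chroms:
        return np.zeros(2 * flank + 1, dtype=np.int64)
    pos, _ = cuts.chroms[chrom]
    per_base = np.bincount(pos, minlength=tracks.length)
    centers = motif_centers(instances)
    strands = instances["strand"].to_numpy()
    ok = _usable(centers, tracks.length, flank)
    centers, strands = centers[ok], strands[ok]
    d = np.arange(-flank, flank + 1)
    obs = np.zeros(2 * flank + 1, dtype=np.int64)
    for strand, sign in (("+", 1), ("-", -1)):
        cen = centers[strands == strand]
        if len(cen) == 0:
            continue
        g = cen[:, None] + sign * d[None, :]
        obs += per_base[g].sum(axis=0)
    return obs


# ---------------------------------------------------------------------------
# footprint score and summary statistics


@dataclass
class FootprintRegions:
    """Deterministic score regions around the motif center for width W.

    base: |pos| <= W/2 + 5; flank: min(18, W/2 + 10) <= |pos| <= 50;
    background: 200 <= |pos| <= 250.  ``widest_inner`` switches the flank
    inner edge to max(18, W/2 + 10) for wide motifs whose base region would
    otherwise overlap the flank.
    """

    width: int
    flank: int = DEFAULT_FLANK
    widest_inner: bool = False

    @property
    def base_halfwidth(self) -> float:
        return self.width / 2 + 5

    @property
    def flank_inner(self) -> float:
        edge = self.width / 2 + 10
        return max(18.0, edge) if self.widest_inner else min(18.0, edge)

    def positions(self) -> np.ndarray:
        return np.arange(-self.flank, self.flank + 1)

    def base_mask(self) -> np.ndarray:
        p = np.abs(self.positions())
        return p <= self.base_halfwidth

    def flank_mask(self) -> np.ndarray:
        p = np.abs(self.positions())
        return (p >= self.flank_inner) & (p <= 50)

    def background_mask(self) -> np.ndarray:
        p = np.abs(self.positions())
        return (p >= 200) & (p <= 250)


@dataclass
class FootprintProfile:
    """Per (motif, sample) footprint profile and summary statistics."""

    motif: str
    sample: str
    positions: np.ndarray
    observed: np.ndarray  # mean-1 normalised
    expected: np.ndarray  # mean-1 normalised
    score: np.ndarray  # log2(observed / expected), NaN where masked
    width: int
    fa: float = float("nan")
    fpd: float = float("nan")
    empty: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": self.positions,
                "observed": self.observed,
                "expected": self.expected,
                "score": self.score,
            }
        )


def footprint_score(
    observed_counts: np.ndarray,
    expected: np.ndarray,
    motif: str = "",
    sample: str = "",
    width: int = 6,
    flank: int = DEFAULT_FLANK,
) -> FootprintProfile:
    """log2 ratio of mean-one observed over mean-one expected cut profiles.

    Positions where the expected (or observed) value is zero are masked to
    NaN and excluded from downstream region means.  A window with zero
    total observed cuts yields a profile flagged empty.
    """
    obs = np.asarray(observed_counts, dtype=float)
    exp = np.asarray(expected, dtype=float)
    positions = np.arange(-flank, flank + 1)
    if obs.sum() == 0:
        nan = np.full_like(obs, np.nan)
        return FootprintProfile(motif, sample, positions, nan, nan, nan, width, empty=True)
    obs_n = obs / obs.mean()
    exp_n = exp / exp.mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.log2(obs_n / exp_n)
    masked = ~np.isfinite(score)
    if masked.any():
        logger.info("%d window positions masked (zero observed or expected)", int(masked.sum()))
        score = np.where(masked, np.nan, score)
    return FootprintProfile(motif, sample, positions, obs_n, exp_n, score, width)


def compute_fa_fpd(
    profile: FootprintProfile, trim: float = 0.10, widest_inner: bool = False
) -> tuple[float, float]:
    """Fill and return (FA, FPD) from the profile's score vector.

    FPD = trimmed_mean(base) - mean(flank); FA = mean(flank) - mean(background).
    Masked (NaN) positions are excluded from their region; a fully masked
    region leaves the statistic NaN.
    """
    regions = FootprintRegions(profile.width, flank=(len(profile.score) - 1) // 2,
                               widest_inner=widest_inner)

    def region_values(mask: np.ndarray) -> np.ndarray:
        v = profile.score[mask]
        return v[np.isfinite(v)]

    base = region_values(regions.base_mask())
    flank_v = region_values(regions.flank_mask())
    bg = region_values(regions.background_mask())
    flank_mean = float(np.mean(flank_v)) if len(flank_v) else float("nan")
    bg_mean = float(np.mean(bg)) if len(bg) else float("nan")
    fpd = trimmed_mean(base, trim) - flank_mean if len(base) else float("nan")
    fa = flank_mean - bg_mean
    profile.fa, profile.fpd = fa, fpd
    return fa, fpd


def differential_footprint(
    summary_a: pd.DataFrame, summary_b: pd.DataFrame
) -> pd.DataFrame:
    """Per-motif (delta_fa, delta_fpd) = condition A minus condition B.

    Inputs are summary frames with columns (motif, fa, fpd); motifs missing
    in one condition are dropped with a log message.  Rank columns are
    ascending (most negative delta_fpd = rank 1: deepest footprint gain in A).
    """
    merged = summary_a.merge(summary_b, on="motif", suffixes=("_a", "_b"), how="inner")
    n_dropped = len(set(summary_a["motif"]) ^ set(summary_b["motif"]))
    if n_dropped:
        logger.info("%d motifs present in only one condition; dropped", n_dropped)
    merged["delta_fa"] = merged["fa_a"] - merged["fa_b"]
    merged["delta_fpd"] = merged["fpd_a"] - merged["fpd_b"]
    merged["rank_delta_fpd"] = merged["delta_fpd"].rank(method="min")
    merged["rank_delta_fa"] = merged["delta_fa"].rank(method="min", ascending=False)
    return merged.sort_values("delta_fpd", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# convenience driver


def footprint_summary(
    cuts,
    instances: pd.DataFrame,
    genome: str,
    blacklist: Sequence[GenomicInterval] | None = None,
    sample: str = "sample",
    motif_widths: dict[str, int] | None = None,
    flank: int = DEFAULT_FLANK,
    tracks: GenomeTracks | None = None,
    genome_freq: np.ndarray | None = None,
    positional: dict[str, np.ndarray] | None = None,
) -> tuple[pd.DataFrame, dict[str, FootprintProfile]]:
    """Full per-motif footprint computation for one sample.

    Returns (summary frame with motif/sample/fa/fpd, profiles by motif).
    Precomputed ``tracks``, ``genome_freq`` and per-motif ``positional``
    matrices may be passed to amortise work across samples and conditions.
    """
    if tracks is None:
        tracks = GenomeTracks.from_genome(genome)
    if genome_freq is None:
        genome_freq = genome_hexamer_freq(genome, blacklist)
    factors = cut_hexamer_factors(cuts, tracks, genome_freq)
    rows = []
    profiles: dict[str, FootprintProfile] = {}
    for motif, sub in instances.groupby("motif", sort=True):
        width = (
            motif_widths[motif]
            if motif_widths is not None
            else int((sub["end"] - sub["start"]).iloc[0])
        )
        pos_freq = (
            positional[motif]
            if positional is not None and motif in positional
            else positional_hexamer_freq(sub, tracks, flank)
        )
        expected = expected_cut_profile(pos_freq, factors)
        chrom = str(sub["chrom"].iloc[0])
        observed = observed_cut_profile(cuts, sub, tracks, flank, chrom=chrom)
        profile = footprint_score(observed, expected, motif, sample, width, flank)
        if not profile.empty:
            compute_fa_fpd(profile)
        profiles[motif] = profile
        rows.append(
            {"motif": motif, "sample": sample, "fa": profile.fa, "fpd": profile.fpd}
        )
    return pd.DataFrame(rows), profiles
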