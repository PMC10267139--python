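"""Synthetic data with known ground truth for the whole pipeline.

Generates (i) i.i.d. genomes with controllable GC content, (ii) planted
consensus motif instances, a stated fraction of which are "protected"
(bound), (iii) single-base transposase cut sites whose rate follows a
hexamer-level sequence-bias table and is multiplicatively depressed across
protected instances, and (iv) negative-binomial peak-count matrices with
planted source-dependent log2 fold-changes and an optional GC confound.

The bias table is symmetrised under reverse complement: the transposase
engages a DNA duplex, so its sequence preference is read identically from
either strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import seq
from .atlas import PeakMatrix
from .intervals import GenomicInterval

__all__ = [
    "CutTrack",
    "SyntheticTruth",
    "make_genome",
    "random_bias_table",
    "plant_motif_instances",
    "simulate_cut_sites",
    "make_design",
    "simulate_count_matrix",
    "simulate_gc_presence_confound",
]

#: positions this close to a contig end are excluded from the cut support
EDGE_EXCLUSION = 5


@dataclass
class CutTrack:
    """Single-base cut sites: per-chromosome sorted positions and strands.

    ``chroms`` maps chromosome name -> (positions int64 sorted ascending,
    strands uint8 with 0='+' and 1='-').
    """

    chroms: dict[str, tuple[np.ndarray, np.ndarray]]

    @property
    def n_cuts(self) -> int:
        return sum(len(p) for p, _ in self.chroms.values())

    def per_chrom(self) -> dict[str, np.ndarray]:
        """chrom -> sorted position array (strand dropped)."""
        return {c: p for c, (p, _) in self.chroms.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom, (pos, strand) in self.chroms.items():
            rows.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "start": pos,
                        "end": pos + 1,
                        "strand": np.where(strand == 0, "+", "-"),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
            columns=["chrom", "start", "end", "strand"]
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CutTrack":
        chroms = {}
        for chrom, grp in df.groupby("chrom", sort=True):
            pos = grp["start"].to_numpy(dtype=np.int64)
            strand = (grp["strand"].to_numpy() == "-").astype(np.uint8)
            order = np.argsort(pos, kind="stable")
            chroms[str(chrom)] = (pos[order], strand[order])
        return cls(chroms)

    def subsample(self, n: int, seed: int) -> "CutTrack":
        rng = np.random.default_rng(seed)
        chroms = {}
        total = self.n_cuts
        for chrom, (pos, strand) in self.chroms.items():
            k = int(round(n * len(pos) / total))
            idx = np.sort(rng.choice(len(pos), size=min(k, len(pos)), replace=False))
            chroms[chrom] = (pos[idx], strand[idx])
        return CutTrack(chroms)


@dataclass
class SyntheticTruth:
    """Ground truth of one synthetic dataset.

    ``planted_motif_instances``: (motif id, interval, strand, protected).
    ``bias_table``: 4096 relative cut propensities, mean exactly 1.
    ``protection_factor``: multiplicative cut-rate reduction inside
    protected instances (0 = fully bound, 1 = no footprint).
    ``planted_differential``: (peak index, true log2FC, direction label).
    """

    planted_motif_instances: list[tuple[str, GenomicInterval, str, bool]] = field(
        default_factory=list
    )
    bias_table: np.ndarray | None = None
    protection_factor: float = 1.0
    planted_differential: list[tuple[int, float, str]] = field(default_factory=list)
    dispersion: float | None = None
    seeds: dict[str, int] = field(default_factory=dict)

    def validate(self, genome_length: int | None = None) -> None:
        if self.bias_table is not None:
            bt = np.asarray(self.bias_table, dtype=float)
            if bt.shape != (seq.N_HEXAMERS,):
                raise ValueError("bias_table must have 4096 entries")
            if (bt <= 0).any():
                raise ValueError("bias_table entries must be > 0")
            if abs(bt.mean() - 1.0) > 1e-9:
                raise ValueError("bias_table mean must be 1")
        if not (0.0 <= self.protection_factor <= 1.0):
            raise ValueError("protection_factor must be in [0, 1]")
        if genome_length is not None:
            for _, iv, _, _ in self.planted_motif_instances:
                if iv.start < 0 or iv.end > genome_length:
                    raise ValueError(f"planted instance {iv.name} outside genome")


def make_genome(length: int, gc_fraction: float = 0.5, seed: int = 0) -> str:
    """I.i.d. genome with P(G) = P(C) = gc_fraction / 2."""
    if length < 1000:
        raise ValueError("genome length must be >= 1000")
    if not (0 < gc_fraction < 1):
        raise ValueError("gc_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    codes = rng.choice(4, size=length, p=[at, gc, gc, at]).astype(np.uint8)
    return seq.decode(codes)


def random_bias_table(seed: int, sd: float = 0.5) -> np.ndarray:
    """Lognormal hexamer cut propensities, reverse-complement symmetric, mean 1.

    ``sd`` is the log-scale spread before symmetrisation; real transposase
    bias spans roughly an order of magnitude across hexamers.
    """
    rng = np.random.default_rng(seed)
    raw = rng.lognormal(mean=0.0, sigma=sd, size=seq.N_HEXAMERS)
    rc = seq.revcomp_kmer_table()
    sym = np.sqrt(raw * raw[rc])  # geometric mean with the revcomp entry
    return sym / sym.mean()


def _consensus_codes(pwm) -> np.ndarray:
    """argmax base per column (ties -> lowest code, i.e. alphabetical)."""
    probs = np.asarray(pwm.probs, dtype=float)
    return np.argmax(probs, axis=0).astype(np.uint8)


def plant_instance_at(
    codes: np.ndarray, pwm, start: int, strand: str
) -> None:
    """Write the consensus of ``pwm`` (revcomp for '-') into ``codes`` at ``start``."""
    cons = _consensus_codes(pwm)
    word = cons if strand == "+" else seq.revcomp_codes(cons)
    codes[start : start + pwm.width] = word


def plant_motif_instances(
    genome: str,
    pwm,
    n: int,
    protected_fraction: float = 0.0,
    seed: int = 0,
    min_flank: int = 250,
    occupied: np.ndarray | None = None,
    chrom: str = "chrS",
    max_tries_per_instance: int = 500,
) -> tuple[str, list[tuple[str, GenomicInterval, str, bool]]]:
    """Write ``n`` non-overlapping consensus copies of ``pwm`` into ``genome``.

    Each placement writes the column-wise argmax base (reverse-complemented
    for '-' placements) at a random position keeping ``min_flank`` bases of
    genome on either side; exactly ``round(n * protected_fraction)``
    placements are flagged protected.  ``occupied`` is an optional boolean
    occupancy array over genome positions (mutated in place), letting
    callers plant several motifs without cross-motif overlap.
    """
    codes = seq.encode(genome).copy()
    width = pwm.width
    L = len(codes)
    if n == 0:
        return genome, []
    if L - 2 * min_flank < width:
        raise ValueError("genome too short for requested flank")
    rng = np.random.default_rng(seed)
    taken = occupied if occupied is not None else np.zeros(L, dtype=bool)
    if taken.shape != (L,):
        raise ValueError("occupied array must match genome length")
    entries: list[tuple[str, GenomicInterval, str, bool]] = []
    placed: list[tuple[int, str]] = []
    for _ in range(n):
        for _try in range(max_tries_per_instance):
            start = int(rng.integers(min_flank, L - min_flank - width + 1))
            end = start + width
            if taken[start:end].any():
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            plant_instance_at(codes, pwm, start, strand)
            taken[start:end] = True
            placed.append((start, strand))
            break
        else:
            raise RuntimeError(
                f"could not place {n} non-overlapping instances of {pwm.id} "
                f"(placed {len(placed)})"
            )
    n_protected = int(round(n * protected_fraction))
    protected_idx = set(rng.permutation(n)[:n_protected].tolist())
    for i, (start, strand) in enumerate(placed):
        iv = GenomicInterval(chrom, start, start + width, strand)
        entries.append((pwm.id, iv, strand, i in protected_idx))
    return seq.decode(codes), entries


def simulate_cut_sites(
    genome: str,
    bias_table: np.ndarray,
    truth: SyntheticTruth,
    depth: int,
    seed: int,
    chrom: str = "chrS",
    weight_multipliers: np.ndarray | None = None,
) -> CutTrack:
    """Draw ``depth`` cuts from a hexamer-biased multinomial over positions.

    The weight of position p is ``bias_table[hexamer anchored at p]`` times
    ``truth.protection_factor`` when p lies inside a protected planted
    instance.  The hexamer anchor is the window [p-3, p+3) on the reference
    strand.  Cut strands are i.i.d. Bernoulli(1/2); positions within
    ``EDGE_EXCLUSION`` bases of either contig end are excluded.
    ``weight_multipliers`` (length = genome) lets callers impose extra
    accessibility structure, e.g. open-region fold-changes per sample.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    truth.validate(genome_length=len(genome))
    codes = seq.encode(genome)
    L = len(codes)
    idx, valid = seq.kmer_index_table(codes)  # k-mer starting at each position
    # hexamer anchored at p occupies [p-3, p+3): k-mer start = p - 3
    weights = np.zeros(L, dtype=float)
    p_lo, p_hi = EDGE_EXCLUSION, L - EDGE_EXCLUSION
    starts = np.arange(p_lo, p_hi) - 3
    ok = valid[starts]
    weights[p_lo:p_hi] = np.where(ok, np.asarray(bias_table)[idx[starts]], 0.0)
    if truth.protection_factor != 1.0:
        for _, iv, _, protected in truth.planted_motif_instances:
            if protected:
                weights[iv.start : iv.end] *= truth.protection_factor
    if weight_multipliers is not None:
        weights *= weight_multipliers
    total = weights.sum()
    if total <= 0:
        raise ValueError("no position has positive cut weight")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(depth, weights / total)
    positions = np.repeat(np.arange(L, dtype=np.int64), counts)
    strands = (rng.random(depth) < 0.5).astype(np.uint8)
    return CutTrack({chrom: (positions, strands)})


def naive_peak_calls(
    cuts: CutTrack,
    genome_length: int,
    top_k: int = 300,
    halfwidth: int = 250,
    smooth: int = 150,
    min_separation: int = 1000,
) -> list:
    """Crude summit picker over a synthetic cut track (plumbing, not a caller).

    Smooths the per-base cut density with a moving average and greedily
    takes local maxima at least ``min_separation`` apart, highest first.
    Good enough to exercise atlas construction on simulated data; real
    analyses should bring their own peak caller output.
    """
    from .intervals import GenomicInterval, Peak

    peaks = []
    for chrom, (pos, _) in cuts.chroms.items():
        density = np.bincount(pos, minlength=genome_length).astype(float)
        kernel = np.ones(smooth) / smooth
        smoothed = np.convolve(density, kernel, mode="same")
        order = np.argsort(smoothed)[::-1]
        chosen: list[int] = []
        blocked = np.zeros(genome_length, dtype=bool)
        for p in order:
            if len(chosen) >= top_k:
                break
            if blocked[p] or smoothed[p] <= 0:
                continue
            chosen.append(int(p))
            lo = max(0, p - min_separation)
            hi = min(genome_length, p + min_separation)
            blocked[lo:hi] = True
        for summit in chosen:
            start = max(0, summit - halfwidth)
            end = min(genome_length, summit + halfwidth + 1)
            peaks.append(
                Peak(GenomicInterval(chrom, start, end), summit, float(smoothed[summit]))
            )
    return peaks


def make_design(
    sources: tuple[str, str] = ("BM", "CB"),
    populations: tuple[int, ...] = (3, 4, 5),
    replicates: int = 2,
    condition: str = "none",
) -> pd.DataFrame:
    """Balanced sample sheet: every (source, population) x replicates."""
    rows = []
    for src in sources:
        for pop in populations:
            for rep in range(1, replicates + 1):
                rows.append(
                    {
                        "sample": f"{src}_p{pop}_r{rep}",
                        "source": src,
                        "population": pop,
                        "condition": condition,
                        "dataset": "synthetic",
                    }
                )
    return pd.DataFrame(rows)


def _check_design(design: pd.DataFrame) -> None:
    counts = design.groupby("source").size()
    if (counts < 2).any():
        raise ValueError("need >= 2 samples per source level")
    if "population" in design.columns and design["population"].nunique() > 1:
        tab = pd.crosstab(design["source"], design["population"])
        # population fully nested in source -> collinear with it
        if ((tab > 0).sum(axis=0) == 1).all():
            raise ValueError(
                "degenerate design: population is confounded with source "
                f"(columns source, population)"
            )


def simulate_count_matrix(
    n_peaks: int,
    design: pd.DataFrame,
    effects: np.ndarray | dict[int, float] | None = None,
    dispersion: float = 0.02,
    gc_confound: bool = False,
    seed: int = 0,
    baseline_range: tuple[float, float] = (50.0, 2000.0),
    population_sd: float = 0.15,
    size_factor_sd: float = 0.15,
    peak_width: int = 500,
) -> tuple[PeakMatrix, SyntheticTruth]:
    """NB counts with planted source log2 fold-changes and optional GC confound.

    counts ~ NB(mean = baseline * sizefactor * 2^(lfc * [source == A] +
    population effect), alpha = ``dispersion``); A is the first source level
    in ``design``, so a positive planted lfc means "up in A".  With
    ``gc_confound`` the planted-differential peaks draw their GC content
    from a distribution shifted +0.08 above the background peaks.
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    _check_design(design)
    rng = np.random.default_rng(seed)
    m = len(design)

    lfc = np.zeros(n_peaks)
    if effects is not None:
        if isinstance(effects, dict):
            for i, v in effects.items():
                lfc[i] = v
        else:
            lfc = np.asarray(effects, dtype=float)
            if lfc.shape != (n_peaks,):
                raise ValueError("effects must have length n_peaks")

    lo, hi = baseline_range
    baseline = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_peaks))
    size_factors = rng.lognormal(mean=0.0, sigma=size_factor_sd, size=m)

    source_a = design["source"].iloc[0]
    is_a = (design["source"] == source_a).to_numpy(dtype=float)
    log2_mu = np.log2(baseline)[:, None] + lfc[:, None] * is_a[None, :]
    if "population" in design.columns and design["population"].nunique() > 1:
        pops = design["population"].to_numpy()
        for pop in np.unique(pops):
            eff = rng.normal(0.0, population_sd, size=n_peaks)
            log2_mu[:, pops == pop] += eff[:, None]
    mu = 2.0**log2_mu * size_factors[None, :]

    r = 1.0 / dispersion
    counts = rng.negative_binomial(r, r / (r + mu))

    gc = rng.normal(0.45, 0.07, size=n_peaks)
    if gc_confound:
        gc[lfc != 0] += 0.08
    gc = np.clip(gc, 0.25, 0.80)

    peaks = [
        GenomicInterval("chrP", 1000 + i * (peak_width + 500), 1000 + i * (peak_width + 500) + peak_width)
        for i in range(n_peaks)
    ]
    matrix = PeakMatrix(peaks=peaks, counts=counts, samples=design.copy(), gc=gc)
    truth = SyntheticTruth(
        planted_differential=[
            (i, float(lfc[i]), f"up_in_{source_a}" if lfc[i] > 0 else f"down_in_{source_a}")
            for i in np.flatnonzero(lfc != 0)
        ],
        dispersion=dispersion,
        seeds={"count_matrix": seed},
    )
    return matrix, truth


def simulate_gc_presence_confound(
    n_differential: int,
    n_pool: int,
    seed: int,
    gc_shift: float = 0.05,
    gc_sd: float = 0.06,
    base_gc: float = 0.45,
    presence_slope: float = 0.9,
    presence_intercept: float = -0.10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """A GC-confounded null for motif-enrichment testing.

    Differential peaks draw GC ~ N(base_gc + gc_shift, gc_sd); background
    pool peaks GC ~ N(base_gc, gc_sd).  Motif presence is Bernoulli with
    probability ``presence_intercept + presence_slope * gc`` (clipped) for
    BOTH sets — the motif tracks GC but has no true association with the
    differential status.  Returns (diff_gc, pool_gc, diff_present,
    pool_present).
    """
    rng = np.random.default_rng(seed)
    diff_gc = np.clip(rng.normal(base_gc + gc_shift, gc_sd, n_differential), 0.2, 0.8)
    pool_gc = np.clip(rng.normal(base_gc, gc_sd, n_pool), 0.2, 0.8)

    def presence(gc: np.ndarray) -> np.ndarray:
        p = np.clip(presence_intercept + presence_slope * gc, 0.02, 0.95)
        return rng.random(len(gc)) < p

    return diff_gc, pool_gc, presence(diff_gc), presence(pool_gc)
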