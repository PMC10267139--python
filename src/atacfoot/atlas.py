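"""Universal peak atlas: summit-window merging, cut counting, VST, filtering.

The atlas is the single coordinate system for all downstream counting: fixed
half-width windows around the top-scoring peak summits of every sample,
union-merged into a sorted, disjoint interval list.  Per-sample "peak scores"
are the number of transposase cut sites falling in each atlas interval.
Scores are normalised with a closed-form negative-binomial variance
stabilising transform (VST) under a single common dispersion, and peaks are
optionally filtered at a percentile of their cross-sample maximum score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

from .intervals import GenomicInterval, Peak, interval_arrays, merge_intervals

logger = logging.getLogger(__name__)


@dataclass
class PeakMatrix:
    """Peaks x samples count matrix with sample metadata.

    ``counts`` holds the raw per-interval cut counts ("peak scores");
    ``normalized``, when filled by :func:`vst_normalize`, has the same shape.
    ``samples`` is a DataFrame with at least a ``sample`` column and
    typically ``source`` (e.g. BM/CB), ``population``, ``condition``,
    ``dataset``.
    """

    peaks: list[GenomicInterval]
    counts: np.ndarray
    samples: pd.DataFrame
    normalized: np.ndarray | None = None
    size_factors: np.ndarray | None = None
    gc: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (peaks x samples)")
        if self.counts.shape != (len(self.peaks), len(self.samples)):
            raise ValueError(
                f"counts shape {self.counts.shape} != "
                f"({len(self.peaks)} peaks, {len(self.samples)} samples)"
            )
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        ids = self.samples["sample"].tolist()
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids")
        if self.normalized is not None and self.normalized.shape != self.counts.shape:
            raise ValueError("normalized must match counts shape")

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def peak_names(self) -> list[str]:
        return [iv.name for iv in self.peaks]

    def subset_peaks(self, mask: np.ndarray) -> "PeakMatrix":
        idx = np.flatnonzero(mask) if mask.dtype == bool else np.asarray(mask)
        return PeakMatrix(
            peaks=[self.peaks[i] for i in idx],
            counts=self.counts[idx],
            samples=self.samples.copy(),
            normalized=None if self.normalized is None else self.normalized[idx],
            size_factors=self.size_factors,
            gc=None if self.gc is None else self.gc[idx],
        )

    def subset_samples(self, mask: np.ndarray) -> "PeakMatrix":
        idx = np.flatnonzero(mask) if np.asarray(mask).dtype == bool else np.asarray(mask)
        return PeakMatrix(
            peaks=list(self.peaks),
            counts=self.counts[:, idx],
            samples=self.samples.iloc[idx].reset_index(drop=True),
            normalized=None if self.normalized is None else self.normalized[:, idx],
            size_factors=None,
            gc=self.gc,
        )


def build_universal_peaks(
    per_sample_peaks: Sequence[Sequence[Peak]],
    top_k: int = 50_000,
    halfwidth: int = 250,
) -> list[GenomicInterval]:
    """Merge fixed windows around the top-``top_k`` summits of every sample.

    Per sample the ``top_k`` peaks by ``call_score`` are kept (ties broken by
    genomic order; all peaks if fewer), each replaced by
    ``[summit - halfwidth, summit + halfwidth)``, and the windows from all
    samples are union-merged.  Windows that would start before the contig
    origin are clipped at 0.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    windows: list[GenomicInterval] = []
    for peaks in per_sample_peaks:
        for p in peaks:
            if p.summit is None:
                raise ValueError(f"peak {p.interval.name} has no summit")
        ranked = sorted(
            peaks,
            key=lambda p: (
                -(p.call_score if p.call_score is not None else 0.0),
                p.interval.chrom,
                p.interval.start,
            ),
        )[:top_k]
        for p in ranked:
            start = p.summit - halfwidth
            if start < 0:
                logger.info(
                    "window for summit %s:%d clipped at contig origin",
                    p.interval.chrom,
                    p.summit,
                )
                start = 0
            windows.append(GenomicInterval(p.interval.chrom, start, p.summit + halfwidth))
    return merge_intervals(windows)


def clip_to_contigs(
    intervals: Sequence[GenomicInterval], lengths: dict[str, int]
) -> list[GenomicInterval]:
    """Clip intervals at contig ends; unknown contigs are dropped with a log."""
    out = []
    for iv in intervals:
        if iv.chrom not in lengths:
            logger.info("interval %s on unknown contig dropped", iv.name)
            continue
        end = min(iv.end, lengths[iv.chrom])
        if end > iv.start:
            out.append(GenomicInterval(iv.chrom, iv.start, end, iv.strand))
    return out


def count_cuts_in_peaks(cuts, atlas: Sequence[GenomicInterval]) -> np.ndarray:
    """Number of cut positions p with start <= p < end, per atlas interval.

    ``cuts`` is a :class:`~atacfoot.synthetic.CutTrack` (or anything with a
    ``.per_chrom()`` mapping chrom -> sorted position array).  Atlas
    intervals are assumed disjoint, so a cut lands in at most one interval.
    Chromosomes present in the track but absent from the atlas are ignored.
    """
    arrays = interval_arrays(atlas)
    out = np.zeros(len(atlas), dtype=np.int64)
    for chrom, positions in cuts.per_chrom().items():
        if chrom not in arrays:
            logger.info("chromosome %s has cuts but no atlas intervals; ignored", chrom)
            continue
        starts, ends, orig = arrays[chrom]
        lo = np.searchsorted(positions, starts, side="left")
        hi = np.searchsorted(positions, ends, side="left")
        out[orig] += hi - lo
    return out


def estimate_size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors against a geometric-mean pseudo-reference.

    The reference is built over peaks with all-positive counts; if none
    exist, zeros are ignored within each peak instead (logged fallback).
    """
    counts = np.asarray(counts, dtype=float)
    allpos = (counts > 0).all(axis=1)
    if allpos.any():
        sub = counts[allpos]
        ref = np.exp(np.mean(np.log(sub), axis=1))
        ratios = sub / ref[:, None]
        sf = np.median(ratios, axis=0)
    else:
        logger.warning(
            "no peak has all-positive counts; ignoring zeros in the reference"
        )
        with np.errstate(divide="ignore"):
            logc = np.where(counts > 0, np.log(counts), np.nan)
        ref = np.exp(np.nanmean(logc, axis=1))
        ok = np.isfinite(ref) & (ref > 0)
        ratios = counts[ok] / ref[ok, None]
        sf = np.nanmedian(np.where(ratios > 0, ratios, np.nan), axis=0)
    if not np.all(np.isfinite(sf)) or (sf <= 0).any():
        raise ValueError("degenerate size factors; check for all-zero samples")
    return sf


def _common_dispersion_mle(scaled: np.ndarray, max_peaks: int = 2000) -> float:
    """MLE of a single NB dispersion alpha on size-factor-scaled counts.

    Each peak contributes a likelihood with its own mean (the peak's scaled
    mean); alpha is shared.  Peaks are subsampled deterministically for speed
    on large matrices.
    """
    scaled = scaled[np.mean(scaled, axis=1) > 0]
    if len(scaled) == 0:
        raise ValueError("no non-zero peaks for dispersion estimation")
    if len(scaled) > max_peaks:
        step = len(scaled) // max_peaks
        scaled = scaled[::step][:max_peaks]
    mu = np.mean(scaled, axis=1, keepdims=True)
    y = scaled

    def negll(log_alpha: float) -> float:
        a = np.exp(log_alpha)
        r = 1.0 / a
        ll = (
            gammaln(y + r)
            - gammaln(r)
            + r * np.log(r / (r + mu))
            + y * np.log(mu / (r + mu))
        )
        return -float(np.sum(ll))

    res = minimize_scalar(negll, bounds=(np.log(1e-8), np.log(10.0)), method="bounded")
    return float(np.exp(res.x))


def vst_transform(counts: np.ndarray, size_factors: np.ndarray, alpha: float) -> np.ndarray:
    """Closed-form NB variance stabilising transform.

    g(n) = log2( n/s + 1/(2a) + sqrt( (n/s)(n/s + 1/a) + 1/(4a^2) ) ),
    strictly monotone in n and asymptotically log2(2 n/s).
    """
    q = np.asarray(counts, dtype=float) / np.asarray(size_factors, dtype=float)[None, :]
    inv_a = 1.0 / alpha
    return np.log2(q + 0.5 * inv_a + np.sqrt(q * (q + inv_a) + 0.25 * inv_a**2))


def vst_normalize(matrix: PeakMatrix) -> PeakMatrix:
    """Fill ``matrix.normalized`` with the VST of its counts (in place; returned).

    Size factors are median-of-ratios; the dispersion is a single common
    alpha fit by maximum likelihood on the scaled counts.
    """
    if matrix.n_samples < 2:
        raise ValueError("need >= 2 samples")
    if (matrix.counts.sum(axis=0) == 0).any():
        raise ValueError("all-zero sample column")
    sf = estimate_size_factors(matrix.counts)
    scaled = matrix.counts / sf[None, :]
    alpha = _common_dispersion_mle(scaled)
    matrix.size_factors = sf
    matrix.normalized = vst_transform(matrix.counts, sf, alpha)
    return matrix


def percentile_filter(
    matrix: PeakMatrix, q: float = 0.80, channel: str = "normalized"
) -> PeakMatrix:
    """Keep peaks whose cross-sample maximum score reaches the q-quantile.

    The threshold is the linear-interpolation quantile of the per-peak
    maxima; peaks with ``max >= threshold`` are retained.  ``q == 0`` keeps
    everything.
    """
    if not (0 <= q < 1):
        raise ValueError("q must be in [0, 1)")
    scores = matrix.normalized if channel == "normalized" else matrix.counts
    if scores is None:
        raise ValueError(f"channel {channel!r} not populated")
    maxima = scores.max(axis=1)
    if q == 0:
        return matrix.subset_peaks(np.ones(matrix.n_peaks, dtype=bool))
    threshold = np.quantile(maxima, q, method="linear")
    return matrix.subset_peaks(maxima >= threshold)
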