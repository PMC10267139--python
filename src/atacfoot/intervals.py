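"""Genomic interval primitives: half-open spans, peaks, and interval algebra."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic span [start, end) on a named chromosome.

    ``strand`` is '+', '-' or '.' (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = field(default=".", compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(f"require 0 <= start < end, got [{self.start}, {self.end})")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_position(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    @property
    def name(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class Peak:
    """A called peak: an interval plus the caller's summit and score."""

    interval: GenomicInterval
    summit: int
    call_score: float | None = None

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(
                f"summit {self.summit} outside {self.interval.name}"
            )


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union-merge intervals; abutting intervals (end == next start) merge.

    Output is sorted by (chrom, start) and pairwise disjoint. Idempotent.
    """
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def interval_arrays(
    intervals: Sequence[GenomicInterval],
) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Per-chromosome (starts, ends, original indices), sorted by start."""
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for i, iv in enumerate(intervals):
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, i))
    out = {}
    for chrom, rows in by_chrom.items():
        rows.sort()
        arr = np.asarray(rows, dtype=np.int64)
        out[chrom] = (arr[:, 0], arr[:, 1], arr[:, 2])
    return out


def assign_positions(
    intervals: Sequence[GenomicInterval], chrom: str, positions: np.ndarray
) -> np.ndarray:
    """Index of the disjoint sorted interval containing each position, or -1.

    ``intervals`` must be disjoint within each chromosome (e.g. a merged
    atlas); positions need not be sorted.
    """
    arrays = interval_arrays(intervals)
    out = np.full(len(positions), -1, dtype=np.int64)
    if chrom not in arrays:
        return out
    starts, ends, orig = arrays[chrom]
    j = np.searchsorted(starts, positions, side="right") - 1
    ok = j >= 0
    ok[ok] &= positions[ok] < ends[j[ok]]
    out[ok] = orig[j[ok]]
    return out
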