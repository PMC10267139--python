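"""Position weight matrices: parsing, exact p-value calibration, scanning.

Match scores are log2 likelihood ratios against a background base
composition.  Match p-values are exact under the background model: the null
score distribution is built by dynamic-programming convolution of the
per-column score distributions after discretising scores to a fixed
granularity (1/1000 bit), so ``p(s) = P(score >= s)`` is computed without
simulation and is monotone non-increasing in the score.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

from . import seq

logger = logging.getLogger(__name__)

#: score discretisation: integer units of 1/1000 bit
SCORE_GRANULARITY = 1000
UNIFORM_BG = np.full(4, 0.25)


@dataclass
class PWM:
    """A motif as per-column base probabilities plus a background.

    ``probs`` is 4 x W in A,C,G,T row order; columns sum to 1.  Zero entries
    are replaced by a 1e-4 pseudo-probability (column renormalised) so the
    log-likelihood ratio is finite everywhere.
    """

    id: str
    probs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BG.copy())

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[0] != 4:
            raise ValueError("probs must be 4 x W")
        if self.width < 4:
            raise ValueError("motif width must be >= 4")
        if (self.probs < 0).any():
            raise ValueError("negative probabilities")
        colsums = self.probs.sum(axis=0)
        if np.abs(colsums - 1.0).max() > 1e-6:
            raise ValueError("columns must sum to 1")
        if (self.background <= 0).any():
            raise ValueError("background frequencies must be positive")
        if (self.probs == 0).any():
            logger.info("PWM %s has zero entries; adding 1e-4 pseudo-probability", self.id)
            self.probs = self.probs + 1e-4
            self.probs /= self.probs.sum(axis=0, keepdims=True)

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(seq.BASES[b] for b in np.argmax(self.probs, axis=0))

    @cached_property
    def int_scores(self) -> np.ndarray:
        """4 x W integer log2-LR scores in units of 1/1000 bit."""
        llr = np.log2(self.probs / self.background[:, None])
        return np.round(llr * SCORE_GRANULARITY).astype(np.int64)

    @cached_property
    def _null_tail(self) -> tuple[int, np.ndarray]:
        """(min_total, tail) with tail[s - min_total] = P(score >= s)."""
        scores = self.int_scores
        bg = self.background
        mins = scores.min(axis=0)
        lo = int(mins.sum())
        hi = int(scores.max(axis=0).sum())
        # index i of dist <-> total score lo + i; per-column shifts are
        # taken relative to the column minimum so they are non-negative
        dist = np.zeros(hi - lo + 1)
        for b in range(4):
            dist[scores[b, 0] - mins[0]] += bg[b]
        for j in range(1, self.width):
            new = np.zeros_like(dist)
            for b in range(4):
                s = int(scores[b, j] - mins[j])
                if s == 0:
                    new += bg[b] * dist
                else:
                    new[s:] += bg[b] * dist[:-s]
            dist = new
        tail = np.cumsum(dist[::-1])[::-1]
        return lo, np.minimum(tail, 1.0)

    def pvalue_of_int_score(self, int_score: np.ndarray) -> np.ndarray:
        """Exact P(null score >= s) for integer scores (vectorised)."""
        lo, tail = self._null_tail
        idx = np.clip(np.asarray(int_score) - lo, 0, len(tail) - 1)
        p = tail[idx]
        return np.where(np.asarray(int_score) < lo, 1.0, p)

    def max_score_pvalue(self) -> float:
        lo, tail = self._null_tail
        return float(tail[-1])

    def reverse_complement(self) -> "PWM":
        return PWM(self.id, self.probs[::-1, ::-1].copy(), self.background[::-1].copy())


def consensus_pwm(motif_id: str, consensus: str, strength: float = 0.85) -> PWM:
    """PWM with ``strength`` on the consensus base per column; N columns uniform."""
    width = len(consensus)
    probs = np.full((4, width), 0.25)
    off = (1.0 - strength) / 3.0
    for j, base in enumerate(consensus.upper()):
        if base == "N":
            continue
        col = np.full(4, off)
        col[seq.BASES.index(base)] = strength
        probs[:, j] = col
    return PWM(motif_id, probs)


def _from_bio(motif, background: np.ndarray | None = None) -> PWM:
    counts = np.array([motif.counts[b] for b in "ACGT"], dtype=float)
    probs = counts / counts.sum(axis=0, keepdims=True)
    name = motif.matrix_id if getattr(motif, "matrix_id", None) else motif.name
    bg = UNIFORM_BG.copy() if background is None else background
    return PWM(str(name), probs, bg)


def read_pwms(path: str, fmt: str | None = None) -> list[PWM]:
    """Read motifs from a JASPAR or MEME-minimal file.

    ``fmt`` is 'jaspar' or 'minimal'; inferred from content when omitted.
    """
    with open(path) as fh:
        text = fh.read()
    if fmt is None:
        fmt = "minimal" if "MEME version" in text else "jaspar"
    records = bio_motifs.parse(io.StringIO(text), fmt)
    return [_from_bio(m) for m in records]


def write_jaspar(pwms: list[PWM], path: str, scale: int = 100) -> None:
    """Write motifs as JASPAR-format (pseudo-)count matrices."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.id} {pwm.id}\n")
            counts = np.round(pwm.probs * scale).astype(int)
            for b, row in zip(seq.BASES, counts):
                fh.write(f"{b} [ " + " ".join(f"{v:4d}" for v in row) + " ]\n")


def effective_cutoff(pwm: PWM, p_cutoff: float = 1e-4, slack: float = 1.2) -> float:
    """Scan cutoff usable for motifs of any width.

    A short motif cannot attain a stringent genome-wide p-value (its
    maximum score already has p = 4**-W under a uniform background), so the
    cutoff is relaxed to just above the maximum-score p-value when needed:
    only (near-)consensus matches are then retained.
    """
    return max(p_cutoff, slack * pwm.max_score_pvalue())


def nfi_fixture_pwms() -> list[PWM]:
    """Bundled synthetic NFI-family matrices.

    Idealised stand-ins for the nuclear-factor-one binding models
    (full site consensus TGGCANNNTGCCA and half-sites TGCCAA / GCCAA):
    0.85 on the consensus base per informative column, uniform on the
    spacer columns.  They are synthetic fixtures, not database matrices.
    """
    from importlib.resources import files

    path = files("atacfoot.data").joinpath("nfi_synthetic.jaspar")
    records = bio_motifs.parse(io.StringIO(path.read_text()), "jaspar")
    return [_from_bio(m) for m in records]


def _window_int_scores(codes: np.ndarray, int_scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Total integer score of every window, plus validity (no N) mask."""
    W = int_scores.shape[1]
    n = len(codes) - W + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    total = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(W):
        window = codes[j : j + n]
        bad = window >= seq.N_CODE
        valid &= ~bad
        total += int_scores[np.minimum(window, 3), j]
    return total, valid


def scan_pwm(
    genome: str | dict[str, str],
    pwm: PWM,
    p_cutoff: float = 1e-4,
    max_instances: int = 500_000,
    chrom: str = "chrS",
) -> pd.DataFrame:
    """Scan both strands for motif matches with exact p <= ``p_cutoff``.

    Returns a DataFrame (motif, chrom, start, end, strand, score, p) sorted
    by coordinate; ``score`` is the log2 likelihood ratio in bits.  When
    more than ``max_instances`` windows pass, the best by p-value are kept
    (ties broken by coordinate).
    """
    contigs = {chrom: genome} if isinstance(genome, str) else genome
    rc_scores = pwm.reverse_complement().int_scores
    frames = []
    for name, sequence in sorted(contigs.items()):
        codes = seq.encode(sequence)
        if len(codes) < pwm.width:
            raise ValueError(f"contig {name} shorter than motif width")
        for strand, scores in (("+", pwm.int_scores), ("-", rc_scores)):
            total, valid = _window_int_scores(codes, scores)
            pvals = pwm.pvalue_of_int_score(total)
            hit = valid & (pvals <= p_cutoff)
            pos = np.flatnonzero(hit)
            if len(pos) == 0:
                continue
            frames.append(
                pd.DataFrame(
                    {
                        "motif": pwm.id,
                        "chrom": name,
                        "start": pos,
                        "end": pos + pwm.width,
                        "strand": strand,
                        "score": total[pos] / SCORE_GRANULARITY,
                        "p": pvals[pos],
                    }
                )
            )
    if not frames:
        return pd.DataFrame(
            columns=["motif", "chrom", "start", "end", "strand", "score", "p"]
        )
    out = pd.concat(frames, ignore_index=True)
    if len(out) > max_instances:
        out = out.sort_values(
            ["p", "chrom", "start", "strand"], kind="stable"
        ).head(max_instances)
    return out.sort_values(["chrom", "start", "strand"], kind="stable").reset_index(
        drop=True
    )
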