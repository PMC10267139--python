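"""Brute-force oracles for the exact-equivalence checks.

Each function recomputes a quantity by the most direct method available —
integer-exact hypergeometric summation, exhaustive window enumeration,
elementary sorting — independently of the optimised implementation it is
compared against.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from . import seq
from .motifs import PWM


def hypergeom_tail(a: int, b: int, c: int, d: int) -> float:
    """P(X >= a) for the 2x2 table margins, by integer-exact summation."""
    N, K, n = a + b + c + d, a + c, a + b
    denom = math.comb(N, n)
    num = 0
    for x in range(a, min(K, n) + 1):
        num += math.comb(K, x) * math.comb(N - K, n - x)
    return num / denom


def hypergeom_tails_for_margins(N: int, K: int, n: int) -> np.ndarray:
    """P(X >= a) for every a in 0..min(K, n), exact integer suffix sums."""
    hi = min(K, n)
    lo = max(0, n - (N - K))
    denom = math.comb(N, n)
    terms = [0] * (hi + 1)
    for x in range(lo, hi + 1):
        terms[x] = math.comb(K, x) * math.comb(N - K, n - x)
    # exact integer suffix sums (binomial coefficients exceed int64)
    suffix = [0] * (hi + 1)
    running = 0
    for x in range(hi, -1, -1):
        running += terms[x]
        suffix[x] = running
    return np.array([s / denom for s in suffix])


def exhaustive_scan(sequence: str, pwm: PWM) -> list[tuple[int, str, int]]:
    """Every window on both strands with its integer score, by direct scoring."""
    codes = seq.encode(sequence)
    out = []
    for strand in "+-":
        for start in range(len(codes) - pwm.width + 1):
            window = codes[start : start + pwm.width]
            if strand == "-":
                window = seq.revcomp_codes(window)
            if (window >= 4).any():
                continue
            s = int(sum(pwm.int_scores[b, j] for j, b in enumerate(window)))
            out.append((start, strand, s))
    return out


def exhaustive_tail_probability(pwm: PWM, int_score: int) -> float:
    """P(score >= s) under the background by enumerating all 4**W words."""
    total = 0.0
    for word in itertools.product(range(4), repeat=pwm.width):
        s = sum(pwm.int_scores[b, j] for j, b in enumerate(word))
        if s >= int_score:
            total += float(np.prod([pwm.background[b] for b in word]))
    return total


def brute_trimmed_mean(values, trim: float = 0.10) -> float:
    v = sorted(float(x) for x in values)
    k = len(v)
    cut = math.floor(trim * k)
    kept = v[cut : k - cut] if cut else v
    return sum(kept) / len(kept)


def brute_bh(p: list[float]) -> list[float]:
    """Step-up BH by the textbook definition: q_i = min_{p_j >= p_i} p_j * n / rank_j."""
    n = len(p)
    out = []
    for pi in p:
        candidates = [pj * n / sum(1 for x in p if x <= pj) for pj in p if pj >= pi]
        out.append(min(1.0, min(candidates)))
    return out


def brute_interval_union(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Base-by-base union of half-open integer spans."""
    if not spans:
        return []
    hi = max(e for _, e in spans)
    covered = np.zeros(hi + 1, dtype=bool)
    for s, e in spans:
        covered[s:e] = True
    out = []
    start = None
    for pos in range(hi + 1):
        if covered[pos] and start is None:
            start = pos
        elif not covered[pos] and start is not None:
            out.append((start, pos))
            start = None
    if start is not None:
        out.append((start, hi + 1))
    return out


def brute_percentile_threshold(maxima: list[float], q: float) -> float:
    """Linear-interpolation quantile computed from first principles."""
    v = sorted(maxima)
    if len(v) == 1:
        return v[0]
    h = q * (len(v) - 1)
    lo = math.floor(h)
    frac = h - lo
    return v[lo] + frac * (v[min(lo + 1, len(v) - 1)] - v[lo])
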