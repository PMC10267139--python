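"""Small shared statistics: BH adjustment, one-sided Fisher, trimmed mean."""

from __future__ import annotations

import numpy as np
from scipy.stats import hypergeom


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaNs passed through).

    NaN entries are excluded from the denominator, matching tests that were
    never performed.
    """
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    ps = p[ok]
    n = len(ps)
    if n == 0:
        return out
    order = np.argsort(ps, kind="stable")
    ranked = ps[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(n)
    res[order] = np.minimum(adjusted, 1.0)
    out[ok] = res
    return out


def fisher_greater(a: int, b: int, c: int, d: int) -> float:
    """One-sided (enrichment) Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Rows are (differential, background); columns (with motif, without).
    p = P(X >= a) for X ~ Hypergeom(N = a+b+c+d, K = a+c, n = a+b).
    """
    n_total = a + b + c + d
    return float(hypergeom.sf(a - 1, n_total, a + c, a + b))


def odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """Sample odds ratio (a*d)/(b*c); NaN when b*c == 0 and a*d > 0, else inf rules."""
    if b * c == 0:
        return float("inf") if a * d > 0 else float("nan")
    return (a * d) / (b * c)


def trimmed_mean(values: np.ndarray, trim: float = 0.10) -> float:
    """Mean after dropping floor(trim * k) values from each tail of the sort."""
    v = np.sort(np.asarray(values, dtype=float))
    k = len(v)
    if k == 0:
        return float("nan")
    cut = int(np.floor(trim * k))
    kept = v[cut : k - cut] if cut > 0 else v
    return float(np.mean(kept))
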