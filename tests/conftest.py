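import numpy as np
import pytest

from atacfoot.intervals import GenomicInterval
from atacfoot.motifs import PWM, consensus_pwm, nfi_fixture_pwms


@pytest.fixture(scope="session")
def nfi_pwms():
    return {p.id: p for p in nfi_fixture_pwms()}


@pytest.fixture
def toy_pwm():
    """Width-4 PWM with a clear consensus ACGT."""
    return consensus_pwm("toy_ACGT", "ACGT", strength=0.7)


@pytest.fixture
def iv():
    def make(start, end, chrom="chrS", strand="."):
        return GenomicInterval(chrom, start, end, strand)

    return make


def brute_force_merge(intervals):
    """Base-by-base union of intervals (oracle for merge_intervals)."""
    out = []
    by_chrom = {}
    for i in intervals:
        by_chrom.setdefault(i.chrom, []).append(i)
    for chrom in sorted(by_chrom):
        ivs = by_chrom[chrom]
        hi = max(i.end for i in ivs)
        covered = np.zeros(hi + 1, dtype=bool)
        for i in ivs:
            covered[i.start : i.end] = True
        start = None
        for pos in range(hi + 1):
            if covered[pos] and start is None:
                start = pos
            elif not covered[pos] and start is not None:
                out.append(GenomicInterval(chrom, start, pos))
                start = None
        if start is not None:
            out.append(GenomicInterval(chrom, start, hi + 1))
    return out
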