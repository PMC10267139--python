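"""Readers and writers for the plain-text formats the pipeline speaks.

Coordinates are 0-based half-open everywhere, matching BED; narrowPeak
summits are ``start + offset`` with the conventional -1 sentinel mapped to
the interval midpoint (logged).  All tabular outputs are TSV so test
diffs stay readable.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GenomicInterval, Peak

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------- FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(contigs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in contigs.items()]
    SeqIO.write(records, str(path), "fasta")


# ----------------------------------------------------------------- BED-likes


def read_bed(path: str | Path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
            out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path,
              header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_narrow_peak(path: str | Path) -> list[Peak]:
    """narrowPeak: 10 columns; summit = start + field 10 (offset -1 -> midpoint)."""
    peaks = []
    n_midpoint = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 10:
                raise ValueError(f"{path}:{lineno}: narrowPeak needs 10 columns")
            iv = GenomicInterval(f[0], int(f[1]), int(f[2]))
            offset = int(f[9])
            if offset == -1:
                summit = iv.start + len(iv) // 2
                n_midpoint += 1
            else:
                summit = iv.start + offset
            peaks.append(Peak(iv, summit, call_score=float(f[6])))
    if n_midpoint:
        logger.info("%d peaks without summit offset; midpoint used", n_midpoint)
    return peaks


# ------------------------------------------------------------------- cut TSV


def read_cuts(path: str | Path):
    from .synthetic import CutTrack

    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        names=["chrom", "start", "end", "strand"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "strand": str},
    )
    return CutTrack.from_frame(df)


def write_cuts(track, path: str | Path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        track.to_frame().to_csv(fh, sep="\t", header=False, index=False)


# ----------------------------------------------------------------- truth TSV


def write_truth(truth, path: str | Path) -> None:
    rows = [
        {
            "motif": motif,
            "chrom": iv.chrom,
            "start": iv.start,
            "end": iv.end,
            "strand": strand,
            "protected": int(protected),
        }
        for motif, iv, strand, protected in truth.planted_motif_instances
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_truth_instances(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# --------------------------------------------------------------- peak matrix


def write_matrix(matrix, path: str | Path, channel: str = "counts",
                 header: str | None = None) -> None:
    data = matrix.counts if channel == "counts" else matrix.normalized
    df = pd.DataFrame(data, index=matrix.peak_names(), columns=matrix.samples["sample"])
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        df.to_csv(fh, sep="\t", index_label="peak")


def read_matrix(path: str | Path, samples: pd.DataFrame):
    from .atlas import PeakMatrix

    df = pd.read_csv(path, sep="\t", comment="#", index_col="peak")
    peaks = []
    for name in df.index:
        chrom, span = name.rsplit(":", 1)
        start, end = span.split("-")
        peaks.append(GenomicInterval(chrom, int(start), int(end)))
    ordered = df[samples["sample"].tolist()]
    return PeakMatrix(peaks=peaks, counts=ordered.to_numpy(), samples=samples)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    if "sample" not in df.columns:
        raise ValueError("sample sheet needs a 'sample' column")
    return df


def write_tsv(df: pd.DataFrame, path: str | Path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        df.to_csv(fh, sep="\t", index=False)
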