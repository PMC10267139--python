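"""Generate the synthetic two-source (BM vs CB) ATAC study used downstream.

Writes genome FASTA, per-sample cut-site tracks, the sample sheet, the
planted-truth tables (motif instances with protection flags; accessible
regions with their source log2 fold-changes), and the motif set, into
scratch/study/ (bulky generated data; the downstream drivers read it from
there and write their summary tables under results/).
"""

from pathlib import Path

from atacfoot.config import RunConfig
from atacfoot.pipeline import run_pipeline

# bulky simulated tracks live under scratch/ (not a deliverable); the
# downstream drivers read from here and write their tables to results/
OUT = Path(__file__).resolve().parent.parent / "scratch" / "study"


def main() -> None:
    cfg = RunConfig(out_dir=str(OUT), seed=20260920)
    run_pipeline(cfg, mode="simulate")
    n_cuts = sum(1 for _ in open(next(OUT.glob("cuts_*.tsv")))) - 1
    print(f"study written to {OUT}")
    print(f"example track size: ~{n_cuts} cuts; see samples.tsv for the design")


if __name__ == "__main__":
    main()
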