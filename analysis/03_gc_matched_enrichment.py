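"""GC confounding in motif enrichment, and what GC matching buys.

Simulates 100 repeats of a null in which differential peaks are GC-shifted
and the motif tracks GC (no true association), then tests enrichment with
a naive random background versus a GC-matched background.  Writes the
false-positive rates to results/gc_matching.tsv.
"""

from pathlib import Path

import pandas as pd

from atacfoot.studies import gc_confound_experiment

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    rates = gc_confound_experiment(seed=20260920, n_repeats=100)
    df = pd.DataFrame(
        [
            {"background": "naive_random", "fp_rate_p_lt_05": rates["naive_fp_rate"]},
            {"background": "gc_matched", "fp_rate_p_lt_05": rates["matched_fp_rate"]},
        ]
    )
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "gc_matching.tsv", sep="\t", index=False)
    print(df.to_string(index=False))
    print(
        "\nA GC-shifted differential set makes a GC-correlated motif look "
        "enriched under a random background; matching the background's "
        "GC-bin proportions to the differential set removes the artefact."
    )


if __name__ == "__main__":
    main()
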