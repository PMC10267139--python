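# atacfoot

Differential chromatin accessibility and transposase-bias-corrected
transcription-factor footprinting for ATAC-seq.

The package targets the comparison that distinguishes fetal-state
(cord-blood, CB) from adult-state (bone-marrow, BM) erythroid cells — the
setting in which nuclear-factor-one (NFI) binding sites surface as the
discriminating regulatory signal — but every stage is generic: it takes a
genome FASTA, per-sample cut-site tracks (or narrowPeak calls), a sample
sheet, and JASPAR/MEME motif files.

Four stages, each usable on its own:

1. **Peak atlas** — merge 500 bp windows around the top-50k peak summits of
   every sample into one disjoint coordinate system; count cut sites per
   interval ("peak score"); normalise with a closed-form negative-binomial
   variance-stabilising transform; filter at the 80th percentile of the
   cross-sample maximum.
2. **Differential accessibility** — per-peak NB log-link GLM (batched IRLS)
   with size-factor offsets and covariates (population stage, dataset
   batch), Cox–Reid dispersion estimates shrunk toward the pooled common
   value, Wald p-values, BH correction; peaks labelled differential per
   direction (FDR < 0.1, |log2FC| > log2 1.25) or background
   (p > 0.1, |log2FC| < log2 1.25).
3. **GC-matched motif enrichment** — exact-p-value PWM scanning (dynamic
   programming over 1/1000-bit score bins, cutoff 1e-4, top 500k
   instances), 20 equal-occupancy GC bins, 2500 background peaks matched to
   the differential set's GC spectrum, one-sided Fisher exact test per
   motif and direction with BH correction.
4. **Footprinting** — hexamer models of Tn5 sequence bias (genomic,
   positional around motif centers ±250 bp, per-sample cut factors), the
   expected-vs-observed log2 cut profile, and the summary statistics

       FPD = trimmed_mean(base) − mean(flank)        (footprint depth)
       FA  = mean(flank) − mean(background)          (flanking accessibility)

   with base `|pos| ≤ W/2+5`, flank `min(18, W/2+10) ≤ |pos| ≤ 50`,
   background `200 ≤ |pos| ≤ 250` for motif width W. Conditions are
   compared by ΔFPD / ΔFA per motif.

A first-class synthetic-data module (`atacfoot.synthetic`) generates
genomes, planted consensus motif instances, hexamer-biased cut tracks with
optional footprint protection, and NB count matrices with known truth, so
the whole pipeline is testable offline. Idealised NFI matrices
(TGGCANNNTGCCA, TGCCAA, GCCAA) ship as fixtures.

## Worked example

```python
from atacfoot import studies

# NFI instances protected (factor 0.2) in condition A only, 20 decoy motifs
diff, _ = studies.planted_footprint_study(seed=20260920)
print(diff[["motif", "fpd_a", "fpd_b", "delta_fpd"]].head(4).to_string(index=False))
```

prints

```
           motif     fpd_a     fpd_b  delta_fpd
        NFI_full -0.793136  0.008216  -0.801353
 NFI_half_TGCCAA -0.216333  0.006442  -0.222775
  NFI_half_GCCAA -0.087411 -0.002492  -0.084919
decoy03_TCCGTGAG -0.004840  0.020747  -0.025587
```

The three NFI motifs take the most negative footprint-depth differences —
their footprints deepen only in the protected condition — while the decoys
sit at noise level (|ΔFPD| ≲ 0.03). `fpd_b ≈ 0` shows the hexamer-bias
correction at work: condition B has the same sequence bias but no
protection, and the corrected profile is flat.

The numbered drivers under `analysis/` run the full narrative and write
tables to `results/`:

```bash
python analysis/01_simulate_study.py          # synthetic BM-vs-CB study (scratch/study)
python analysis/02_accessibility_differential.py
python analysis/03_gc_matched_enrichment.py
python analysis/04_footprinting.py
```

`02` recovers 8/8 planted up-in-BM and 8/8 up-in-CB regions as
differential peaks; `03` shows a GC-correlated motif called "enriched" in
71% of confounded-null repeats with a naive background but 7% with the
GC-matched background; `04` reproduces the bias-null flatness and the NFI
ΔFPD ranking above.

There is also a CLI (`atacfoot simulate|atlas|diff|enrich|footprint|
footprint-diff|run`) wrapping the same library calls for shell use.

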