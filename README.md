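# methylscreen

Reusable pipeline for case–control methylation-array analysis on 850K-style
β-value matrices: probe QC filtering, Δβ-based differential methylation
position (DMP) calling, genomic-context distribution and chi-square
enrichment, a three-criterion promoter biomarker gene screen, and clinical
validation statistics (2^-ΔΔCt expression, gated correlations, ROC/AUC).
A synthetic data generator with complete truth tables makes every stage
testable offline — no array downloads or IDAT decoding required.

## What it does

1. **`manifest_io`** — probe annotation (gene/region mappings, island
   relation, QC flags), β/detection-P/bead-count matrices, sample sheets,
   BED6 export. Accepts semicolon-delimited parallel gene/region lists and
   pre-exploded long-format manifests.
2. **`qc_filter`** — ordered exclusion cascade: detection P ≥ 0.01 in any
   sample; fewer than 3 beads in ≥ 5% of samples; non-CpG probes;
   SNP-associated/cross-reactive probes; X/Y probes. Removals are attributed
   to the first stage that hits them and reported per stage.
3. **`dmp_analysis`** — group means and Δβ (case − control), Welch t or
   empirical-Bayes moderated t, Benjamini–Hochberg adjustment, DMP calling
   at adjusted P < 0.05 and |Δβ| > 0.1 (both strict), PCA embedding, pooled
   region-level methylation comparison.
4. **`genomic_distribution`** — gene-region / island-relation / chromosome
   distribution tables, island classification from interval geometry
   (shore 0–2 kb, shelf 2–4 kb), Pearson chi-square enrichment between probe
   sets (no continuity correction; Fisher fallback flagged when expected
   counts drop below 5), per-chromosome DMP/gene tallies.
5. **`biomarker_screen`** — cascade: promoter location (TSS1500, TSS200,
   5'UTR, 1stExon) → extreme case-group mean β (< 0.3 or > 0.7) → genes with
   ≥ 3 surviving DMPs; per-stage counts recorded.
6. **`clinical_stats`** — 2^-ΔΔCt relative expression calibrated to the
   control-group mean ΔCt, Lilliefors-gated t / Mann–Whitney comparison,
   Pearson/Spearman correlation with the same gate, empirical ROC with
   trapezoid AUC and Youden cutoff, mean-β (or PC1) composite scores,
   DMP × phenotype correlation grids.
7. **`synthetic_data`** — seeded generator for manifest + cohort: bimodal
   Beta-mixture probe means with logit-normal sample noise, planted Δβ
   effects, planted QC failures for every filter stage, and one promoter
   biomarker gene whose methylation anti-correlates with expression and TSH.
   Returns a `PlantedTruth` for exact recovery scoring.

## CLI

```bash
methylscreen simulate --seed 17 --out-dir run/           # synthetic cohort + truth
methylscreen filter --beta run/beta.tsv --manifest run/manifest.tsv \
    --detp run/detp.tsv --beads run/beads.tsv --out-dir run/flt
methylscreen dmp --beta run/flt/beta_retained.tsv --manifest run/manifest.tsv \
    --samples run/samples.csv --alpha 0.05 --delta 0.1 --out-dir run/dmp
methylscreen distribution --dmps run/dmp/dmps.tsv --manifest run/manifest.tsv \
    --background background.txt --out-dir run/dist
methylscreen screen --dmps run/dmp/dmps.tsv --manifest run/manifest.tsv \
    --beta-lo 0.3 --beta-hi 0.7 --min-dmps 3 --out-dir run/scr
methylscreen clinical --beta run/beta.tsv --manifest run/manifest.tsv \
    --samples run/samples.csv --gene-dmps ids.txt --out-dir run/clin
methylscreen run-all --seed 17 --out-dir run/all         # full pipeline + report.json
```

`run-all` also accepts `--config run.yaml` (per-stage sections; unknown keys
rejected; flags override the file).

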