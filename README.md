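# lncsig

Call a core regulatory-T-cell lncRNA signature from RNA-seq counts and test
whether it is shaped by a transcription factor: positional classification of
the signature relative to protein-coding genes, ChIP-peak colocalization
enrichment, knockout-reversal analysis, cross-dataset fold-change concordance,
conserved-region scanning of pairwise alignments, and 2^-ddCT qPCR
quantification. A synthetic-data module plants every structure the analysis
assumes, so the whole pipeline runs offline with no downloads.

## Modules

| module | what it does |
| --- | --- |
| `lncsig.models` | domain types (genes, peaks, count matrices, alignments) and GTF/BED/TSV/FASTA I/O; internal coordinates are 0-based half-open |
| `lncsig.simulate` | seeded generators for annotations, peaks, NB counts, alignments and qPCR plates, with planted ground truth |
| `lncsig.diffexpr` | median-of-ratios size factors, moment-based NB dispersion, Wald test, BH adjustment, FPKM, expressed filter |
| `lncsig.signature` | up/down/non-differential signature calling, summary, sense/antisense/lincRNA classification, positional enrichment |
| `lncsig.coloc` | promoter/gene-body peak flags, Fisher's exact test, core-vs-background peak enrichment |
| `lncsig.dependence` | knockout reversal flags/report, Mann-Whitney U (exact for small samples), cross-dataset concordance |
| `lncsig.conservation` | sliding-window conserved-region detection (>100 bp, >70% identity by default) |
| `lncsig.qpcr` | CT tables, delta-CT with multi-reference normalization, 2^-ddCT folds, knockout absence check |
| `lncsig.pipeline` | end-to-end orchestration with per-stage seeding and JSON/TSV artifacts |

## CLI

Everything is reachable through the `lncsig` command:

```bash
# full simulated run: simulate -> DE -> signature -> classify -> coloc ->
# reversal -> concordance -> report.json
lncsig run --seed 1 --out runs/demo

# or stage by stage
lncsig simulate --seed 1 --out data/
lncsig de --counts data/counts.tsv --sample-conditions data/conditions.tsv \
          --conditions naive,treg_wt --out de.tsv
lncsig signature --de de.tsv --alpha 0.05 --out sig.tsv
lncsig classify --gtf data/annotation.gtf --out classes.tsv
lncsig coloc --gtf data/annotation.gtf --peaks data/peaks.bed --sig sig.tsv \
             --promoter-up 2000 --promoter-down 500 --out coloc.json
lncsig de --counts data/counts.tsv --sample-conditions data/conditions.tsv \
          --conditions treg_wt,treg_kiko --out ko.tsv
lncsig reversal --sig sig.tsv --ko-de ko.tsv --lfc-threshold 0.5 --out rev.json
lncsig ecr --aln pair.afa --min-len 100 --min-id 0.70 --out ecr.tsv
lncsig qpcr --ct plate.tsv --refs ref1,ref2 --calibrator WT --target mygene \
            --out rel.tsv
```

`lncsig run` accepts a flat JSON config (`--config cfg.json`) whose keys are
the fields of `SimConfig` and `PipelineConfig`; unknown keys are rejected.
Exit codes: 0 ok, 2 validation error, 3 stage failure. Reruns with the same
seed produce byte-identical artifacts.

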