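# panelscope

Toolkit for the computational core of a targeted inherited-retinal-dystrophy
gene panel: reference-pool copy-number-loss calling on binned read depth,
VAF-based zygosity assignment, ACMG/AMP five-tier evidence combination,
panel QC metrics, analytical-validation statistics, and seeded synthetic-data
generators so the whole pipeline runs offline.

## Modules

| module | what it does |
|---|---|
| `panelscope.panel_model` | BED-backed panel model: gene-annotated target regions, 50-bp binning, the bundled 82-gene fixture |
| `panelscope.cnv_caller` | library-size + pool normalization to per-bin fold depth, z-scored loss calling, log2 ratio / copy-number estimation |
| `panelscope.variant_interpretation` | VCF ingest (AD/DP), ≥20× depth gate, VAF→zygosity, evidence-code combination into the five tiers, Summary/Sequencing reports |
| `panelscope.qc_metrics` | FASTQ Q20/Q30/GC, variant-window GC, coverage breadth at a depth threshold, GC-bin depth summaries |
| `panelscope.validation_stats` | Clopper–Pearson exact CIs, PPA/NPA concordance, zygosity concordance, replicate-design precision, detection rates |
| `panelscope.synthetic_data` | seeded negative-binomial depth simulator with unimodal GC bias, planted deletions, reference pools, replicate VCF cohorts |
| `panelscope.cli` | `panelscope` command with `simulate / qc / callcnv / interpret / validate / run-all` |

## CLI

```bash
# end-to-end demo on simulated data (pool + sample with 5 planted deletions)
panelscope run-all --seed 7 --out demo/

# individual stages
panelscope simulate --seed 7 --out sim/
panelscope callcnv --sample sim/sample.depth.tsv --pool sim/pool/ --sex female --out cnv/
panelscope interpret --vcf sim/sample.vcf --evidence ev.json --sex female --out reports/
panelscope qc --depth sim/sample.depth.tsv --out qc.json
panelscope validate --tp 43 --fp 0 --fn 0 --tn 4281
```

Depth input is a per-base TSV `(chrom, pos[1-based], depth)`; a reference pool
is a directory of such TSVs with an optional `manifest.tsv` (filename,
sample_id, sex). CNV events are reported as JSON (0-based, with the per-bin
fold/z audit track), TSV (1-based inclusive) and BED.

## Bundled fixture

`src/panelscope/data/ird_panel.bed` is an 82-gene panel with synthetic but
deterministic exon coordinates (regenerate via `python scripts/make_fixture.py`).
Gene symbols and the exon-count structure relevant to validation (e.g., the
153/90-base exon pair, 14-exon gene targets, an intronic target, a 1,706-base
low-complexity terminal-exon target, six X-linked genes) are preserved; genomic
coordinates are not real.
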