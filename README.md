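# senespread

Quantification toolkit for histone-mark redistribution between two cell
states (e.g. early-passage quiescent vs. senescent fibroblasts): TSS-window
and gene-body mark densities, metagene spreading profiles, Pol II pausing
indices, combined RNA/nascent-transcription regulation calls,
gene-length-stratified fold-change analysis, and gene-set overlap statistics
— together with a synthetic-data generator that plants each of these effects
for end-to-end validation.

## Layout

| module | role |
| --- | --- |
| `senespread.genome_io` | gene models (BED12/GTF), coverage tracks (bedGraph), strand-aware window resolution |
| `senespread.synthetic_data` | planted-effect generator: gene models, two-condition mark tracks, RNA/GRO-like count tables, ground truth |
| `senespread.coverage_quant` | window densities, TSS profiles, scaled-body metagene profiles, sorted profile matrices |
| `senespread.transcription_analysis` | log2 fold changes, S_GAINED/S_LOST classification, length stratification, pausing indices and PI curves |
| `senespread.mark_dynamics` | promoter/body mark change, mark-defined gene selection, mark-vs-expression association, spreading summaries |
| `senespread.set_stats` | Welch z-test, Mann–Whitney U (exact + asymptotic), Fisher overlap with Jaccard, boxplot summaries, BH |
| `senespread.pipeline` / `senespread.cli` | YAML-config orchestration with manifest + deterministic outputs |

Conventions: all coordinates are 0-based half-open; the TSS of a minus-strand
gene is its half-open right edge and windows are expressed in transcribed
orientation; densities are tags per kb per 10 million library tags;
overlapping bedGraph intervals are merged by summation.

## CLI

```bash
senespread run --config config.yaml            # full pipeline
senespread run --config config.yaml --stages quantify,classify
senespread simulate --config config.yaml --out dataset/
senespread profile --track mark.bedGraph --genes genes.bed --mode metagene --out prof.tsv
senespread pause --track gro.bedGraph --genes genes.bed --out pausing.tsv
senespread markshift --track-a epq.bedGraph --track-b sen.bedGraph \
    --genes genes.bed --region tss:-300..200 --threshold -2.5 --out mc.tsv
senespread enrich --set-a a.txt --set-b b.txt --universe u.txt --out enr.tsv
```

Exit codes: 0 success, 1 validation problem, 2 runtime failure.  A run
directory contains every stage table (TSV), `manifest.json` (config echo,
output hashes, exclusion counts) and `run.log`; two runs with the same config
and seed produce byte-identical tables.

Minimal config:

```yaml
output_dir: out
seed: 1
synthetic:
  n_genes: 500
  depth: 1.0e6
  expr_effect: 2.0
  mark_loss_coupling: -5.0
  mark_shapes:
    h4r3me2s/epq: {promoter_amplitude: 10, promoter_width_bp: 150, body_level: 0.1}
    h4r3me2s/sen: {promoter_amplitude: 10, promoter_width_bp: 150, body_level: 0.1}
    gro/epq: {promoter_amplitude: 3, body_level: 1.0}
    gro/sen: {promoter_amplitude: 3, body_level: 1.0}
up_thresh: 1.0
down_thresh: -1.0
mark_loss_threshold: -2.5
length_edges: [10000, 30000, 100000]
```

Real data can be supplied instead of `synthetic:` via
`inputs: {genes: genes.bed, rna_counts: rna.tsv, gro_counts: gro.tsv,
tracks: {mark_epq: a.bedGraph, mark_sen: b.bedGraph}}`.

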