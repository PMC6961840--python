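# junctiondb

Build concise, tissue-specific protein FASTA databases from alternative-splicing
junctions. `junctiondb` consumes rMATS event tables (SE, MXE, A3SS, A5SS, RI)
together with a genome FASTA, an Ensembl-dialect GTF and a canonical proteome
FASTA, and emits a searchable target database of translated junction pairs plus
an optional reversed-decoy companion.

The build applies, in order:

1. **Read-count thresholding** — a two-component Gaussian mixture is fitted to
   `log2(count+1)`-transformed minimum-replicate skipped-junction counts; the
   threshold is the smallest integer count whose posterior probability of
   belonging to the highly expressed component reaches 0.95 (configurable, or
   overridden with `--theta`).
2. **Replicate-consistency filtering** — events whose rMATS p-value flags
   significantly differential usage (p ≤ 0.01 by default) are removed; missing
   p-values pass.
3. **Slice extraction** — each event resolves to two nucleotide slices
   (upstream exon + alternative exon(s) + downstream exon vs. the skipped
   alternative), strand-corrected and trimmed to annotated coding bounds.
4. **Four-tier single-frame translation** — annotated frame without
   frameshift/PTC (tier 1); frameshifted but PTC-free (tier 2); one common
   alternative frame (tier 3); exactly one PTC-bearing slice, truncated at the
   stop (tier 4).
5. **10-aa overhang stitching** — each translated slice is spliced into its
   canonical protein by exact terminal 10-mer matching; unstitchable orphans
   are discarded (and logged), duplicates merged, canonical-identical entries
   flagged.

## CLI

Generate a self-consistent toy bundle (genome + GTF + proteome + rMATS tables
with a ground-truth manifest), then build a database from it:

```bash
junctiondb fixture --n 14 --seed 7 --out fixture/
junctiondb build \
    --rmats-dir fixture/ \
    --genome fixture/genome.fa \
    --gtf fixture/annotation.gtf \
    --canonical fixture/proteome.fasta \
    --out build/ \
    --theta 4 --decoys
```

Useful `build` options: `--posterior-cutoff 0.95`, `--p-cutoff 0.01`,
`--overhang 10`, `--types SE,MXE,A3SS,A5SS,RI`, `--seed S`, and
`--config FILE` (flat `key = value` overrides). Outputs in `--out`:
`database.fasta` (+ `database.fasta.decoy.fasta` with `--decoys`),
`threshold.txt`, `rejects.tsv` (every discarded record with its reason) and
`summary.tsv` (per-stage counts).

`junctiondb fixture --worked-example --out dir/` emits the single-gene MYBPC3
exon-skip bundle used by the acceptance suite.

## Package layout

```
src/junctiondb/
  rmats_io.py            rMATS JC table parsing + event/count model
  junction_filter.py     mixture-model threshold + consistency filter
  sequence_retrieval.py  genome slices, GTF frame/phase recovery
  translation.py         codon translation + four-tier pair resolution
  stitching_db.py        overhang stitching, dedup, FASTA + decoy output
  fixtures.py            toy bundle generator with ground-truth manifest
  pipeline.py            end-to-end orchestration
  cli.py                 click entry points
```
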