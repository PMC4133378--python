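# epilandscape

Window-based chromatin-landscape analysis for plant-style methylomes:
weighted DNA methylation (CG / CHG / CHH) in 100 bp genome tiles, H3K9me2
ChIP read sums per tile, element-anchored metaprofiles, transposable-element
sub-family and flank summaries, genic-TE cataloging, and TSS chromatin-state
classification with expression cross-tabulation.  A fully parameterized
synthetic-data generator provides ground-truth datasets for every stage.

## Layout

| module | purpose |
| --- | --- |
| `epilandscape.genome_model` | domain types + plain-text I/O (cytosine report, GFF3, BED, expression TSV); all coordinates 0-based half-open internally |
| `epilandscape.windows` | genome tiling, weighted methylation per context, ChIP window sums, mean+k·sd significance thresholds, tile-level distributions, window location labels |
| `epilandscape.profiles` | relative (scaled-element, 60-bin) and absolute (TSS/TTS, 100-bin) metaprofiles, with TE masking and metadata grouping |
| `epilandscape.features` | TE sub-family chromatin summaries, 900–1000 bp flank bands, nearest-gene distances, genic-TE (>1 kb in introns) catalog, TE-class enrichment |
| `epilandscape.classify` | CHG×CHH → ChIP 10×9 heatmap, high-CHG / high-K9 TSS gene sets (data-derived cutoffs), RPKM, five-category expression grouping, crosstabs |
| `epilandscape.synthdata` | synthetic genome / methylome / ChIP / expression generator with a planted-truth manifest |
| `epilandscape.cli` | `epilandscape` command-line entry point |

## CLI

Generate a synthetic dataset and run the whole pipeline:

```sh
epilandscape simulate --seed 7 -o sim/
epilandscape all \
    --cytosines sim/cytosines.tsv --chip sim/chip.bed \
    --genes sim/genes.gff3 --tes sim/tes.bed --expr sim/expression.tsv \
    -o out/ --mask-genic-tes --plots
```

`out/` then contains the window table, per-context tile-level
distributions, the CHG×CHH heatmap, relative/absolute profile tables
(plus masked variants), sub-family and genic-TE summaries, TSS gene
lists, the expression crosstab and a run log reporting the realized
data-derived cutoffs (e.g. the genome's top-decile CHG boundary).

Stages can also run separately and chain through the window table:
`epilandscape windows` → `profiles` / `te-summary` / `classify`.
All defaults match the standard analysis parameters (100 bp windows,
1000 bp flanks, 2 kb/3 kb absolute extents, 900–1000 bp flank bands,
>1000 bp genic-TE threshold, 1 / 2 SD ChIP cutoffs, 0.90 CHG quantile).

Simulation parameters can be overridden with a YAML config
(`epilandscape simulate --config sim.yaml`); keys mirror
`epilandscape.synthdata.SimConfig`.

## Input formats

* cytosine report: TSV of `chrom, 1-based pos, strand, n_meth, n_unmeth,
  context, trinucleotide` (Bismark-style per-cytosine output)
* genes/exons: GFF3 (`gene` + `exon` with `Parent`; optional
  `gene_set` / `synteny` / `subgenome` attributes)
* TEs: BED6+2 (`name, score, strand, subfamily_code, spreading_class`)
* ChIP reads: BED3+
* expression: TSV `gene_id, rep1..repN, length` (or a `rpkm` column)

All readers accept gzip-compressed files.

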