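# srnapipe

A small RNA-seq analysis pipeline for comparing two sequencing libraries
(a control and a knockdown), covering the full path from raw reads to
annotated differential miRNA expression:

- **preprocess** — FASTQ cleaning (3' adapter trimming by longest exact
  overlap, mean-quality filter, 18–30 nt retention, adaptor-dimer
  removal), collapsing reads into unique tags with counts, and library
  composition summaries (length distribution, base bias, inter-library
  overlap).
- **annotate** — exact genome mapping on both strands and single-category
  annotation under a fixed priority rule
  (rRNA-class ncRNA with GenBank > Rfam, then known miRNA > repeat >
  exon > intron, sense/antisense split for exon/intron), plus the
  40 %-rRNA sample quality mark and per-miRNA quantification against a
  precursor/mature reference.
- **novel** — novel miRNA candidate calling: candidate precursor windows
  around unannotated mapped tags are folded with a nearest-neighbor
  minimum-free-energy dynamic program (Watson–Crick + G:U pairs, stacking
  energies, linear loop penalties, exact for its bundled energy model) and
  filtered on MFE < −20 kcal/mol, arm placement of the mature tag on the
  hairpin stem, and ≥ 1 TPM expression in both libraries.
- **diffexpr** — TPM normalization, an exact conditional two-library test
  (binomial, minimum-likelihood two-sided), Benjamini–Hochberg adjustment,
  and up/down classification at a fold-change and adjusted-P threshold.
- **targets** — miRNA:target duplex hybridization energies by an
  intermolecular-only dynamic program with extreme-value p-values, and
  per-gene aggregation keeping genes targeted by more than 3 up- or
  down-regulated miRNAs.
- **enrich** — upper-tail hypergeometric term enrichment with Bonferroni
  (or BH) correction.
- **synthdata** — a fully seeded synthetic data generator (genome with
  planted miRNA precursors, novel hairpins, ncRNA/repeat/exon/intron
  background, adapter-ligated FASTQ libraries with planted fold changes
  and a ground-truth manifest) used throughout the test suite.
- **pipeline** — end-to-end orchestration with YAML config, persisted
  TSV/FASTA intermediates and a JSON report, plus a replay utility that
  re-applies the classification rule to bundled published DE tables.

## Command line

Every stage is exposed through one `srnapipe` entry point:

```bash
srnapipe simulate --seed 7 --outdir sim/            # synthetic dataset
srnapipe preprocess reads.fastq --adapter TGGAATTCTCGGGTGCCAAGG --out tags.tsv
srnapipe annotate tags.tsv --genome g.fa --ncrna nc.fa \
    --mirna-hairpin hp.fa --mirna-mature mat.fa --features f.gff3 --out cat.tsv
srnapipe diffexp counts.tsv --total-control N1 --total-knockdown N2 --out de.tsv
srnapipe denovo unannotated.tsv --genome g.fa --out novel.tsv
srnapipe targets --mature mat.fa --utr utr.fa --de-table de.tsv --out genes.tsv
srnapipe enrichment genes.txt --term-map terms.tsv --out enrich.tsv
srnapipe run-all --config run.yaml                  # everything in order
srnapipe replay --table known                       # bundled-table replay
```

`run-all` reads a YAML file whose keys mirror
`srnapipe.pipeline.RunConfig` (input paths plus stage parameters such as
`adapter`, `mfe_max`, `alpha_known`, `evd_location_slope`, ...).

## Notable conventions

- Sequences are stored internally as DNA (U↔T normalized at the edges);
  coordinates are 0-based half-open internally, GFF3 1-based inclusive on
  disk.
- The two-library test is an exact conditional binomial test (in the
  spirit of Audic–Claverie for unreplicated libraries); the fold-change
  floor for zero TPMs defaults to 0.01.
- The folding/duplex energy model is a deliberately small, fully
  documented nearest-neighbor parameter set bundled as data
  (`srnapipe._energy`); both dynamic programs are exact for that model and
  are verified against exhaustive enumeration in the test suite.
- Library-overlap percentages use the union of distinct sequences
  (unique) and the grand total of counts (total) as denominators.
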