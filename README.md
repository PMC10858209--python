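# mitocomp

Comparative analytics for annotated circular mitochondrial genomes
(teleost-style: 13 protein-coding genes, 22 tRNAs, 2 rRNAs, a control
region, and the OL/OH replication origins).

The package computes, per genome and across genome sets:

- **Composition & skew** — base counts/percentages and the strand-asymmetry
  statistics `AT-skew = (A−T)/(A+T)`, `GC-skew = (G−C)/(G+C)`, reported for
  the whole genome and per region class (PCG / rRNA / tRNA / control region).
- **Codon usage** — CDS extraction with strand resolution and
  origin-wrapping, start/stop calling including incomplete stops (`TA-`,
  `T--`) detected from length mod 3, codon counts, RSCU, synonymous-family
  degeneracy derived from the vertebrate mitochondrial code (translation
  table 2, with Leu1/Leu2 and Ser1/Ser2 split), and amino-acid composition.
- **Intergenic spacers & overlaps** — signed inter-feature distances
  (`start(next) − end(prev) − 1`) on the circle, including the wrap gap;
  per-genome summaries (count, total bp, longest spacer and its flanking
  pair, overlap census) and multi-genome comparison tables.
- **Control-region tandem repeats** — self-comparison scanner reporting
  motif, period, fractional copy number (e.g. "2.4 copies") and
  copy-to-copy identity; forward orientation only.
- **Gene order** — rotation-invariant signed gene orders anchored at trnF,
  duplication censuses, and pairwise breakpoint distances on shared
  single-copy genes.
- **Synthetic genomes** — a generator that realizes a full feature plan
  (lengths, strands, signed gaps, codon constraints, composition targets,
  planted control-region repeats, duplications) with machine-readable
  ground truth, so every pipeline stage is testable offline.

A coordinate fixture transcribing the *Boleophthalmus dussumieri*
mitogenome annotation (16,685 bp, 40 features) ships with the package
(`mitocomp/data/boleophthalmus_dussumieri.tsv`).

## CLI

```sh
mitocomp igs --table dussumieri --out igs.tsv      # spacer/overlap summary
mitocomp stats --input genome.gb --out stats.tsv   # composition & skew
mitocomp rscu --input genome.gb --out rscu.tsv     # codon usage
mitocomp repeats --input genome.gb                 # CR tandem repeats
mitocomp order --input a.gb --input b.gb           # gene orders + breakpoints
mitocomp compare --input a.gb --input b.gb --out reports/
mitocomp simulate --seed 7 --out family/ --members 3
```

Inputs may be GenBank flat files, FASTA, or plain feature tables
(TSV with `name  from  to  strand [type] [wraps]`; coordinates 1-based
inclusive; table inputs additionally need `--genome-length`/`--species`).
Table-only genomes run every coordinate-based stage; sequence-dependent
subcommands print a notice and skip them. Exit status is 0 on success and
2 on validation errors.

## Conventions

- Coordinates are 1-based inclusive (GenBank style) throughout; features on
  the light strand keep heavy-strand-frame coordinates.
- Region composition concatenates same-class features in genomic order read
  on the heavy strand (no reverse-complementing), so skew signs are
  comparable across genomes.
- The default spacer chain policy `exclude-container` drops a control-region
  umbrella feature that wholly contains another feature (keeping, e.g., an
  OH annotated inside the D-loop); `--policy keep-all` keeps everything.
- Gaps of exactly 0 are neither spacers nor overlaps.
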