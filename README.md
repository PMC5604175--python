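# zwmap

Sex-locus discovery toolkit for dioecious F1 crosses with a ZW
(female-heterogametic) system. The package implements, as reusable and
tested components, the analysis chain needed to map a sex-determining
locus from a cross between two heterozygous parents:

- **`zwmap.simpop`** — synthetic-data generator: two highly heterozygous
  parents (a ZW female carrying a female-specific W insertion flanked by
  configurable Z/W divergence, and a ZZ male), F1 progeny with labile ZW
  sex expression, phenotype-selected bulks, per-site pileups, shotgun
  reads, RAD tags, and a ground-truth table for scoring every downstream
  caller.
- **`zwmap.qtlseq`** — F1-adapted bulked-segregant SNP-index mapping:
  parent-substituted references, classification of parent-specific
  heterozygous sites (index 0.4–0.6 in one parent, 0 in the other,
  depth ≥ 16 in both), per-bulk SNP-index / ΔSNP-index (depth ≥ 6),
  1-Mb/50-kb sliding windows, simulation-based null confidence bands,
  and candidate-region calling.
- **`zwmap.wregion`** — W-linked region delineation: a combined
  dual-parent reference, an exact-seed + bounded-Hamming mini-mapper
  whose unique flag is the MAPQ-60 analog, per-base bulk-specific region
  extraction (≥ 90 % unique coverage, other-bulk depth ≤ 0), N-statistic
  size filtering, exact-match-chain anchoring onto pseudo-chromosomes,
  and the final W-interval call (optionally trimmed by a ZZ-selected
  bulk).
- **`zwmap.radmap`** — pseudo-testcross RAD linkage mapping: SNP- and
  presence/absence-type marker selection with exact binomial segregation
  filtering, two-point rf/LOD, rf-based scaffold splitting,
  repulsion-to-coupling conversion over a LOD 10→5→3 schedule,
  single-linkage grouping with greedy seriation, dual-map merging, and
  N-gapped pseudo-molecule construction with an AGP-style placement
  table.
- **`zwmap.gsize`** — genome-size estimators (k-mer coverage formulas
  and flow-cytometry peak ratios), assembly and GFF3 annotation summary
  statistics, and perfect-SSR scanning (motif 2–10 bp, ≥ 10 repeats,
  mononucleotide runs excluded).
- **`zwmap.sexmarker`** — in silico PCR and CAPS genotyping of
  sex-linked markers, dominant presence/absence ZW/ZZ inference, an
  exact two-sided Fisher test (integer arithmetic), and multi-season
  genotype/phenotype concordance reporting.

## Command line

```bash
zwmap simulate --config cfg.yaml --out sim/          # synthetic cross
zwmap qtlseq --female-bulk f.tsv --male-bulk m.tsv \
             --p3 p3.tsv --p4 p4.tsv --ref ref.fasta --out qtl/
zwmap wregion --asm-f p3.fasta --asm-m p4.fasta \
              --bulk-f f.fastq --bulk-m m.fastq --target chr.fasta --out w/
zwmap stats assembly asm.fasta
zwmap stats annotation genes.gff3 --fasta asm.fasta
zwmap stats ssr asm.fasta
zwmap stats gsize --kc 25.66 --rl 228.8 --k 25 --total-len 16771579510
zwmap marker pcr templates.fasta --forward ... --reverse ...
zwmap marker caps haplotypes.fasta --forward ... --reverse ... --enzyme EcoRI
zwmap marker concordance --calls calls.tsv --phenotypes phenos.tsv
```

Pileup tables are TSV (`chrom pos ref A C G T depth sample`, 0-based
positions); intervals are emitted as 0-based half-open BED.

## Conventions

Internal coordinates are 0-based half-open everywhere; sequence I/O is
FASTA/FASTQ via Biopython; randomness flows through
`numpy.random.Generator` seeded from a single config seed, and equal
seeds give byte-identical outputs.
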