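# archori

Rule-based prediction of replication origins (*oriC*s) in archaeal
genomes, for microbial genomicists annotating newly sequenced archaea and
for anyone studying archaeal replication initiation.

Archaeal *oriC*s share three hallmarks: they are intergenic regions lying
next to replication-initiation genes (Orc1/Cdc6, Whip, DNA primase); they
contain origin recognition boxes (ORBs), the conserved binding sites of
the Orc1/Cdc6 initiator; and they sit near extrema of the genome's
cumulative composition-disparity curves, because the two replichores
accumulate mirrored G−C and A−T skews. `archori` combines these signals:

* **Z-curve analysis** — cumulative walks x (R−Y), y (M−K), z (W−S) and
  the AT/GC disparity curves (x±y)/2; global and local extrema; rotation
  of a circular genome to its GC-disparity maximum.
* **ORB motif scanning** — eleven built-in ORB motifs organised by
  taxonomic cluster, scored as PSSM log-likelihood ratios in bits with
  *exact* p-values computed by dynamic programming over a discretised
  score lattice; default cutoff p ≤ 1e-4.
* **Replication-gene roles** — keyword classification of annotated gene
  products (Orc1/Cdc6 > Whip > primase > other replication proteins).
* **Repeat annotation** — maximal exact direct repeats and
  reverse-complement palindromes inside candidate regions.
* **Two decision rules** — Rule A: an intergenic region flanked by a
  replication-related gene and holding ≥1 ORB hit; Rule B: any
  intergenic region holding ≥3 ORB hits. Disparity-extremum proximity,
  AT content and repeats are reported as evidence, never used as gates.

A seeded synthetic-genome generator (two-replichore skew, tiled genes, an
Orc1/Cdc6 gene flanking a planted origin with ORB instances) makes every
stage testable without downloads, and an evaluation harness computes
sensitivity = TP/reference and precision = TP/predicted under one-to-one
greedy interval matching.

## Worked example

Simulate a 100 kb toy chromosome with a composition-skew switch and a
planted, Orc1/Cdc6-flanked origin at position 30,000, then predict:

```sh
$ archori simulate --length 100000 --origin 30000 --skew 0.08 --seed 11 --out-prefix toy
wrote toy.gbk/.fna/.ptt/.truth.tsv (origin at 30000)

$ archori predict --genbank toy.gbk --out run
accession          toy_00000011
genome size        100000 bp
GC content         49.99%
replication genes  1
  toy_orc  28801..30000 (+) orc1_cdc6: orc1/cdc6 replication initiation protein
predicted oriCs    1
  oriC_1  30001..30496  rule=gene_adjacent_orb  ORB hits=1  AT=52.2%
```

The single prediction is the intergenic region right of the `toy_orc`
gene (1-based 30001..30496), called by Rule A: it is flanked by an
orc1_cdc6-classified gene and contains one ORB hit. `run/orb_hits.tsv`
shows that hit — the planted Common-motif ORB:

```
motif   start  end    strand  score_bits  p_value    sequence
Common  30020  30040  +       35.593      1.455e-11  TCCACTTGAAATGAAGGGGT
```

`run/predictions.tsv` carries the full evidence bundle per call (rule,
motif count, flanking gene and role, AT content, signed distance to the
nearest disparity-curve extremum, repeat count); `run/predictions.bed`
and `run/predictions.gff3` give the same intervals in standard formats,
`run/zcurve.tsv` the disparity curves, and `--plot` adds a four-panel
disparity figure with gene ticks and prediction arrows. For real genomes
pass an annotated GenBank file (`--genbank`) or FASTA plus NCBI protein
table (`--fasta`/`--ptt`); `--reference origins.bed` additionally writes
sensitivity/precision against a reference interval set.

Other subcommands: `archori scan` (ORB scanner on any sequence),
`archori zcurve` (curve export), `archori evaluate` (interval-set
scoring), `archori motifs` (export the motif set in MEME format).

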