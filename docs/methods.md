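# Methods

`archori` predicts replication origins (*oriC*s) in archaeal genomes. The
biological premises are the three regularities of known archaeal origins:
they lie in intergenic regions next to replication-initiation genes
(Orc1/Cdc6, Whip, DNA primase), they carry conserved origin recognition
boxes (ORBs, the Orc1/Cdc6 binding sites), and they sit near extrema of
the genome's cumulative base-composition disparity curves, because the two
replichores replicate on opposite strands and accumulate mirrored
G-over-C and A-over-T skews.

## The decision procedure

The predictor is deliberately rule-based, not probabilistic. On an
annotated circular chromosome it

1. extracts every maximal intergenic gap of at least `min_intergenic`
   (default 50 bp — shorter gaps cannot hold a ~17–21 bp ORB), merging
   overlapping genes first and including the wrap-around gap;
2. scans each gap with the ORB motif set at a PSSM p-value cutoff of
   1e-4;
3. fires **Rule A** (`gene_adjacent_orb`) when a gap both flanks a
   replication-related gene and holds ≥1 ORB hit, and **Rule B**
   (`multi_motif`) when a gap holds ≥3 ORB hits regardless of its
   neighbours (Rule B exists because species-specific initiation genes
   may be unannotated or unrecognised);
4. attaches evidence to each call: all motif hits, flanking roles, AT
   content, internal exact repeats/palindromes, and the signed circular
   distance from the region midpoint to the global extremum of each
   disparity curve.

The disparity-curve proximity is *evidence only*, never a gate. Gating on
curve extrema would suppress secondary origins in multi-origin genomes
(common in archaea), which is precisely where sensitivity is hardest;
users who want the classical single-origin heuristic can read the
`distance_to_extremum` column and filter. The AT content and repeat
annotations are likewise descriptive: AT-rich unwinding elements and
ORB-flanking G-stretches characterise origins but do not separate them
cleanly from other intergenic sequence.

"Adjacent" means the two genes immediately flanking the gap — the
strictest reading; a region satisfying both rules is reported once,
under Rule A. Rule B's threshold of three follows the best-documented
multi-motif origin call in the benchmark literature (an origin carrying
three ORB motifs next to genes not then known as replication-related).

## Z-curve and disparity curves

A sequence is reduced to three cumulative integer walks: x (purines −
pyrimidines), y (amino − keto) and z (weak − strong H-bonding). The AT
disparity (x+y)/2 counts cumulative A−T excess and the GC disparity
(x−y)/2 the G−C excess. Disparities are half-integers; they are kept
doubled internally so every extremum comparison is exact integer
arithmetic, with ties broken toward the smaller coordinate. Ambiguous
IUPAC bases contribute zero steps. The z component is computed as W−S,
the standard orientation in the Z-curve literature; it is reported but
not used by the predictor.

`find_extrema` reports a curve as *flat* when its total range does not
exceed `flat_threshold` (default 0, i.e. a truly constant curve, e.g. an
all-N sequence). A finite unbiased sequence still produces a random walk,
so "no significant skew" is a statistical statement, not an exact one;
callers testing for absence of drift should pass a null-calibrated
threshold such as 4·sqrt(var·n) (the doubled-GC walk has per-step
variance 2 under equal base frequencies, and a genuine replichore skew
of strength δ produces a drift amplitude of ~2δn, two orders of
magnitude larger at genomic scale).

Local-extremum listing uses peak prominence on a curve decimated to
~5,000 points; origin-scale skew features span many kilobases, and
prominence computation on a raw 100 kb integer walk costs minutes for no
extra information. Global extrema are always taken on the full-resolution
curve. Default smoothing is none below 1 Mb (cumulative curves are
already integrals and stable), n/1000 above.

## ORB motifs and scanning

Eleven ORB motifs are built in, organised by taxonomic cluster
(Halobacteriaceae, Methanobacteriaceae, Methanomicrobia,
Methanococcaceae, Sulfolobaceae ×3, Thermococcaceae ×3, plus a Common
motif derived from all clusters). Each is published only as a degenerate
bracket-notation consensus, so the position-specific probability matrix
is derived: at each position the unlisted bases get pseudocount ε = 0.005
and the k listed alternatives share (1 − u·ε)/k uniformly (u = number of
unlisted bases). This is a declared approximation — the original
MEME-derived matrices are no longer obtainable — with the property that
every string matching the consensus scores identically and far above the
scan threshold. The set ships as a MEME minimal-format resource
(`archori/data/orb_motifs.meme`) consumable by MEME-suite tools.

Scanning scores every window on both strands with the log-likelihood
ratio in bits, Σᵢ log₂(p(i, bᵢ)/q(bᵢ)), against a uniform background by
default (a genome-composition background is available but makes results
dataset-dependent). P-values are exact under the background model:
per-position scores are discretised to 1/1000-bit bins and the null
distribution of the window score is computed by dynamic programming over
the lattice — the same construction FIMO-class scanners use. Observed
window scores are integerised on the same lattice, so hit p-values are
exact for the discretised model rather than approximations; a test
verifies bin-level equality against exhaustive enumeration of all 4^w
windows for w ≤ 6. Windows containing any non-ACGT base are unscorable
and skipped whole. Overlapping hits are all retained; the default cutoff
is p ≤ 1e-4. Motif-set selection matches the genome's taxonomy lineage
against cluster names and always adds the Common motif; with no lineage
match only the Common motif is used.

## Repeats

Candidate regions are annotated with maximal exact direct repeats and
reverse-complement palindromes (minimum length 8 bp by default; regions
are short, and 8 bp keeps noise manageable in AT-rich origins). The
finder scans match-runs per diagonal (direct: positions i vs i+d) and
per anti-diagonal (palindromic: i vs the complement at c−i); each maximal
run is exactly one maximal repeat, which keeps the degenerate homopolymer
case linear per diagonal where seed-pair enumeration would be quadratic.
Correctness is checked against a quadratic all-pairs oracle in the test
suite. Low-complexity hits (one base ≥ 75%, or a two-letter alphabet)
are flagged rather than removed, since G-stretches flanking ORBs are
biologically meaningful.

## Evaluation

`evaluate` matches predictions to reference intervals one-to-one,
greedily by decreasing overlap length, counting a reference as recovered
on ≥1 bp overlap (a midpoint-inside-reference alternative is provided;
the choice is configurable because published benchmark totals do not
state their matching criterion). Sensitivity is TP/reference count,
precision TP/prediction count, with precision flagged undefined when
nothing was predicted. Overlap is wrap-aware on circular coordinates.

## Synthetic genomes

The generator emulates exactly the origin features the predictor exploits
and nothing else. A 100 kb circular chromosome (default) gets a
two-replichore composition: on the arm running into the planted origin
P(G) = P(A) = 0.25 + δ and P(C) = P(T) = 0.25 − δ, mirrored on the other
arm, with δ = `skew_strength` (default 0.08, a mid-range archaeal skew);
the GC and AT disparity maxima therefore coincide with the origin, with
binomial noise ~sqrt(n/2) ≪ drift δ·n. Genes of 600–1500 bp with 80–300
bp gaps tile the rest of the circle (split at the coordinate origin so
every record survives flat-file round trips; the final span is closed
with one fitted gene so tiling artifacts never leave a large unannotated
gap). One 1200 bp Orc1/Cdc6-annotated gene sits immediately upstream of
a 400 bp origin region, into which the Common-motif consensus string is
planted verbatim (the maximum-probability string, a guaranteed scan hit).
All randomness flows through one seeded generator; identical specs give
byte-identical genomes.

The toys do **not** emulate codon structure, operons, RNA genes,
realistic intergenic composition, or multi-origin chromosomes — so
passing synthetic tests demonstrates the machinery (coordinates, rules,
scanning, recovery under noise), not field performance on real archaea,
where unknown initiation genes and divergent ORBs dominate the error
budget.

`rule_b_genome` builds the multi-motif test bed: no replication-annotated
gene anywhere and exactly *k* planted ORBs in the origin region. Because
a ~500 bp region has a ~10% chance of one background hit at p ≤ 1e-4,
the generator scrubs chance hits (deterministically mutating bases of
the offending window outside every planted word, rescanning until only
planted hits remain) — "exactly k hits" is part of the fixture's
definition.

## Numerical and degenerate-input choices

* Coordinates are 0-based half-open on the forward strand everywhere
  internally; GenBank/PTT/GFF3 writers and readers convert at the
  boundary; intervals may run past the coordinate origin (end > genome
  length) to represent wrap.
* Empty sequence → a valid single-entry Z-curve profile; empty reference
  set → evaluation error (sensitivity undefined); zero predictions →
  precision flagged undefined, not 0.
* p-value lookups clamp into the attainable lattice, so a score that
  rounds one bin past the DP maximum returns the smallest attainable
  p-value rather than 0.
* Score ties at the scan threshold are kept (p ≤ cutoff, inclusive).
* RNA genes count as genes for intergenic extraction by default
  (configurable off): a region between a tRNA and a CDS is not
  "intergenic" under the plain reading.

## Problem sizes in the shipped checks

The standard study condition for recovery statistics is 100 genomes of
100 kb at skew 0.08, one planted origin each; unit tests use 20 kb
genomes for speed. Enumeration oracles run at motif width 6 (4,096
windows) and repeat oracles at ≤ 200 bp, sizes where brute force is
exact and instant.

## Known limitations

* The PSPMs are consensus-derived stand-ins; scores are comparable
  within this package but not to FIMO runs with the original matrices.
* The replication-gene keyword table covers the families named in the
  origin literature plus conservative extensions; it is a sensitivity
  knob (`--role-table`) and certainly incomplete for real genomes.
* Single-replicon analysis only; no homology search against origin
  databases; no gene prediction for unannotated sequence (annotation is
  a required input).
* Rule B's hit count treats repeated hits of one motif the same as hits
  of distinct motifs.
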