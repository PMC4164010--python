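"""Seeded toy archaeal genomes with known ground truth.

The generator emulates the sequence features a single-origin circular
archaeal chromosome shows around its replication origin:

* a two-replichore base-composition skew — on the arm running into the
  origin G and A are in excess (P(G) = 0.25 + skew, P(C) = 0.25 − skew,
  likewise A/T), mirrored on the other arm, so the cumulative GC- and
  AT-disparity curves peak at the planted origin and trough at the
  antipodal terminus;
* protein-coding genes tiled around the chromosome with short intergenic
  gaps, one Orc1/Cdc6-annotated gene immediately upstream of a dedicated
  origin intergenic region;
* ORB consensus instances planted verbatim in chosen intergenic regions
  (the maximum-probability string of the motif, so a planted copy is a
  guaranteed PSSM hit at the default p-value cutoff).

Everything is drawn from one seeded generator stream, so identical specs
give byte-identical genomes.  What the toys do **not** emulate: codon
structure, operons, RNA genes, real intergenic composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .errors import ArchoriError
from .genome_io import AnnotatedGenome, GeneRecord, IntergenicRegion, \
    extract_intergenic, ptt_location
from .motif_scan import builtin_motifs


class GenerationError(ArchoriError):
    """The requested toy genome cannot be constructed (e.g. a motif would
    land inside a gene, or a planted region does not exist)."""


DEFAULT_ORC_PRODUCT = "orc1/cdc6 replication initiation protein"


@dataclass
class ToyGenomeSpec:
    """Construction parameters of one toy genome.

    Defaults describe the standard study condition: a 100 kb circular
    chromosome, composition skew 0.08, an Orc1/Cdc6 gene flanking a 400 bp
    origin region carrying one planted Common-motif ORB.
    """

    length: int = 100_000
    origin_position: int = 30_000
    skew_strength: float = 0.08
    n_genes: int = 90
    origin_region_length: int = 400
    origin_gene_length: int = 1200
    origin_gene_product: str = DEFAULT_ORC_PRODUCT
    #: (motif name, region key, copies); region key is "origin" or an index
    #: into the extracted intergenic-region list.
    planted_motifs: list = field(default_factory=lambda: [("Common", "origin", 1)])
    #: (gene placement index, product string) overrides.
    planted_role_products: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.origin_position < self.length):
            raise GenerationError("origin_position must lie inside the genome")
        if not (0.0 <= self.skew_strength <= 0.25):
            raise GenerationError("skew_strength must be in [0, 0.25]")


@dataclass
class ToyGroundTruth:
    """A generated genome plus the facts the generator knows about it."""

    genome: AnnotatedGenome
    true_origin_interval: tuple[int, int]
    planted_hit_positions: list[int]
    spec: ToyGenomeSpec


def _skewed_sequence(spec: ToyGenomeSpec, rng: np.random.Generator) -> np.ndarray:
    n, ori, delta = spec.length, spec.origin_position, spec.skew_strength
    # arm A: forward from origin to terminus (C/T rich); arm B: the rest
    p_arm_a = np.array([0.25 - delta, 0.25 + delta, 0.25 - delta, 0.25 + delta])
    p_arm_b = np.array([0.25 + delta, 0.25 - delta, 0.25 + delta, 0.25 - delta])
    alphabet = np.array(list("ACGT"))
    offsets = (np.arange(n) - ori) % n
    in_arm_a = offsets < n // 2
    seq = np.empty(n, dtype="<U1")
    seq[in_arm_a] = rng.choice(alphabet, size=int(in_arm_a.sum()), p=p_arm_a)
    seq[~in_arm_a] = rng.choice(alphabet, size=int((~in_arm_a).sum()), p=p_arm_b)
    return seq


def _tile_genes(spec: ToyGenomeSpec, rng: np.random.Generator) -> list[GeneRecord]:
    n, ori = spec.length, spec.origin_position
    genes: list[GeneRecord] = []
    orc_start = (ori - spec.origin_gene_length) % n
    genes.append(GeneRecord("toy_orc", orc_start, orc_start + spec.origin_gene_length,
                            "+", spec.origin_gene_product))
    # tile the rest of the circle between the origin region's right edge
    # and the Orc gene's left edge, in unwrapped coordinates
    cursor = ori + spec.origin_region_length
    stop = ori + n - spec.origin_gene_length
    placed = 0
    while placed < spec.n_genes:
        gap = int(rng.integers(80, 300))
        glen = int(rng.integers(600, 1500))
        if cursor + gap + glen > stop - 80:
            # close the remaining span with one fitted gene so no
            # multi-kb leftover gap survives next to the Orc gene
            glen = stop - 80 - (cursor + gap)
            if glen < 300:
                break
        start = cursor + gap
        if start < n <= start + glen:
            # never emit a gene wrapping the coordinate origin: cut it at
            # the origin so every record round-trips through flat files
            glen = n - start
            if glen < 300:
                cursor = n
                continue
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneRecord(f"toy_{placed:04d}", start % n,
                                start % n + glen, strand,
                                "hypothetical protein"))
        cursor = start + glen
        placed += 1
        if cursor + 380 > stop - 80:
            break
    for idx, product in spec.planted_role_products:
        if not (0 <= idx < len(genes)):
            raise GenerationError(f"no gene at placement index {idx}")
        genes[idx].product = product
    return genes


def make_toy_genome(spec: ToyGenomeSpec) -> ToyGroundTruth:
    """Build a toy genome and its ground truth from a spec (deterministic)."""
    rng = np.random.default_rng(spec.seed)
    seq = _skewed_sequence(spec, rng)
    genes = _tile_genes(spec, rng)
    genome = AnnotatedGenome("toy_%08d" % spec.seed, "".join(seq),
                             circular=True, genes=genes, taxonomy=[])

    regions = extract_intergenic(genome, min_len=50)
    origin_region = next(
        (r for r in regions if r.start == spec.origin_position), None)
    motif_by_name = {m.name: m for m in builtin_motifs()}
    planted: list[int] = []
    arr = np.array(list(genome.sequence), dtype="<U1")
    for name, key, copies in spec.planted_motifs:
        if name not in motif_by_name:
            raise GenerationError(f"unknown motif {name!r}")
        if key == "origin":
            region = origin_region
        else:
            region = regions[key] if 0 <= key < len(regions) else None
        if region is None:
            raise GenerationError(f"planting region {key!r} does not exist")
        word = motif_by_name[name].top_sequence()
        step = len(word) + 30
        if 20 + copies * step > region.length:
            raise GenerationError(
                f"{copies} copies of {name} do not fit region {key!r} "
                f"({region.length} bp)")
        for c in range(copies):
            off = 20 + c * step
            pos = (region.start + off) % genome.length
            if pos + len(word) > genome.length:
                raise GenerationError("planted motif would wrap the origin "
                                      "of coordinates")
            arr[pos: pos + len(word)] = list(word)
            planted.append(pos)
    genome = AnnotatedGenome(genome.accession, "".join(arr), True,
                             genes, taxonomy=[])
    ori_interval = (spec.origin_position,
                    spec.origin_position + spec.origin_region_length)
    return ToyGroundTruth(genome, ori_interval, planted, spec)


def rule_b_genome(copies: int, seed: int = 0) -> ToyGroundTruth:
    """A toy genome with *no* replication-annotated gene and **exactly**
    ``copies`` Common-motif ORB hits in the origin region (multi-motif
    rule test bed).

    Background sequence occasionally yields a chance ORB hit at the
    p ≤ 1e-4 cutoff (~1e-4 per window and strand); any such hit in the
    origin region would change the region's hit count, so chance hits are
    scrubbed by deterministically mutating one base of the offending
    window outside every planted word until only the planted hits remain.
    """
    from .motif_scan import PValueTable, scan, select_motifs

    spec = ToyGenomeSpec(
        origin_gene_product="hypothetical protein",
        planted_motifs=[("Common", "origin", copies)],
        seed=seed,
    )
    truth = make_toy_genome(spec)
    genome = truth.genome
    motif = select_motifs([])[0]  # the Common motif
    table = PValueTable(motif)
    width = motif.width
    planted = [(p, p + width) for p in truth.planted_hit_positions]
    rng = np.random.default_rng((seed * 2_654_435_761 + 12345) % (2 ** 31))
    for _ in range(100):
        region = next(r for r in extract_intergenic(genome, min_len=50)
                      if r.start == spec.origin_position)
        extra = [h for h in scan(motif, region, table=table)
                 if not any(s <= h.genome_position < e for s, e in planted)]
        if not extra:
            break
        arr = np.array(list(genome.sequence), dtype="<U1")
        for h in extra:
            free = [q for q in range(h.genome_position, h.genome_position + width)
                    if not any(s <= q < e for s, e in planted)]
            if not free:
                continue
            q = free[int(rng.integers(len(free)))]
            arr[q] = rng.choice([b for b in "ACGT" if b != arr[q]])
        genome = AnnotatedGenome(genome.accession, "".join(arr), True,
                                 genome.genes, taxonomy=[])
    else:
        raise GenerationError("could not scrub chance ORB hits from the "
                              "origin region")
    return ToyGroundTruth(genome, truth.true_origin_interval,
                          truth.planted_hit_positions, spec)


# ---------------------------------------------------------------------------
# writers


def _to_seqrecord(genome: AnnotatedGenome) -> SeqRecord:
    record = SeqRecord(Seq(genome.sequence), id=genome.accession,
                       name=genome.accession[:16], description="synthetic toy genome")
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = "circular" if genome.circular else "linear"
    record.annotations["taxonomy"] = list(genome.taxonomy)
    for g in genome.genes:
        loc = FeatureLocation(g.start, min(g.end, genome.length),
                              strand=1 if g.strand == "+" else -1)
        record.features.append(SeqFeature(loc, type=g.kind, qualifiers={
            "locus_tag": [g.identifier], "product": [g.product]}))
    return record


def write_genbank(genome: AnnotatedGenome, path) -> None:
    SeqIO.write(_to_seqrecord(genome), str(path), "genbank")


def write_fasta(genome: AnnotatedGenome, path) -> None:
    SeqIO.write(_to_seqrecord(genome), str(path), "fasta")


def write_ptt(genome: AnnotatedGenome, path) -> None:
    """Write the gene table in the legacy NCBI PTT layout."""
    with open(path, "w") as fh:
        fh.write(f"{genome.accession} - 0..{genome.length}\n")
        fh.write(f"{len(genome.genes)} proteins\n")
        fh.write("Location\tStrand\tLength\tPID\tGene\tSynonym\tCode\tCOG\tProduct\n")
        for g in genome.genes:
            aa = max((g.length // 3) - 1, 1)
            fh.write(f"{ptt_location(g)}\t{g.strand}\t{aa}\t-\t-\t"
                     f"{g.identifier}\t-\t-\t{g.product}\n")


def write_truth(truth: ToyGroundTruth, path) -> None:
    """TSV of the planted facts (origin interval, motif positions)."""
    with open(path, "w") as fh:
        fh.write("key\tvalue\n")
        fh.write(f"accession\t{truth.genome.accession}\n")
        fh.write(f"length\t{truth.genome.length}\n")
        fh.write(f"origin_start\t{truth.true_origin_interval[0]}\n")
        fh.write(f"origin_end\t{truth.true_origin_interval[1]}\n")
        fh.write(f"seed\t{truth.spec.seed}\n")
        for pos in truth.planted_hit_positions:
            fh.write(f"planted_motif_position\t{pos}\n")
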