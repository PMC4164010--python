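"""Read annotated archaeal genomes and extract intergenic regions.

Supported inputs are a single-record GenBank flat file, or a FASTA
nucleotide file paired with a legacy NCBI protein table (PTT).  All
coordinates are held internally as 0-based half-open intervals on the
forward strand; on a circular chromosome an interval may run past the
coordinate origin, in which case ``end`` exceeds the genome length and the
span wraps.  File writers and readers convert to/from the 1-based
inclusive convention of GenBank and PTT at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from Bio import SeqIO

from .errors import InputError, UsageError

logger = logging.getLogger(__name__)

#: gene roles assigned by :mod:`archori.gene_roles`
ROLE_NONE = "none"

_COMPLEMENT = str.maketrans("ACGTRYMKWSBDHVNacgtrymkwsbdhvn",
                            "TGCAYRKMWSVHDBNtgcayrkmwsvhdbn")


def revcomp(sequence: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC aware)."""
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass
class GeneRecord:
    """One annotated gene on the forward-strand coordinate system.

    ``start``/``end`` are 0-based half-open; for a gene wrapping the
    coordinate origin of a circular chromosome ``end`` may exceed the
    genome length.  ``role`` is filled by :func:`archori.gene_roles.annotate_roles`.
    """

    identifier: str
    start: int
    end: int
    strand: str
    product: str = ""
    role: str = ROLE_NONE
    kind: str = "CDS"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise UsageError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.end <= self.start:
            raise UsageError(f"gene {self.identifier}: end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AnnotatedGenome:
    """A circular (or linear) chromosome with its gene annotation."""

    accession: str
    sequence: str
    circular: bool = True
    genes: list[GeneRecord] = field(default_factory=list)
    taxonomy: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise InputError("genome sequence is empty")
        self.sequence = self.sequence.upper()
        self.genes.sort(key=lambda g: (g.start, g.end))

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def gc_content(self) -> float:
        s = self.sequence
        return (s.count("G") + s.count("C")) / len(s)

    def fetch(self, start: int, end: int) -> str:
        """Subsequence for a possibly wrapping half-open interval."""
        n = self.length
        span = end - start
        if span < 0 or span > n:
            raise UsageError(f"interval [{start}, {end}) does not fit the genome")
        start %= n
        end = start + span
        if end <= n:
            return self.sequence[start:end]
        return self.sequence[start:] + self.sequence[: end - n]


@dataclass
class IntergenicRegion:
    """A maximal gap between annotated genes on the chromosome.

    ``end`` may exceed the genome length for the wrap-around gap between
    the last and the first gene of a circular chromosome.
    """

    start: int
    end: int
    sequence: str
    left_gene: GeneRecord | None
    right_gene: GeneRecord | None
    genome_length: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start

    def midpoint(self) -> int:
        n = self.genome_length or self.end
        return ((self.start + self.end) // 2) % n


# ---------------------------------------------------------------------------
# readers


def read_genbank(path, include_rna_genes: bool = True) -> AnnotatedGenome:
    """Parse a single-record GenBank flat file into an :class:`AnnotatedGenome`.

    CDS features (plus tRNA/rRNA when ``include_rna_genes``) become
    :class:`GeneRecord` entries; GenBank's 1-based inclusive locations are
    converted to 0-based half-open.  Topology is read from the LOCUS line,
    defaulting to circular; the taxonomy comes from the ORGANISM lineage.
    """
    try:
        record = next(SeqIO.parse(str(path), "genbank"))
    except (StopIteration, ValueError, FileNotFoundError) as exc:
        raise InputError(f"cannot read GenBank file {path}: {exc}") from exc
    sequence = str(record.seq)
    if not sequence:
        raise InputError(f"GenBank record {record.id} carries no sequence")
    topology = record.annotations.get("topology", "circular")
    kinds = {"CDS", "tRNA", "rRNA"} if include_rna_genes else {"CDS"}
    genes: list[GeneRecord] = []
    n = len(sequence)
    for feat in record.features:
        if feat.type not in kinds:
            continue
        try:
            parts = sorted(feat.location.parts, key=lambda p: int(p.start))
            start = int(parts[0].start)
            end = int(parts[-1].end)
            strand = "-" if feat.location.strand == -1 else "+"
            if len(parts) == 2 and int(parts[-1].end) == n and int(parts[0].start) == 0:
                # join(x..n, 1..y): a gene wrapping the coordinate origin
                start = int(parts[-1].start)
                end = n + int(parts[0].end)
        except (TypeError, ValueError) as exc:
            logger.warning("skipping %s feature with unparseable location: %s",
                           feat.type, exc)
            continue
        if end <= start:  # zero-length or a multi-part join we cannot order
            logger.warning("skipping %s feature with void span %d..%d",
                           feat.type, start, end)
            continue
        quals = feat.qualifiers
        ident = (quals.get("locus_tag") or quals.get("gene") or ["?"])[0]
        product = (quals.get("product") or [""])[0]
        genes.append(GeneRecord(ident, start, end, strand, product, kind=feat.type))
    lineage = [t for t in record.annotations.get("taxonomy", []) if t]
    return AnnotatedGenome(
        accession=record.id or record.name,
        sequence=sequence,
        circular=(topology != "linear"),
        genes=genes,
        taxonomy=lineage,
    )


def read_fasta_ptt(fasta, ptt) -> AnnotatedGenome:
    """Parse a one-record FASTA plus its NCBI protein table (PTT).

    The PTT layout is two free-text header lines, a column-header line, then
    tab-separated rows with a 1-based inclusive ``a..b`` Location column.
    Rows with a malformed Location are skipped with a warning; a table with
    zero parsable rows is an input error.
    """
    try:
        record = next(SeqIO.parse(str(fasta), "fasta"))
    except (StopIteration, FileNotFoundError) as exc:
        raise InputError(f"cannot read FASTA file {fasta}: {exc}") from exc
    if len(record.seq) == 0:
        raise InputError(f"FASTA record {record.id} is empty")
    genes: list[GeneRecord] = []
    try:
        with open(ptt) as fh:
            lines = fh.read().splitlines()
    except OSError as exc:
        raise InputError(f"cannot read PTT file {ptt}: {exc}") from exc
    for line in lines[3:]:
        if not line.strip():
            continue
        cols = line.split("\t")
        try:
            lo, hi = cols[0].split("..")
            start, end = int(lo) - 1, int(hi)
            strand = cols[1].strip()
            if strand not in "+-" or end <= start:
                raise ValueError(cols[0])
        except (ValueError, IndexError):
            logger.warning("skipping PTT row with malformed location: %r", line)
            continue
        synonym = cols[5].strip() if len(cols) > 5 else "?"
        product = cols[8].strip() if len(cols) > 8 else ""
        genes.append(GeneRecord(synonym or "?", start, end, strand, product))
    if not genes:
        raise InputError(f"PTT file {ptt} contains no parsable gene rows")
    return AnnotatedGenome(
        accession=record.id,
        sequence=str(record.seq),
        circular=True,
        genes=genes,
        taxonomy=[],
    )


def ptt_location(gene: GeneRecord) -> str:
    """1-based inclusive ``a..b`` Location string for a gene record."""
    return f"{gene.start + 1}..{gene.end}"


# ---------------------------------------------------------------------------
# intergenic extraction


def _merged_spans(genome: AnnotatedGenome) -> list[tuple[int, int]]:
    """Merge (possibly overlapping/nested/wrapping) gene spans into disjoint
    covered intervals within [0, n), splitting wrapped genes at the origin."""
    n = genome.length
    raw: list[tuple[int, int]] = []
    for g in genome.genes:
        start, end = g.start % n, g.end
        end = start + min(g.length, n)
        if end <= n:
            raw.append((start, end))
        else:  # wraps the coordinate origin
            raw.append((start, n))
            raw.append((0, end - n))
    raw.sort()
    merged: list[tuple[int, int]] = []
    for s, e in raw:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    # merge across the origin on circular genomes
    if genome.circular and len(merged) > 1 and merged[0][0] == 0 and merged[-1][1] == n:
        first = merged.pop(0)
        merged[-1] = (merged[-1][0], n + first[1])
    return merged


def _flank(genome: AnnotatedGenome, boundary: int, side: str) -> GeneRecord | None:
    """The annotated gene whose span touches ``boundary`` on the given side."""
    n = genome.length
    best = None
    for g in genome.genes:
        if side == "left":
            d = (boundary - g.end) % n
        else:
            d = (g.start - boundary) % n
        if best is None or d < best[0]:
            best = (d, g)
    return best[1] if best else None


def extract_intergenic(genome: AnnotatedGenome, min_len: int = 50) -> list[IntergenicRegion]:
    """All maximal gaps of length >= ``min_len`` between annotated genes.

    Overlapping genes are merged into covered spans first.  On a circular
    chromosome the wrap-around gap between the last and the first gene is
    included (its ``end`` exceeds the genome length).  Each region carries
    its two immediately flanking genes.
    """
    if not genome.genes:
        raise UsageError("intergenic extraction requires an annotated genome")
    n = genome.length
    merged = _merged_spans(genome)
    if not merged:
        return []
    regions: list[IntergenicRegion] = []
    total = sum(min(e, n) - s if e <= n else (n - s) + (e - n) for s, e in merged)
    if total >= n:  # genes cover everything
        return []
    gaps: list[tuple[int, int]] = []
    for (s1, e1), (s2, e2) in zip(merged, merged[1:]):
        gaps.append((e1, s2))
    if genome.circular:
        last_end = merged[-1][1] % n
        first_start = merged[0][0]
        gaps.append((last_end, first_start + n if first_start <= last_end else first_start))
        # linear leading/trailing gaps folded into the wrap gap above
    else:
        if merged[0][0] > 0:
            gaps.insert(0, (0, merged[0][0]))
        if merged[-1][1] < n:
            gaps.append((merged[-1][1], n))
    for start, end in gaps:
        if end - start <= 0 or end - start < min_len:
            continue
        regions.append(IntergenicRegion(
            start=start,
            end=end,
            sequence=genome.fetch(start, end),
            left_gene=_flank(genome, start % n, "left"),
            right_gene=_flank(genome, end % n, "right"),
            genome_length=n,
        ))
    regions.sort(key=lambda r: r.start)
    return regions


def shift_genome(genome: AnnotatedGenome, offset: int) -> AnnotatedGenome:
    """Rotate a circular genome so old position ``offset`` becomes 0."""
    if not genome.circular:
        raise UsageError("cannot rotate a linear genome")
    n = genome.length
    offset %= n
    seq = genome.sequence[offset:] + genome.sequence[:offset]
    genes = [replace(g, start=(g.start - offset) % n,
                     end=(g.start - offset) % n + g.length)
             for g in genome.genes]
    return AnnotatedGenome(genome.accession, seq, genome.circular, genes,
                           list(genome.taxonomy))
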