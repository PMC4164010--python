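"""Genome readers, coordinate conventions and intergenic extraction."""

import numpy as np
import pytest

from archori.errors import InputError, UsageError
from archori.genome_io import (AnnotatedGenome, GeneRecord, extract_intergenic,
                               ptt_location, read_fasta_ptt, read_genbank,
                               revcomp)
from archori.synthetic import (ToyGenomeSpec, make_toy_genome, write_fasta,
                               write_genbank, write_ptt)

MINI_GENBANK = """\
LOCUS       TESTSEQ                  300 bp    DNA     circular BCT 01-JAN-2000
DEFINITION  two-gene fixture.
ACCESSION   TESTSEQ
VERSION     TESTSEQ.1
SOURCE      synthetic
  ORGANISM  synthetic
            Archaea; Euryarchaeota; Thermococcaceae.
FEATURES             Location/Qualifiers
     CDS             190..255
                     /locus_tag="g1"
                     /product="Cdc6-related protein"
     CDS             complement(10..30)
                     /locus_tag="g2"
                     /product="hypothetical protein"
ORIGIN
""" + "\n".join(
    f"{i * 60 + 1:>9} " + " ".join("acgtacgtag" for _ in range(6))
    for i in range(5)
) + "\n//\n"


def test_genbank_coordinate_conversion(tmp_path):
    """1-based inclusive GenBank locations become 0-based half-open."""
    path = tmp_path / "mini.gbk"
    path.write_text(MINI_GENBANK)
    genome = read_genbank(path)
    assert genome.length == 300
    assert genome.circular
    assert genome.taxonomy == ["Archaea", "Euryarchaeota", "Thermococcaceae"]
    by_id = {g.identifier: g for g in genome.genes}
    g1, g2 = by_id["g1"], by_id["g2"]
    assert (g1.start, g1.end, g1.strand) == (189, 255, "+")
    assert (g2.start, g2.end, g2.strand) == (9, 30, "-")
    assert g1.product == "Cdc6-related protein"


def test_genbank_unreadable_is_input_error(tmp_path):
    with pytest.raises(InputError):
        read_genbank(tmp_path / "missing.gbk")
    bad = tmp_path / "bad.gbk"
    bad.write_text("not a genbank file\n")
    with pytest.raises(InputError):
        read_genbank(bad)


def test_ptt_row_parsing(tmp_path):
    fasta = tmp_path / "g.fna"
    fasta.write_text(">acc test\n" + "ACGT" * 100 + "\n")
    ptt = tmp_path / "g.ptt"
    ptt.write_text(
        "acc - 0..400\n1 proteins\n"
        "Location\tStrand\tLength\tPID\tGene\tSynonym\tCode\tCOG\tProduct\n"
        "190..255\t+\t21\t-\t-\ttag1\t-\t-\tCdc6-related protein\n"
        "bogus..row\t+\t1\t-\t-\ttag2\t-\t-\tignored\n")
    genome = read_fasta_ptt(fasta, ptt)
    assert len(genome.genes) == 1  # malformed row skipped with a warning
    g = genome.genes[0]
    assert (g.start, g.end, g.strand) == (189, 255, "+")
    assert g.identifier == "tag1"
    assert g.product == "Cdc6-related protein"
    assert genome.taxonomy == []
    assert ptt_location(g) == "190..255"


def test_empty_ptt_is_input_error(tmp_path):
    fasta = tmp_path / "g.fna"
    fasta.write_text(">acc\nACGTACGTAC\n")
    ptt = tmp_path / "g.ptt"
    ptt.write_text("acc - 0..10\n0 proteins\n"
                   "Location\tStrand\tLength\tPID\tGene\tSynonym\tCode\tCOG\tProduct\n")
    with pytest.raises(InputError):
        read_fasta_ptt(fasta, ptt)


@pytest.mark.parametrize("fmt", ["genbank", "fasta_ptt"])
def test_writer_reader_round_trip(tmp_path, small_truth, fmt):
    """Synthetic genomes survive the write/read cycle with genes intact."""
    genome = small_truth.genome
    if fmt == "genbank":
        path = tmp_path / "toy.gbk"
        write_genbank(genome, path)
        back = read_genbank(path)
        assert back.circular
    else:
        write_fasta(genome, tmp_path / "toy.fna")
        write_ptt(genome, tmp_path / "toy.ptt")
        back = read_fasta_ptt(tmp_path / "toy.fna", tmp_path / "toy.ptt")
    assert back.sequence == genome.sequence
    assert len(back.genes) == len(genome.genes)
    for a, b in zip(back.genes, genome.genes):
        assert (a.start, a.end, a.strand, a.product) == \
            (b.start, b.end, b.strand, b.product)


def test_intergenic_no_gaps():
    genome = AnnotatedGenome("x", "ACGT" * 25, genes=[
        GeneRecord("a", 0, 60, "+"), GeneRecord("b", 50, 100, "-")])
    assert extract_intergenic(genome, min_len=0) == []


def test_intergenic_single_gene_wraps():
    """One gene [100,200) on a 1 kb circle leaves one 900 bp wrap gap."""
    seq = "AC" * 500
    genome = AnnotatedGenome("x", seq, genes=[GeneRecord("a", 100, 200, "+")])
    regions = extract_intergenic(genome, min_len=0)
    assert len(regions) == 1
    r = regions[0]
    assert (r.start, r.end) == (200, 1100)
    assert r.length == 900
    assert r.sequence == seq[200:] + seq[:100]
    assert r.left_gene.identifier == "a" and r.right_gene.identifier == "a"


def test_intergenic_min_len_threshold():
    genome = AnnotatedGenome("x", "A" * 1000, genes=[
        GeneRecord("a", 0, 400, "+"), GeneRecord("b", 430, 1000, "+")])
    gaps = [(r.start, r.end) for r in extract_intergenic(genome, min_len=50)]
    assert gaps == []  # the 30 bp gap is below threshold, no wrap gap exists
    gaps = [(r.start, r.end) for r in extract_intergenic(genome, min_len=10)]
    assert gaps == [(400, 430)]


def test_region_overlaps_no_gene(small_genome):
    spans = [(g.start, g.end) for g in small_genome.genes]
    n = small_genome.length
    for r in extract_intergenic(small_genome, min_len=0):
        for s, e in spans:
            # compare on the unrolled circle
            for shift in (-n, 0, n):
                assert not (r.start < e + shift and r.end > s + shift)


def test_tiling_property(rng):
    """Merged gene spans plus min_len=0 gaps tile the circle exactly once."""
    for _ in range(20):
        n = int(rng.integers(200, 2000))
        genes = []
        ngenes = int(rng.integers(1, 12))
        for i in range(ngenes):
            start = int(rng.integers(0, n))
            length = int(rng.integers(10, n // 2))
            genes.append(GeneRecord(f"g{i}", start, start + length, "+"))
        genome = AnnotatedGenome("x", "A" * n, genes=genes)
        covered = np.zeros(n, dtype=int)
        for g in genome.genes:
            for p in range(g.start, g.end):
                covered[p % n] += 1
        for r in extract_intergenic(genome, min_len=0):
            assert r.length == (r.end - r.start) % n or r.length == n
            for p in range(r.start, r.end):
                covered[p % n] += 1
        assert np.all(covered >= 1)
        # intergenic gaps never overlap genes, so gap positions count once
        gap_total = sum(r.length for r in extract_intergenic(genome, min_len=0))
        merged_total = int(np.count_nonzero(
            _covered_mask(genome)))
        assert gap_total + merged_total == n


def _covered_mask(genome):
    mask = np.zeros(genome.length, dtype=bool)
    for g in genome.genes:
        for p in range(g.start, g.end):
            mask[p % genome.length] = True
    return mask


def test_revcomp():
    assert revcomp("ACGT") == "ACGT"
    assert revcomp("AAGC") == "GCTT"
    assert revcomp("ANCG") == "CGNT"


def test_gene_record_validation():
    with pytest.raises(UsageError):
        GeneRecord("x", 10, 5, "+")
    with pytest.raises(UsageError):
        GeneRecord("x", 0, 5, "fwd")
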