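"""ORB motif set, PSSM scoring, exact p-values and scanning."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from archori.errors import UsageError
from archori.genome_io import revcomp
from archori.motif_scan import (DEFAULT_EPSILON, MotifModel, PValueTable,
                                SCORE_BIN_BITS, builtin_motifs,
                                builtin_motif_resource, match_regex,
                                parse_consensus, pspm_from_consensus,
                                pvalue_table, read_meme, scan, score_window,
                                select_motifs)

COMMON = "TCCA[CG]T[TG]GAAA[TC][GA]AAGGGGT"


def perfect_motif(word: str) -> MotifModel:
    """A zero-pseudocount motif that assigns probability 1 along ``word``."""
    pspm = np.zeros((len(word), 4))
    for i, b in enumerate(word):
        pspm[i, "ACGT".index(b)] = 1.0
    return MotifModel(word, "Common", "", pspm)


def test_builtin_set_shape():
    motifs = builtin_motifs()
    assert len(motifs) == 11
    by_name = {m.name: m for m in motifs}
    assert by_name["Common"].width == 20
    assert by_name["Common"].consensus == COMMON
    assert by_name["Methanococcaceae"].consensus == \
        "TT[TA][GT]ATTCA[TC][GA]AT[AT]T[AT]T[AT]"
    clusters = {m.taxonomy for m in motifs}
    assert clusters == {"Halobacteriaceae", "Methanobacteriaceae",
                        "Methanomicrobia", "Methanococcaceae",
                        "Sulfolobaceae", "Thermococcaceae", "Common"}
    for m in motifs:
        assert m.width == len(parse_consensus(m.consensus))
        np.testing.assert_allclose(m.pspm.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(m.pspm >= 0) and np.all(m.pspm <= 1)


def test_pspm_pseudocount_arithmetic():
    pspm = pspm_from_consensus("A[CG]")
    eps = DEFAULT_EPSILON
    np.testing.assert_allclose(pspm[0], [1 - 3 * eps, eps, eps, eps])
    np.testing.assert_allclose(
        pspm[1], [eps, (1 - 2 * eps) / 2, (1 - 2 * eps) / 2, eps])


def test_regex_match_forward():
    common = builtin_motifs()[-1]
    hits = match_regex(common, "TCCACTTGAAATGAAGGGGT")
    assert [(h.region_offset, h.strand) for h in hits] == [(0, "+")]
    assert hits[0].matched_sequence == "TCCACTTGAAATGAAGGGGT"
    assert hits[0].score is None and hits[0].p_value is None


def test_regex_match_reverse():
    common = builtin_motifs()[-1]
    hits = match_regex(common, revcomp("TCCACTTGAAATGAAGGGGT"))
    assert [(h.region_offset, h.strand) for h in hits] == [(0, "-")]
    assert hits[0].matched_sequence == "TCCACTTGAAATGAAGGGGT"


def test_regex_short_sequence_empty():
    for m in builtin_motifs():
        assert match_regex(m, "AAAA") == []


def test_score_window_pure_motif():
    m = perfect_motif("AA")
    assert score_window(m, "AA") == pytest.approx(4.0)  # 2·log2(1/0.25)
    assert score_window(m, "AC") == float("-inf")  # zero-probability base
    assert score_window(m, "AN") == float("-inf")  # ambiguity rule


def test_score_window_pseudocount():
    m = MotifModel("aa", "Common", "AA", pspm_from_consensus("AA"))
    eps = DEFAULT_EPSILON
    expected = math.log2((1 - 3 * eps) / 0.25) + math.log2(eps / 0.25)
    assert score_window(m, "AC") == pytest.approx(expected)


def test_score_window_length_mismatch():
    with pytest.raises(UsageError):
        score_window(perfect_motif("AA"), "AAA")


def test_pvalue_pure_motif():
    """Only AA attains the maximum among the 16 dinucleotides."""
    table = pvalue_table(perfect_motif("AA"))
    assert table.pvalue_bits(4.0) == pytest.approx(1 / 16)
    assert table.pvalue_bits(float("-inf")) == 1.0


def test_pvalue_minimum_score_is_one():
    for m in builtin_motifs()[:3]:
        table = pvalue_table(m)
        assert table.pvalue_int(table.min_sum) == pytest.approx(1.0)


def enumeration_lattice_pvalues(motif):
    """Brute-force oracle: integer-lattice scores of all 4^w windows under
    a uniform background, independent of the DP implementation."""
    llr = motif.llr_matrix()
    ints = np.round(llr / SCORE_BIN_BITS).astype(np.int64)
    totals = np.array([
        sum(ints[i, "ACGT".index(b)] for i, b in enumerate(word))
        for word in itertools.product("ACGT", repeat=motif.width)])
    return totals


@pytest.mark.parametrize("consensus", ["TCCA[CG]T", "A[CG][ACG]T[AT]A", "GGGGGG"])
def test_dp_matches_enumeration_synthetic(consensus):
    motif = MotifModel("syn", "Common", consensus,
                       pspm_from_consensus(consensus))
    table = pvalue_table(motif)
    totals = enumeration_lattice_pvalues(motif)
    for t in np.unique(totals):
        exact = float(np.mean(totals >= t))
        assert table.pvalue_int(int(t)) == pytest.approx(exact, abs=1e-9), consensus


def test_scan_finds_planted_consensus():
    common = builtin_motifs()[-1]
    word = common.top_sequence()
    seq = "ACGT" * 10 + word + "TTTT" * 10
    hits = scan(common, seq)
    assert any(h.region_offset == 40 and h.strand == "+" for h in hits)
    hit = [h for h in hits if h.region_offset == 40][0]
    assert hit.matched_sequence == word
    assert hit.p_value <= 1e-4
    assert hit.score == pytest.approx(score_window(common, word))


def test_scan_all_n_region_empty():
    common = builtin_motifs()[-1]
    assert scan(common, "N" * 100) == []


def test_scan_cutoff_monotonicity():
    common = builtin_motifs()[-1]
    rng = np.random.default_rng(3)
    seq = "".join(rng.choice(list("ACGT"), size=500)) + common.top_sequence()
    loose = scan(common, seq, p_cutoff=2e-4)
    tight = scan(common, seq, p_cutoff=1e-4)
    assert len(loose) >= len(tight)


def test_scan_bad_cutoff():
    with pytest.raises(UsageError):
        scan(builtin_motifs()[-1], "ACGT" * 30, p_cutoff=2.0)


@given(st.text(alphabet="ACGT", min_size=25, max_size=80))
def test_strand_symmetry(seq):
    """Scanning the reverse complement mirrors hit coordinates and strands."""
    common = builtin_motifs()[-1]
    table = PValueTable(common)
    fwd = scan(common, seq, table=table)
    rev = scan(common, revcomp(seq), table=table)
    n, w = len(seq), common.width
    mirrored = sorted((n - h.region_offset - w,
                       "+" if h.strand == "-" else "-") for h in rev)
    assert sorted((h.region_offset, h.strand) for h in fwd) == mirrored


def test_every_regex_match_is_pssm_hit():
    """Consensus instantiations always pass the p ≤ 1e-4 PSSM scan."""
    for motif in builtin_motifs():
        word = "".join(alts[-1] for alts in parse_consensus(motif.consensus))
        hits = scan(motif, "ACGTAC" + word + "GTACGT")
        assert any(h.region_offset == 6 and h.strand == "+" for h in hits), \
            motif.name


def test_meme_resource_matches_builtin():
    shipped = read_meme(builtin_motif_resource())
    motifs = builtin_motifs()
    assert [m.name for m in shipped] == [m.name for m in motifs]
    for a, b in zip(shipped, motifs):
        assert a.consensus == b.consensus
        np.testing.assert_allclose(a.pspm, b.pspm, atol=1e-6)


def test_select_motifs_by_lineage():
    names = {m.name for m in select_motifs(
        ["Archaea", "Euryarchaeota", "Thermococcaceae", "Pyrococcus"])}
    assert names == {"Thermococcaceae_1", "Thermococcaceae_2",
                     "Thermococcaceae_3", "Common"}
    assert {m.name for m in select_motifs([])} == {"Common"}
    assert {m.name for m in select_motifs(None)} == {"Common"}
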