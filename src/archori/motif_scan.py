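"""ORB motif models and intergenic-sequence scanning.

Archaeal replication origins carry origin recognition boxes (ORBs), the
binding sites of the Orc1/Cdc6 initiator.  This module ships a built-in
set of eleven ORB motifs organised by taxonomic cluster (Halobacteriaceae,
Methanobacteriaceae, Methanomicrobia, Methanococcaceae, Sulfolobaceae,
Thermococcaceae, plus one Common motif derived from all clusters), given
as degenerate consensus patterns in bracket notation, e.g.
``TCCA[CG]T[TG]GAAA[TC][GA]AAGGGGT``.

Two scanners are provided:

* :func:`match_regex` — literal degenerate-consensus matching on both
  strands (bracket positions are alternatives);
* :func:`scan` — position-specific scoring matrix (PSSM) scanning with a
  log-likelihood-ratio score in bits and an *exact* p-value under the
  background model, obtained by dynamic programming over a discretised
  score lattice (the approach FIMO-class scanners use).  The default
  p-value cutoff is 1e-4.

Because only the degenerate consensus of each motif is published, the
position-specific probability matrix is derived from it: each base absent
from a position receives pseudocount probability ``eps`` (default 0.005)
and the listed alternatives share the remainder uniformly.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .errors import UsageError
from .genome_io import IntergenicRegion, revcomp

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
DEFAULT_EPSILON = 0.005
DEFAULT_P_CUTOFF = 1e-4
SCORE_BIN_BITS = 1e-3  # p-value DP lattice resolution
_NEG_SENTINEL = -(10 ** 9)  # integer stand-in for an unscorable base

#: (name, taxonomic cluster, degenerate consensus) for the built-in ORB set.
ORB_CONSENSUS_TABLE: tuple[tuple[str, str, str], ...] = (
    ("Halobacteriaceae", "Halobacteriaceae", "TT[TC]CACC[GCT]GAAAC[GA][AC][GA]G[GT]G[GT]"),
    ("Methanobacteriaceae", "Methanobacteriaceae", "TT[TA]CACTTGAAAT[GTA]T[CT][CG]TC"),
    ("Methanomicrobia", "Methanomicrobia", "TCCA[GC]T[GT]GAAA[CT][AG]A[AT]GGGGT"),
    ("Methanococcaceae", "Methanococcaceae", "TT[TA][GT]ATTCA[TC][GA]AT[AT]T[AT]T[AT]"),
    ("Sulfolobaceae_1", "Sulfolobaceae", "[GC]GGCCGG[AG]A[GT][CT][GT]T[CG]A[CA]CC[TC]GG"),
    ("Sulfolobaceae_2", "Sulfolobaceae", "TCCA[AG][AT][TG]GAA[CA][CT][GA]AAGGGGT"),
    ("Sulfolobaceae_3", "Sulfolobaceae", "GAGTGC[GT]CGGTT[CGT]GCA[ATC]CC[AG]"),
    ("Thermococcaceae_1", "Thermococcaceae", "[TC]TCCAGTGGAAA[TC][GA]AA[AG]CTC"),
    ("Thermococcaceae_2", "Thermococcaceae", "[CAG]TTTCCA[CT][TA]GGA[AT][CGA][CT]"),
    ("Thermococcaceae_3", "Thermococcaceae", "AATG[ACT]ACA[AT]A[AGT]ATG[TA][TG]CATT"),
    ("Common", "Common", "TCCA[CG]T[TG]GAAA[TC][GA]AAGGGGT"),
)

UNIFORM_BACKGROUND = np.full(4, 0.25)


def parse_consensus(consensus: str) -> list[str]:
    """Split a bracket-notation pattern into per-position allowed-base sets."""
    tokens: list[str] = []
    i = 0
    while i < len(consensus):
        ch = consensus[i]
        if ch == "[":
            j = consensus.index("]", i)
            alts = consensus[i + 1: j]
            if not alts or any(b not in BASES for b in alts):
                raise UsageError(f"bad bracket group in consensus: {consensus[i:j+1]}")
            tokens.append(alts)
            i = j + 1
        elif ch in BASES:
            tokens.append(ch)
            i += 1
        else:
            raise UsageError(f"bad character {ch!r} in consensus {consensus!r}")
    return tokens


def pspm_from_consensus(consensus: str, eps: float = DEFAULT_EPSILON) -> np.ndarray:
    """Probability matrix from a degenerate consensus.

    Unlisted bases get probability ``eps``; the k listed alternatives share
    (1 − u·eps)/k, u being the number of unlisted bases.
    """
    tokens = parse_consensus(consensus)
    pspm = np.empty((len(tokens), 4))
    for i, alts in enumerate(tokens):
        unlisted = 4 - len(alts)
        pspm[i, :] = eps
        pspm[i, [_BASE_INDEX[b] for b in alts]] = (1.0 - unlisted * eps) / len(alts)
    return pspm


@dataclass
class MotifModel:
    """One ORB motif: consensus, probability matrix and background."""

    name: str
    taxonomy: str
    consensus: str
    pspm: np.ndarray
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BACKGROUND.copy())

    def __post_init__(self) -> None:
        self.pspm = np.asarray(self.pspm, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.pspm.ndim != 2 or self.pspm.shape[1] != 4:
            raise UsageError("pspm must be a width x 4 matrix")
        if np.any(self.pspm < 0) or np.any(self.pspm > 1):
            raise UsageError("pspm entries must lie in [0, 1]")
        if not np.allclose(self.pspm.sum(axis=1), 1.0, atol=1e-9):
            raise UsageError("each pspm row must sum to 1")
        if not math.isclose(float(self.background.sum()), 1.0, abs_tol=1e-9):
            raise UsageError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.pspm.shape[0]

    def top_sequence(self) -> str:
        """A maximum-probability string (first-listed base breaks ties)."""
        if self.consensus:
            return "".join(alts[0] for alts in parse_consensus(self.consensus))
        return "".join(BASES[i] for i in np.argmax(self.pspm, axis=1))

    def llr_matrix(self) -> np.ndarray:
        """Per-position log2 likelihood ratios; −inf where pspm is 0."""
        with np.errstate(divide="ignore"):
            return np.log2(self.pspm / self.background)


@dataclass
class MotifHit:
    """One scored motif occurrence on either strand.

    ``genome_position``/``region_offset`` are the forward-strand 0-based
    starts of the matched window; for a − strand hit ``matched_sequence``
    is the reverse complement of the forward-strand window, i.e. the
    motif-oriented sequence.
    """

    motif_name: str
    region_offset: int
    genome_position: int
    strand: str
    matched_sequence: str
    score: float | None = None
    p_value: float | None = None


def builtin_motifs(eps: float = DEFAULT_EPSILON,
                   background: np.ndarray | None = None) -> list[MotifModel]:
    """The eleven built-in ORB motif models, one per consensus row."""
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, float)
    return [MotifModel(name, taxonomy, consensus,
                       pspm_from_consensus(consensus, eps), bg.copy())
            for name, taxonomy, consensus in ORB_CONSENSUS_TABLE]


def select_motifs(taxonomy: list[str] | None,
                  motifs: list[MotifModel] | None = None) -> list[MotifModel]:
    """Motifs whose cluster matches a lineage string, plus the Common motif.

    With no lineage match (or an empty lineage) only the Common motif is
    returned.
    """
    pool = motifs if motifs is not None else builtin_motifs()
    lineage = [t.lower() for t in (taxonomy or [])]
    chosen = [m for m in pool
              if m.taxonomy != "Common"
              and any(m.taxonomy.lower() in t or t in m.taxonomy.lower()
                      for t in lineage)]
    chosen += [m for m in pool if m.taxonomy == "Common"]
    return chosen


# ---------------------------------------------------------------------------
# degenerate-consensus matching


def match_regex(motif: MotifModel, sequence: str) -> list[MotifHit]:
    """All (overlapping) occurrences of the degenerate consensus, both strands."""
    if not motif.consensus:
        raise UsageError(f"motif {motif.name} has no consensus pattern")
    width = motif.width
    pattern = re.compile(f"(?=({motif.consensus}))")
    seq = sequence.upper()
    hits: list[MotifHit] = []
    for m in pattern.finditer(seq):
        hits.append(MotifHit(motif.name, m.start(), m.start(), "+", m.group(1)))
    rc = revcomp(seq)
    for m in pattern.finditer(rc):
        offset = len(seq) - m.start() - width
        hits.append(MotifHit(motif.name, offset, offset, "-", m.group(1)))
    hits.sort(key=lambda h: (h.region_offset, h.strand))
    return hits


# ---------------------------------------------------------------------------
# PSSM scoring


def _int_llr(motif: MotifModel) -> tuple[np.ndarray, np.ndarray]:
    """(float llr, integer lattice llr) matrices; unscorable cells get a
    large-negative sentinel on the integer side."""
    llr = motif.llr_matrix()
    ints = np.full(llr.shape, _NEG_SENTINEL, dtype=np.int64)
    finite = np.isfinite(llr)
    ints[finite] = np.round(llr[finite] / SCORE_BIN_BITS).astype(np.int64)
    return llr, ints


def score_window(motif: MotifModel, window: str) -> float:
    """Log-likelihood-ratio score in bits of one window of motif width.

    Any non-ACGT base (or a zero-probability base under a zero-pseudocount
    matrix) makes the window unscorable: −inf.
    """
    if len(window) != motif.width:
        raise UsageError(
            f"window length {len(window)} != motif width {motif.width}")
    llr = motif.llr_matrix()
    total = 0.0
    for i, base in enumerate(window.upper()):
        j = _BASE_INDEX.get(base)
        if j is None:
            return float("-inf")
        v = llr[i, j]
        if not np.isfinite(v):
            return float("-inf")
        total += v
    return total


class PValueTable:
    """Exact null distribution of the integer-lattice PSSM score.

    Built by dynamic programming: the distribution of the sum of
    per-position scores of a random background string, on a lattice of
    :data:`SCORE_BIN_BITS`-bit bins.  ``pvalue_bits(s)`` returns
    P(score ≥ s); it is non-increasing in s and equals 1 at −inf.
    """

    def __init__(self, motif: MotifModel):
        _, ints = _int_llr(motif)
        bg = motif.background
        dist = np.ones(1)
        offset = 0  # integer score corresponding to dist[0]
        for i in range(motif.width):
            row = ints[i]
            finite = row > _NEG_SENTINEL
            if not np.any(finite):
                dist = np.zeros(1)
                break
            lo, hi = row[finite].min(), row[finite].max()
            new = np.zeros(len(dist) + (hi - lo), dtype=float)
            for b in range(4):
                if finite[b] and bg[b] > 0:
                    shift = row[b] - lo
                    new[shift: shift + len(dist)] += bg[b] * dist
            dist = new
            offset += lo
        self.min_sum = offset
        self.max_sum = offset + len(dist) - 1
        # survival function over the finite lattice
        self.sf = np.cumsum(dist[::-1])[::-1]
        self.mass_finite = float(dist.sum())

    def pvalue_int(self, total: int) -> float:
        # clamp into the attainable lattice: float/integer rounding of an
        # observed score may land one bin past the DP range
        idx = min(max(total - self.min_sum, 0), len(self.sf) - 1)
        return float(self.sf[idx])

    def pvalue_bits(self, score_bits: float) -> float:
        """P(score ≥ score_bits) under the background model."""
        if score_bits == float("-inf"):
            return 1.0
        return self.pvalue_int(int(round(score_bits / SCORE_BIN_BITS)))

    def threshold_int(self, p_cutoff: float) -> int | None:
        """Smallest lattice score whose p-value is ≤ p_cutoff."""
        idx = np.searchsorted(-self.sf, -p_cutoff, side="left")
        if idx >= len(self.sf):
            return None
        return self.min_sum + int(idx)


def pvalue_table(motif: MotifModel) -> PValueTable:
    """Exact DP p-value table for a motif under its background model."""
    return PValueTable(motif)


def _encode(seq: str) -> np.ndarray:
    table = np.full(256, 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].astype(np.int64)


def _window_int_scores(codes: np.ndarray, ints: np.ndarray) -> np.ndarray:
    """Integer-lattice scores of every window; sentinel where unscorable."""
    width = ints.shape[0]
    m = len(codes) - width + 1
    if m <= 0:
        return np.empty(0, dtype=np.int64)
    padded = np.hstack([ints, np.full((width, 1), _NEG_SENTINEL, dtype=np.int64)])
    total = np.zeros(m, dtype=np.int64)
    for i in range(width):
        total += padded[i, codes[i: i + m]]
    total[total < _NEG_SENTINEL // 2] = _NEG_SENTINEL
    return total


def scan(motif: MotifModel, region: "IntergenicRegion | str",
         p_cutoff: float = DEFAULT_P_CUTOFF,
         table: PValueTable | None = None) -> list[MotifHit]:
    """All windows on both strands whose exact p-value is ≤ ``p_cutoff``.

    ``region`` may be an :class:`~archori.genome_io.IntergenicRegion` (hit
    genome positions are then absolute, modulo the genome length for
    wrapping regions) or a plain string.  Overlapping hits are all kept;
    deduplication is the predictor's concern.
    """
    if not (0 < p_cutoff < 1):
        raise UsageError(f"p_cutoff must be in (0, 1), got {p_cutoff}")
    if isinstance(region, IntergenicRegion):
        seq, base, n = region.sequence, region.start, region.genome_length or 0
    else:
        seq, base, n = str(region), 0, 0
    width = motif.width
    if len(seq) < width:
        return []
    if table is None:
        table = PValueTable(motif)
    cut = table.threshold_int(p_cutoff)
    if cut is None:
        return []
    llr, ints = _int_llr(motif)
    ints_rc = ints[::-1, ::-1]
    llr_rc = llr[::-1, ::-1]
    codes = _encode(seq)
    hits: list[MotifHit] = []
    for strand, imat, fmat in (("+", ints, llr), ("-", ints_rc, llr_rc)):
        totals = _window_int_scores(codes, imat)
        for off in np.nonzero(totals >= cut)[0]:
            off = int(off)
            window = seq[off: off + width].upper()
            bits = float(sum(fmat[i, codes[off + i]] for i in range(width)))
            pos = base + off
            if n:
                pos %= n
            hits.append(MotifHit(
                motif_name=motif.name,
                region_offset=off,
                genome_position=pos,
                strand=strand,
                matched_sequence=window if strand == "+" else revcomp(window),
                score=bits,
                p_value=table.pvalue_int(int(totals[off])),
            ))
    hits.sort(key=lambda h: (h.region_offset, h.strand))
    return hits


def scan_all(motifs: list[MotifModel], region: "IntergenicRegion | str",
             p_cutoff: float = DEFAULT_P_CUTOFF,
             tables: dict[str, PValueTable] | None = None) -> list[MotifHit]:
    """Concatenated, position-sorted scan over a motif set."""
    hits: list[MotifHit] = []
    for motif in motifs:
        table = tables.get(motif.name) if tables else None
        hits.extend(scan(motif, region, p_cutoff, table=table))
    hits.sort(key=lambda h: (h.region_offset, h.motif_name, h.strand))
    return hits


# ---------------------------------------------------------------------------
# MEME minimal-format export / import


def write_meme(motifs: list[MotifModel], path) -> None:
    """Write motifs as a MEME minimal letter-probability file."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = motifs[0].background if motifs else UNIFORM_BACKGROUND
        fh.write("Background letter frequencies\n")
        fh.write("A {:.5f} C {:.5f} G {:.5f} T {:.5f}\n\n".format(*bg))
        for m in motifs:
            fh.write(f"MOTIF {m.name} {m.consensus}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {m.width} "
                     f"nsites= 20 E= 0\n")
            for row in m.pspm:
                fh.write(" {:.6f} {:.6f} {:.6f} {:.6f}\n".format(*row))
            fh.write("\n")


def read_meme(path) -> list[MotifModel]:
    """Read motifs back from a MEME minimal letter-probability file."""
    motifs: list[MotifModel] = []
    bg = UNIFORM_BACKGROUND.copy()
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            parts = lines[i + 1].split()
            bg = np.array([float(parts[j]) for j in (1, 3, 5, 7)])
            i += 2
            continue
        if line.startswith("MOTIF"):
            parts = line.split()
            name = parts[1]
            consensus = parts[2] if len(parts) > 2 else ""
            i += 1
            while not lines[i].strip().startswith("letter-probability"):
                i += 1
            width = int(re.search(r"w=\s*(\d+)", lines[i]).group(1))
            rows = [list(map(float, lines[i + 1 + j].split())) for j in range(width)]
            # cluster name recoverable from the builtin table when present
            taxonomy = next((t for n, t, _ in ORB_CONSENSUS_TABLE if n == name), "")
            motifs.append(MotifModel(name, taxonomy, consensus,
                                     np.array(rows), bg.copy()))
            i += 1 + width
            continue
        i += 1
    return motifs


def builtin_motif_resource() -> str:
    """Path-like handle to the shipped MEME-format ORB motif resource."""
    return str(resources.files("archori").joinpath("data/orb_motifs.meme"))
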