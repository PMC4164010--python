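"""Maximal exact repeats and reverse-complement palindromes in short regions.

Candidate origin regions are annotated with their internal repeat
structure: *direct* repeats (two identical substrings) and *palindromic*
repeats (a substring equal to the reverse complement of another, the
hallmark of inverted-repeat initiator sites; G-stretches and other
low-complexity runs are flagged rather than removed because they flank
ORBs in several taxa).

Every reported hit is maximal — extending the pair one base left or
right breaks the equality.  The finder scans match-runs per diagonal
(direct: positions ``i`` vs ``i+d``) and anti-diagonal (palindromic:
``i`` vs the complement at ``c−i``), which enumerates exactly the maximal
repeats and stays linear per diagonal even on degenerate homopolymer
input.  Regions here are short (typically < 5 kb), so the quadratic
diagonal count is irrelevant.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .errors import UsageError
from .genome_io import revcomp

KINDS = frozenset({"direct", "palindromic"})

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMP = {0: 3, 1: 2, 2: 1, 3: 0}


@dataclass(frozen=True)
class RepeatHit:
    """A maximal exact repeat pair within a region (0-based starts)."""

    kind: str
    pos1: int
    pos2: int
    length: int
    sequence: str
    low_complexity: bool = False


def _is_low_complexity(seq: str) -> bool:
    # dominated by one base, or by a 2-letter alphabet on longer runs
    counts = Counter(seq)
    top = counts.most_common(1)[0][1]
    return top / len(seq) >= 0.75 or len(counts) <= 2


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, length) of every maximal run of True."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.nonzero(diff == 1)[0]
    ends = np.nonzero(diff == -1)[0]
    return [(int(s), int(e - s)) for s, e in zip(starts, ends)]


def find_repeats(sequence: str, min_len: int = 8,
                 kinds: set[str] = frozenset(KINDS)) -> list[RepeatHit]:
    """All maximal exact repeats of the requested kinds, length ≥ ``min_len``.

    Self-overlapping direct pairs (tandem repeats) are allowed; palindromic
    hits are normalised to ``pos1 ≤ pos2`` and a contiguous self-reverse-
    complement span is reported with ``pos1 == pos2``.  Sorted by
    (pos1, pos2); positions with ambiguous bases never match.
    """
    if min_len < 4:
        raise UsageError("min_len must be at least 4")
    bad = kinds - KINDS
    if bad:
        raise UsageError(f"unknown repeat kinds: {sorted(bad)}")
    seq = sequence.upper()
    n = len(seq)
    hits: list[RepeatHit] = []
    if n < min_len:
        return hits
    codes = np.array([_CODE.get(b, -1) for b in seq], dtype=np.int8)
    comp = np.array([_COMP.get(int(c), -9) for c in codes], dtype=np.int8)
    valid = codes >= 0

    if "direct" in kinds:
        for d in range(1, n - min_len + 1):
            mask = (codes[:-d] == codes[d:]) & valid[:-d] & valid[d:]
            for start, length in _runs(mask):
                if length >= min_len:
                    sub = seq[start: start + length]
                    hits.append(RepeatHit("direct", start, start + d, length,
                                          sub, _is_low_complexity(sub)))

    if "palindromic" in kinds:
        # match i against the complement of c − i along each anti-diagonal
        for c in range(min_len - 1, 2 * n - min_len):
            i_lo = max(0, c - n + 1)
            i_hi = min(c, n - 1)
            idx = np.arange(i_lo, i_hi + 1)
            mask = (codes[idx] == comp[c - idx]) & valid[idx] & valid[c - idx]
            for start0, length in _runs(mask):
                u = i_lo + start0
                mirror = c - (u + length - 1)
                if mirror == u:  # self-reverse-complement span
                    if length >= min_len:
                        sub = seq[u: u + length]
                        hits.append(RepeatHit("palindromic", u, u, length,
                                              sub, _is_low_complexity(sub)))
                elif u < mirror:  # report each mirror pair once
                    if length >= min_len:
                        sub = seq[u: u + length]
                        hits.append(RepeatHit("palindromic", u, mirror, length,
                                              sub, _is_low_complexity(sub)))

    unique = sorted(set(hits), key=lambda h: (h.pos1, h.pos2, h.kind, h.length))
    return unique
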