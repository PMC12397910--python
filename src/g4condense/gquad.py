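"""Putative G-quadruplex (QGRS) enumeration and G-score classification.

A quadruplex-forming G-rich sequence is the motif

    G{x} N{y1} G{x} N{y2} G{x} N{y3} G{x}

with four equal-length guanine tracts (x >= 2) joined by three loops, and a
total length bounded by a window cap (30 nt by default).  Candidates are
scored by a documented integer G-score that honours the established
quadruplex-stability principles — more tetrads score higher, shorter total
loops score higher, and even loop partitions score higher than skewed ones —
and a candidate is called "stable" when its score strictly exceeds a
threshold (35 by default).

The committed scoring formula is::

    gscore = 24*(x - 2) + 2*(12 - (y1 + y2 + y3)) - (max(y) - min(y))

where ``x`` is the tract length and ``y`` the loop lengths.  The formula is
this package's own; numeric parity with external G4 prediction servers is
not claimed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .errors import InvalidParameterError, InvalidSequenceError

DEFAULT_MAX_LEN = 30
DEFAULT_MIN_TRACT = 2
DEFAULT_STABLE_THRESHOLD = 35

_VALID = set("ACGTUN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class G4Candidate:
    """One putative quadruplex: position, geometry, strand and score."""

    start: int                      # 0-based, forward-strand coordinates
    tract_length: int
    loop_lengths: tuple             # (y1, y2, y3) in 5'->3' on the strand
    strand: str = "+"
    score: int = 0

    @property
    def total_length(self) -> int:
        return 4 * self.tract_length + sum(self.loop_lengths)

    @property
    def end(self) -> int:
        return self.start + self.total_length


def _normalize(seq: str) -> str:
    s = seq.upper().replace("U", "T")
    bad = set(s) - _VALID
    if bad:
        raise InvalidSequenceError(f"illegal characters in sequence: {sorted(bad)}")
    return s


def reverse_complement(seq: str) -> str:
    return _normalize(seq)[::-1].translate(_COMPLEMENT)


def find_g_runs(seq: str, min_len: int = 1) -> list[tuple[int, int]]:
    """Maximal runs of G of length >= ``min_len`` as (start, length)."""
    s = _normalize(seq)
    return [(m.start(), m.end() - m.start())
            for m in re.finditer("G+", s)
            if m.end() - m.start() >= min_len]


def enumerate_qgrs(seq: str, max_len: int = DEFAULT_MAX_LEN,
                   min_tract: int = DEFAULT_MIN_TRACT,
                   strands: str = "+") -> list[G4Candidate]:
    """All quadruplex candidates in ``seq``, scored, overlapping included.

    Tracts are equal-length G-runs (length >= ``min_tract``); loops may be
    any bases (including G); candidate total length <= ``max_len``.  With
    ``strands="+-"`` the reverse complement is enumerated too and minus-
    strand candidates are reported in forward coordinates (``start`` is the
    leftmost base of the motif on the forward strand).
    """
    if min_tract < 2:
        raise InvalidParameterError("min_tract must be >= 2")
    s = _normalize(seq)
    out = list(_enumerate_forward(s, max_len, min_tract, "+"))
    if "-" in strands:
        rc = reverse_complement(s)
        for c in _enumerate_forward(rc, max_len, min_tract, "-"):
            fwd_start = len(s) - (c.start + c.total_length)
            out.append(G4Candidate(start=fwd_start,
                                   tract_length=c.tract_length,
                                   loop_lengths=c.loop_lengths,
                                   strand="-", score=c.score))
    out.sort(key=lambda c: (c.start, c.strand, c.tract_length))
    return out


def _enumerate_forward(s: str, max_len: int, min_tract: int, strand: str):
    n = len(s)
    max_tract = min((max_len // 4) if max_len else n // 4, n // 4)
    for x in range(min_tract, max_tract + 1):
        # positions where a length-x all-G tract starts
        starts = [p for p in range(n - x + 1)
                  if s[p:p + x] == "G" * x]
        for i, s1 in enumerate(starts):
            limit = s1 + max_len
            for s2 in starts[i + 1:]:
                if s2 < s1 + x:
                    continue
                if s2 + 3 * x > limit:
                    break
                for s3 in starts:
                    if s3 < s2 + x:
                        continue
                    if s3 + 2 * x > limit:
                        break
                    for s4 in starts:
                        if s4 < s3 + x:
                            continue
                        if s4 + x > limit:
                            break
                        loops = (s2 - s1 - x, s3 - s2 - x, s4 - s3 - x)
                        cand = G4Candidate(start=s1, tract_length=x,
                                           loop_lengths=loops, strand=strand)
                        yield G4Candidate(start=s1, tract_length=x,
                                          loop_lengths=loops, strand=strand,
                                          score=gscore(cand))


def gscore(candidate: G4Candidate) -> int:
    """Integer G-score of one candidate (see module docstring for formula).

    Strictly increases with tract length at fixed loops, strictly decreases
    with total loop length at fixed tract length, and over all partitions of
    a fixed loop total is maximal exactly when the loops are as even as
    possible.
    """
    x = candidate.tract_length
    y = candidate.loop_lengths
    if x < 2 or len(y) != 3 or any(l < 0 for l in y):
        raise InvalidParameterError("malformed candidate geometry")
    return 24 * (x - 2) + 2 * (12 - sum(y)) - (max(y) - min(y))


def max_gscore(seq: str, max_len: int = DEFAULT_MAX_LEN,
               min_tract: int = DEFAULT_MIN_TRACT,
               strands: str = "+") -> tuple[G4Candidate, int] | None:
    """Highest-scoring candidate in the sequence, ties to the smaller start.

    Returns ``(candidate, score)`` or ``None`` when no candidate exists.
    """
    cands = enumerate_qgrs(seq, max_len=max_len, min_tract=min_tract,
                           strands=strands)
    if not cands:
        return None
    best = max(cands, key=lambda c: (c.score, -c.start))
    return best, best.score


def classify_stable(score: int,
                    threshold: int = DEFAULT_STABLE_THRESHOLD) -> bool:
    """True iff the score strictly exceeds the stability threshold."""
    return score > threshold


# ---------------------------------------------------------------------------
# FASTA / table I/O
# ---------------------------------------------------------------------------

def scan_fasta(path, max_len: int = DEFAULT_MAX_LEN,
               min_tract: int = DEFAULT_MIN_TRACT, strands: str = "+",
               threshold: int = DEFAULT_STABLE_THRESHOLD):
    """Scan every record of a FASTA file; yields per-candidate dict rows."""
    from Bio import SeqIO

    for rec in SeqIO.parse(str(path), "fasta"):
        for c in enumerate_qgrs(str(rec.seq), max_len=max_len,
                                min_tract=min_tract, strands=strands):
            yield {
                "seq_id": rec.id, "start": c.start, "end": c.end,
                "strand": c.strand, "tract_length": c.tract_length,
                "loop1": c.loop_lengths[0], "loop2": c.loop_lengths[1],
                "loop3": c.loop_lengths[2], "score": c.score,
                "stable": classify_stable(c.score, threshold),
            }
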