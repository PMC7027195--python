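"""Affine-gap Smith–Waterman local alignment.

Desk-scale surrogate for a megablast-style search: the detection method only
needs "best local alignment of query against reference", so a correctness-
first dynamic-programming aligner is used (Biopython's C implementation of
Smith–Waterman with affine gaps).  Scores follow a classic blastn-like
scheme: match +2, mismatch −3, gap open −5, gap extend −2, where a gap of
length k costs open + (k−1)·extend.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from Bio import Align

#: Co-optimal tracebacks examined when applying the deterministic tie-break.
#: Enumerating every co-optimal alignment can blow up combinatorially on
#: low-complexity input, so the tie-break key (smallest reference start, then
#: smallest query start, then shortest alignment) is applied over a bounded
#: prefix of the enumeration.
MAX_CO_OPTIMAL = 64


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scores; gap of length k costs ``gap_open + (k-1)*gap_extend``."""

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0


DEFAULT_SCORING = ScoringScheme()


@dataclass(frozen=True)
class LocalAlignment:
    """A local alignment, 1-based inclusive on both sequences.

    ``aligned_length`` counts alignment columns (matches + mismatches +
    gapped columns); ``percent_identity`` is 100 × matches / aligned_length.
    ``strand`` describes the template strand the query matched and is set by
    the caller (the aligner itself works on the forward orientation).
    """

    query_start: int
    query_end: int
    ref_start: int
    ref_end: int
    score: float
    aligned_length: int
    percent_identity: float
    gap_count: int
    strand: str = "+"


@lru_cache(maxsize=8)
def _aligner(scoring: ScoringScheme) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def local_score(query: str, reference: str,
                scoring: ScoringScheme = DEFAULT_SCORING) -> float:
    """Maximum local alignment score only (no traceback; much faster)."""
    if not query or not reference:
        raise ValueError("cannot align an empty sequence")
    return _aligner(scoring).score(query, reference)


def _from_biopython(alignment, scoring: ScoringScheme) -> LocalAlignment:
    counts = alignment.counts()
    qblocks, rblocks = alignment.aligned[0], alignment.aligned[1]
    qstart, qend = int(qblocks[0][0]), int(qblocks[-1][1])
    rstart, rend = int(rblocks[0][0]), int(rblocks[-1][1])
    length = int(alignment.length)
    identities = int(counts.identities)
    return LocalAlignment(
        query_start=qstart + 1,
        query_end=qend,
        ref_start=rstart + 1,
        ref_end=rend,
        score=float(alignment.score),
        aligned_length=length,
        percent_identity=100.0 * identities / length if length else 0.0,
        gap_count=int(counts.gaps),
    )


def local_align(query: str, reference: str,
                scoring: ScoringScheme = DEFAULT_SCORING) -> LocalAlignment | None:
    """Maximum-score local alignment of ``query`` against ``reference``.

    Ties among co-optimal alignments are broken deterministically by
    (smallest reference start, smallest query start, shortest alignment).
    Returns ``None`` when no local alignment has positive score (the two
    sequences share no matching base).
    """
    if not query or not reference:
        raise ValueError("cannot align an empty sequence")
    alignments = _aligner(scoring).align(query, reference)
    if alignments.score <= 0:
        return None
    best = None
    best_key = None
    for i, alignment in enumerate(alignments):
        if i >= MAX_CO_OPTIMAL:
            break
        cand = _from_biopython(alignment, scoring)
        key = (cand.ref_start, cand.query_start, cand.aligned_length)
        if best_key is None or key < best_key:
            best, best_key = cand, key
    return best
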