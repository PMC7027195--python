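"""Swinger detection: classify reads as canonical, swinger or unidentified.

A read is *canonical* when it aligns to the reference collection without any
transformation, *swinger* when one of the 23 systematic nucleotide exchanges
applied to the read produces a passing local alignment, and *unidentified*
otherwise.  Detection mirrors the two-stage screen used with megablast at
database scale: the untransformed read is tried first, then all 23
transformed variants, each in both orientations.

Strand convention: ``detection_transformation`` is always expressed for the
forward-oriented read — a hit with strand "−" means the transformation
applied to the reverse complement of the read aligns to the forward
reference strand.  The two descriptions of the same alignment (transform
then reverse-complement vs reverse-complement then conjugate-transform) are
related by complement conjugation; expressing everything on the forward
orientation makes the reported class deterministic.

``transcription_transformation`` is the inverse of the detection
transformation: the exchange the polymerase must have performed on the
template to produce the read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping

from . import transforms
from .align import DEFAULT_SCORING, LocalAlignment, ScoringScheme, local_align, local_score
from .transforms import IDENTITY, TRANSFORMATIONS, Transformation

logger = logging.getLogger(__name__)

CANONICAL = "canonical"
SWINGER = "swinger"
UNIDENTIFIED = "unidentified"

HIT_COLUMNS = (
    "read_id", "classification", "detection_transformation",
    "transcription_transformation", "reference_id", "ref_start", "ref_end",
    "strand", "aligned_length", "percent_identity", "score", "ambiguous_flag",
)


class ReferenceDB:
    """Named reference sequences with optional per-reference metadata."""

    def __init__(self, sequences: Mapping[str, str],
                 metadata: Mapping[str, dict] | None = None):
        if not sequences:
            raise ValueError("reference database is empty")
        self.sequences: dict[str, str] = {}
        for ref_id, seq in sequences.items():
            if not seq:
                raise ValueError(f"reference {ref_id!r} has an empty sequence")
            self.sequences[ref_id] = transforms.apply_transformation(IDENTITY, seq)
        self.metadata = dict(metadata or {})

    @classmethod
    def from_fasta(cls, path) -> "ReferenceDB":
        from .io import read_fasta
        return cls(read_fasta(path))

    def __len__(self) -> int:
        return len(self.sequences)

    def items(self):
        return self.sequences.items()


@dataclass(frozen=True)
class DetectionParams:
    """Detection thresholds and scoring.

    Defaults bracket the extremes seen in practice for EST-scale hits
    (alignments down to ~41 nt and ~75% identity): a hit must align over at
    least ``min_aligned_length`` columns at ``min_percent_identity`` or
    better.  ``min_score`` is the significance filter: a seeded database
    search only ever reports alignments anchored on a long exact word and
    below its e-value cutoff, whereas exhaustive Smith–Waterman happily
    returns short chance alignments that can reach 75% identity over 40-odd
    columns against a multi-kilobase reference.  The default of 60 (the
    score of a perfect ~30 nt match) sits far above the chance-score regime
    at desk scale and far below any genuine hit class — the weakest
    realistic hit, ~41 nt at ~95% identity, scores ~72.  With
    ``canonical_first`` the untransformed read is screened before any
    transformation is tried, so canonical reads are never reported as
    swinger.
    """

    min_aligned_length: int = 40
    min_percent_identity: float = 75.0
    min_score: float = 60.0
    scoring: ScoringScheme = field(default_factory=ScoringScheme)
    canonical_first: bool = True

    def __post_init__(self):
        if self.min_aligned_length <= 0:
            raise ValueError("min_aligned_length must be positive")
        if not 0 < self.min_percent_identity <= 100:
            raise ValueError("min_percent_identity must be in (0, 100]")
        if self.min_score < 0:
            raise ValueError("min_score must be non-negative")

    def passes(self, alignment: LocalAlignment) -> bool:
        return (alignment.aligned_length >= self.min_aligned_length
                and alignment.percent_identity >= self.min_percent_identity
                and alignment.score >= self.min_score)

    def min_passing_score(self) -> float:
        """A sound lower bound on the score of any passing alignment.

        A passing alignment has length L ≥ min_aligned_length and at least
        p·L matching columns (p = min identity fraction); every non-matching
        column costs at most 5 (gap open is the worst case).  When the
        per-column bound is positive the minimum is attained at the shortest
        passing length; otherwise any positive score may hide a passing
        alignment and no pruning is possible.
        """
        p = self.min_percent_identity / 100.0
        worst = max(-self.scoring.mismatch, -self.scoring.gap_open,
                    -self.scoring.gap_extend)
        per_column = self.scoring.match * p - worst * (1 - p)
        if per_column <= 0:
            return max(self.min_score, 1e-9)
        return max(per_column * self.min_aligned_length, self.min_score)


@dataclass(frozen=True)
class SwingerHit:
    """One read's classification and, when aligned, its template locus."""

    read_id: str
    classification: str
    detection_transformation: Transformation
    transcription_transformation: Transformation
    reference_id: str | None = None
    alignment: LocalAlignment | None = None
    ambiguous: bool = False
    reason: str | None = None

    def to_row(self) -> tuple:
        aln = self.alignment
        return (
            self.read_id, self.classification,
            self.detection_transformation.name,
            self.transcription_transformation.name,
            self.reference_id or "",
            aln.ref_start if aln else "", aln.ref_end if aln else "",
            aln.strand if aln else "",
            aln.aligned_length if aln else "",
            f"{aln.percent_identity:.3f}" if aln else "",
            f"{aln.score:g}" if aln else "",
            "1" if self.ambiguous else "0",
        )


def _unidentified(read_id: str, reason: str) -> SwingerHit:
    return SwingerHit(read_id, UNIDENTIFIED, IDENTITY, IDENTITY, reason=reason)


def _variants(read: str, candidates: Iterable[Transformation]):
    """(transformation, strand, query) for each orientation of each
    transformation, with the transformation expressed for the forward-
    oriented read."""
    rc = transforms.reverse_complement(read)
    for t in candidates:
        yield t, "+", transforms.apply_transformation(t, read)
        yield t, "-", transforms.apply_transformation(t, rc)


def _best_hit(read_id: str, read: str, db: ReferenceDB, params: DetectionParams,
              candidates: tuple[Transformation, ...]) -> SwingerHit | None:
    """Best passing alignment over candidates × strands × references.

    Scores every combination with the fast score-only pass, then computes
    full alignments in descending score order until one passes the
    thresholds.  Equal-score candidates are ordered by (fewer moved bases,
    canonical name, strand "+" first, reference id); a tie between two
    *different* transformations at the winning score marks the hit
    ambiguous.
    """
    floor = params.min_passing_score()
    scored = []
    for t, strand, query in _variants(read, candidates):
        for ref_id, ref_seq in db.items():
            s = local_score(query, ref_seq, params.scoring)
            if s >= floor:
                scored.append((s, t.moved_bases, t.name, strand, ref_id, t, query))
    scored.sort(key=lambda c: (-c[0], c[1], c[2], c[3], c[4]))

    best: SwingerHit | None = None
    best_score = None
    failure: LocalAlignment | None = None
    for s, _, _, strand, ref_id, t, query in scored:
        if best is not None and s < best_score:
            break
        alignment = local_align(query, db.sequences[ref_id], params.scoring)
        if alignment is None:
            continue
        alignment = replace(alignment, strand=strand)
        if not params.passes(alignment):
            if failure is None or alignment.score > failure.score:
                failure = alignment
            continue
        if best is None:
            classification = CANONICAL if t.is_identity else SWINGER
            best = SwingerHit(
                read_id, classification, t, transforms.invert(t),
                reference_id=ref_id, alignment=alignment,
            )
            best_score = alignment.score
        elif (alignment.score == best_score
              and t is not best.detection_transformation):
            best = replace(best, ambiguous=True)
    if best is not None:
        return best
    if failure is not None:
        if failure.aligned_length < params.min_aligned_length:
            return _unidentified(read_id, "below minimum aligned length")
        if failure.percent_identity < params.min_percent_identity:
            return _unidentified(read_id, "below minimum percent identity")
        return _unidentified(read_id, "below minimum alignment score")
    return None


def detect_swinger(read: str, db: ReferenceDB,
                   params: DetectionParams | None = None,
                   read_id: str = "read") -> SwingerHit:
    """Classify one read against the reference collection.

    With ``canonical_first`` the untransformed read (both orientations) is
    screened first; only reads that fail the canonical screen are tested
    under the 23 transformations — mirroring the two-pass database screen
    in which only reads with no canonical homology enter the transformed
    search.
    """
    params = params or DetectionParams()
    if not read:
        raise ValueError("read is empty")
    read = transforms.apply_transformation(IDENTITY, read)
    if params.canonical_first:
        canonical = _best_hit(read_id, read, db, params, (IDENTITY,))
        if canonical is not None and canonical.classification == CANONICAL:
            return canonical
        hit = _best_hit(read_id, read, db, params, TRANSFORMATIONS)
        if hit is None:
            hit = canonical  # keep the canonical stage's failure reason
    else:
        hit = _best_hit(read_id, read, db, params, (IDENTITY,) + TRANSFORMATIONS)
    if hit is None:
        return _unidentified(read_id, "no alignment")
    return hit


def batch_detect(reads: Iterable[tuple[str, str]], db: ReferenceDB,
                 params: DetectionParams | None = None) -> list[SwingerHit]:
    """Classify a stream of (read_id, sequence) pairs, order-preserving.

    Records with empty or invalid sequences are skipped with a warning.
    Emits one summary log line with per-classification counts.
    """
    params = params or DetectionParams()
    hits: list[SwingerHit] = []
    skipped = 0
    for read_id, seq in reads:
        try:
            hits.append(detect_swinger(seq, db, params, read_id=read_id))
        except ValueError as exc:
            skipped += 1
            logger.warning("skipping read %s: %s", read_id, exc)
    counts = {c: 0 for c in (CANONICAL, SWINGER, UNIDENTIFIED)}
    for h in hits:
        counts[h.classification] += 1
    logger.info(
        "detect: %d reads, %d canonical, %d swinger, %d unidentified, %d skipped",
        len(hits), counts[CANONICAL], counts[SWINGER], counts[UNIDENTIFIED],
        skipped,
    )
    return hits


def write_hits_tsv(hits: Iterable[SwingerHit], handle) -> None:
    handle.write("\t".join(HIT_COLUMNS) + "\n")
    for hit in hits:
        handle.write("\t".join(str(v) for v in hit.to_row()) + "\n")


def read_tabular_hits(handle, transformation_column: int = 12) -> list[SwingerHit]:
    """Import externally produced tabular hits (BLAST outfmt-6-like).

    Expects the 12 standard columns (query, subject, %id, length, mismatches,
    gapopen, qstart, qend, sstart, send, evalue, bitscore) plus a column
    carrying the detection transformation name, so searches run at database
    scale with an external aligner can feed the downstream analyses.
    Subject coordinates with start > end are normalised to start ≤ end with
    strand "−".
    """
    hits = []
    for line_no, line in enumerate(handle, 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) <= transformation_column:
            raise ValueError(f"line {line_no}: expected at least "
                             f"{transformation_column + 1} columns")
        t = transforms.parse_name(fields[transformation_column])
        sstart, send = int(fields[8]), int(fields[9])
        strand = "+" if sstart <= send else "-"
        if strand == "-":
            sstart, send = send, sstart
        length = int(fields[3])
        qstart, qend = sorted((int(fields[6]), int(fields[7])))
        alignment = LocalAlignment(
            query_start=qstart, query_end=qend,
            ref_start=sstart, ref_end=send,
            score=float(fields[11]), aligned_length=length,
            percent_identity=float(fields[2]),
            gap_count=int(fields[5]), strand=strand,
        )
        classification = CANONICAL if t.is_identity else SWINGER
        hits.append(SwingerHit(
            fields[0], classification, t, transforms.invert(t),
            reference_id=fields[1], alignment=alignment,
        ))
    return hits
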