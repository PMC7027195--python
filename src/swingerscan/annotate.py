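"""Mapping hits onto gene models: thirds compartmentalization and
exon/intron structure.

The regional analysis divides each gene into three equal-length regions —
5′, mid and 3′ along the gene's own reading direction — and assigns each hit
to the region containing its midpoint.  Counting hits in the mid+3′ regions
against a null probability of 2/3 feeds the one-tailed sign test used to ask
whether non-canonical transcription is biased away from the 5′ end (as a
polymerase-fatigue mechanism would predict).

Thirds are computed on transcript length when an exon structure is
available and on the genomic span otherwise.  Coordinates are 1-based
inclusive throughout; BED12 input (0-based half-open) is converted on load.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

FIVE_PRIME = "FIVE_PRIME"
MID = "MID"
THREE_PRIME = "THREE_PRIME"

EXONIC = "exonic"
INTRONIC = "intronic"
SPANNING = "spanning"
INTERGENIC = "intergenic"


@dataclass(frozen=True)
class GeneModel:
    """A gene/transcript with exon structure, 1-based inclusive coordinates."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]
    category: str = "protein-coding"

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        prev_end = None
        for s, e in self.exons:
            if s > e or s < self.start or e > self.end:
                raise ValueError(f"{self.gene_id}: exon ({s},{e}) outside span")
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or unsorted")
            prev_end = e

    @property
    def transcript_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def span_length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class RegionAssignment:
    third: str
    midpoint: int


def assign_third(hit_start: int, hit_end: int, length: int) -> RegionAssignment:
    """Third of the gene containing the hit's midpoint.

    Coordinates must already be oriented 5′→3′ along the gene.  The midpoint
    is floor((start+end)/2); boundary positions exactly at floor(L/3) or
    floor(2L/3) belong to the earlier (more 5′) region.
    """
    if not 1 <= hit_start <= hit_end <= length:
        raise ValueError(
            f"interval ({hit_start}, {hit_end}) outside [1, {length}]")
    midpoint = (hit_start + hit_end) // 2
    if midpoint <= length // 3:
        third = FIVE_PRIME
    elif midpoint <= (2 * length) // 3:
        third = MID
    else:
        third = THREE_PRIME
    return RegionAssignment(third, midpoint)


def orient_interval(start: int, end: int, length: int, strand: str) -> tuple[int, int]:
    """Re-express an interval in the gene's 5′→3′ direction."""
    if strand == "-":
        return length - end + 1, length - start + 1
    return start, end


def assign_third_genomic(model: GeneModel, g_start: int, g_end: int) -> RegionAssignment:
    """Thirds on the genomic span, orientation-normalised to the gene."""
    s, e = g_start - model.start + 1, g_end - model.start + 1
    s, e = orient_interval(s, e, model.span_length, model.strand)
    return assign_third(s, e, model.span_length)


def to_transcript_coords(model: GeneModel, g_start: int, g_end: int) -> tuple[int, int]:
    """Project a genomic interval onto transcript coordinates (5′→3′).

    The interval is clipped to the exons; raises ``ValueError`` when it
    does not overlap any exon.
    """
    offsets = []
    pos = 0
    lo = hi = None
    for s, e in model.exons:
        o_s, o_e = max(s, g_start), min(e, g_end)
        if o_s <= o_e:
            t_s = pos + (o_s - s) + 1
            t_e = pos + (o_e - s) + 1
            lo = t_s if lo is None else min(lo, t_s)
            hi = t_e if hi is None else max(hi, t_e)
        pos += e - s + 1
    if lo is None:
        raise ValueError("interval overlaps no exon")
    return orient_interval(lo, hi, model.transcript_length, model.strand)


def classify_structure(g_start: int, g_end: int, model: GeneModel) -> str:
    """Exon/intron structure class of a genomic interval against a model.

    ``exonic`` when fully covered by exons, ``intronic`` when inside the
    gene span but disjoint from every exon, ``spanning`` when it overlaps
    both exonic and non-exonic sequence, and ``intergenic`` when it lies
    entirely outside the span.  Exhaustive and mutually exclusive.
    """
    if g_start > g_end:
        raise ValueError("invalid interval")
    if g_end < model.start or g_start > model.end:
        return INTERGENIC
    covered = 0
    touches = False
    for s, e in model.exons:
        o = min(e, g_end) - max(s, g_start) + 1
        if o > 0:
            covered += o
            touches = True
    span = g_end - g_start + 1
    if covered == span:
        return EXONIC
    if not touches and model.start <= g_start and g_end <= model.end:
        return INTRONIC
    return SPANNING


def mid_or_three_counts(assignments: Iterable[RegionAssignment]) -> tuple[int, int]:
    """(hits in MID or THREE_PRIME, total hits) — the sign-test input."""
    k = n = 0
    for a in assignments:
        n += 1
        if a.third in (MID, THREE_PRIME):
            k += 1
    return k, n


def load_bed12(handle) -> list[GeneModel]:
    """Gene models from BED12 (0-based half-open; blocks become exons)."""
    models = []
    for line_no, line in enumerate(handle, 1):
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        if len(f) < 12:
            raise ValueError(f"line {line_no}: BED12 requires 12 columns")
        chrom, chrom_start, name, strand = f[0], int(f[1]), f[3], f[5]
        block_sizes = [int(x) for x in f[10].rstrip(",").split(",")]
        block_starts = [int(x) for x in f[11].rstrip(",").split(",")]
        if len(block_sizes) != int(f[9]) or len(block_starts) != int(f[9]):
            raise ValueError(f"line {line_no}: block count mismatch")
        exons = tuple(
            (chrom_start + bs + 1, chrom_start + bs + sz)
            for bs, sz in zip(block_starts, block_sizes)
        )
        models.append(GeneModel(
            gene_id=name, chrom=chrom, strand=strand,
            start=chrom_start + 1, end=int(f[2]), exons=exons,
        ))
    return models
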