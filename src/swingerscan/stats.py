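"""Statistical analyses of swinger RNA classes.

Three procedures recur in this analysis:

* **Abundance–length correlation.**  Pearson correlation of log10 class
  abundance against mean aligned length over the detected transformation
  classes.  Under a polymerase-state interpretation a positive correlation
  means the factor that promotes switching into a given exchange mode also
  stabilises it.  p-values come from the exact t transform
  t = r·sqrt((n−2)/(1−r²)) on n−2 degrees of freedom.

* **Exact sign test.**  One-tailed binomial upper tail of k hits in the
  mid+3′ gene regions among n, against a null success probability of 2/3
  (the two regions jointly cover two thirds of the gene).  Computed with
  exact rational arithmetic — no normal approximation.

* **Conservation index.**  For a transformation t, the fraction of the 64
  codons whose translation (stop treated as a 21st class) is unchanged when
  t is applied to each codon base.  More-conservative exchanges are
  expected to be more abundant among detected swinger RNAs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .transforms import TRANSFORMATIONS, Transformation, apply_transformation


@dataclass(frozen=True)
class ClassSummary:
    """Per-transformation abundance and mean alignment statistics."""

    transformation: str
    abundance: int
    mean_aligned_length: float | None
    mean_percent_identity: float | None


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    tails: str
    n: int


@dataclass(frozen=True)
class SignTestResult:
    k: int
    n: int
    p0: float
    p: float


def _as_triples(hits) -> Iterable[tuple[str, float, float]]:
    for h in hits:
        if isinstance(h, tuple):
            yield h
        else:  # a detection hit
            if h.classification != "swinger":
                continue
            yield (h.detection_transformation.name,
                   h.alignment.aligned_length, h.alignment.percent_identity)


def class_summaries(hits, include_zero: bool = False) -> list[ClassSummary]:
    """One summary per transformation class.

    Accepts detection hits (canonical/unidentified reads are ignored) or
    bare (transformation_name, aligned_length, percent_identity) triples.
    With ``include_zero`` every one of the 23 classes appears, which the
    23-class conservation correlation requires.
    """
    by_class: dict[str, list[tuple[float, float]]] = {}
    for name, length, pid in _as_triples(hits):
        by_class.setdefault(name, []).append((length, pid))
    names = [t.name for t in TRANSFORMATIONS]
    out = []
    for name in names:
        values = by_class.get(name, [])
        if not values and not include_zero:
            continue
        out.append(ClassSummary(
            transformation=name,
            abundance=len(values),
            mean_aligned_length=(
                float(np.mean([v[0] for v in values])) if values else None),
            mean_percent_identity=(
                float(np.mean([v[1] for v in values])) if values else None),
        ))
    unknown = set(by_class) - set(names)
    if unknown:
        raise ValueError(f"unknown transformation classes: {sorted(unknown)}")
    return out


def pearson(x: Sequence[float], y: Sequence[float],
            tails: str = "two") -> CorrelationResult:
    """Pearson r with its t-transform p-value on n−2 degrees of freedom.

    ``tails="one"`` tests for positive association (upper tail of t).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y):
        raise ValueError("x and y differ in length")
    if n < 3:
        raise ValueError("need at least 3 pairs (df = n - 2 > 0)")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        if tails == "two":
            p = 2.0 * float(sps.t.sf(abs(t), n - 2))
        elif tails == "one":
            p = float(sps.t.sf(t, n - 2))
        else:
            raise ValueError("tails must be 'one' or 'two'")
    return CorrelationResult(r=r, p=p, tails=tails, n=n)


def abundance_length_correlation(summaries: Iterable[ClassSummary],
                                 log: bool = True) -> CorrelationResult:
    """Correlation of (log10) class abundance with mean aligned length.

    Only classes with abundance ≥ 1 enter (mean length is undefined for
    empty classes).  The log10 transform is the default: abundances span
    orders of magnitude while mean lengths do not, and the log scale is the
    one under which the relationship is close to linear.  ``log=False``
    correlates raw abundances instead.  Two-tailed p.
    """
    detected = [s for s in summaries if s.abundance >= 1]
    if len(detected) < 3:
        raise ValueError("need at least 3 detected classes")
    x = [math.log10(s.abundance) if log else float(s.abundance)
         for s in detected]
    y = [s.mean_aligned_length for s in detected]
    return pearson(x, y, tails="two")


def sign_test(k: int, n: int, p0: float | Fraction = Fraction(2, 3)) -> SignTestResult:
    """Exact one-tailed binomial upper tail P(X ≥ k | n, p0).

    Evaluated with exact rational arithmetic, then converted to float once
    at the end, so the result is correct to full double precision even deep
    in the tail.
    """
    if not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n")
    q0 = Fraction(p0)
    if not 0 < q0 < 1:
        raise ValueError("require 0 < p0 < 1")
    total = Fraction(0)
    for i in range(k, n + 1):
        total += math.comb(n, i) * q0 ** i * (1 - q0) ** (n - i)
    return SignTestResult(k=k, n=n, p0=float(q0), p=float(total))


# --- conservation ---------------------------------------------------------

def standard_genetic_code() -> dict[str, str]:
    """The 64-codon standard nuclear code; stop codons translate to ``*``."""
    from Bio.Data import CodonTable
    table = CodonTable.unambiguous_dna_by_id[1]
    code = dict(table.forward_table)
    for codon in table.stop_codons:
        code[codon] = "*"
    return code


def conservation_index(t: Transformation,
                       code: Mapping[str, str] | None = None) -> float:
    """Fraction of the 64 codons whose translation survives the exchange.

    The transformation is applied to every base of each codon; a codon
    counts as conserved when the encoded amino acid (or stop) is unchanged.
    The identity map scores 1.0; no non-identity exchange conserves all 64
    codons.
    """
    if code is None:
        code = standard_genetic_code()
    bases = "ACGT"
    codons = [a + b + c for a in bases for b in bases for c in bases]
    missing = [c for c in codons if c not in code]
    if missing:
        raise ValueError(f"genetic code is missing codons: {missing[:5]}...")
    conserved = sum(
        1 for codon in codons
        if code[apply_transformation(t, codon)] == code[codon]
    )
    return conserved / 64.0


def conservation_abundance_correlation(
        abundances: Sequence[float],
        indices: Sequence[float]) -> CorrelationResult:
    """One-tailed Pearson correlation over all 23 transformation classes.

    Both vectors must cover the full 23 classes — zero abundances included —
    because the hypothesis concerns which exchanges are *absent* as much as
    which dominate.
    """
    if len(abundances) != 23 or len(indices) != 23:
        raise ValueError("expected exactly 23 paired values")
    return pearson(abundances, indices, tails="one")
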