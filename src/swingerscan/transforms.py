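"""Permutation algebra of systematic nucleotide exchanges.

A systematic nucleotide exchange ("swinger" transformation) is a non-identity
bijection of the DNA alphabet {A, C, G, T} applied uniformly along a sequence.
Exactly 23 such bijections exist: 9 symmetric (involutions — 6 single swaps
such as A↔T and 3 double swaps such as A↔T+C↔G) and 14 asymmetric directional
cycles (8 three-cycles such as A→C→T→A and 6 four-cycles such as A→T→C→G→A).
Together with the identity they form the symmetric group S4 acting on the
alphabet, so composition and inversion stay inside the set.

Names follow the field's arrow notation.  Symmetric swaps are written
``X↔Y`` with X alphabetically first, double swaps ``X↔Y+Z↔W`` with pairs
sorted; asymmetric cycles are written starting from the alphabetically first
moved base, e.g. ``A→T→C→G→A``.  ASCII aliases (``A<>T``, ``A-T-C-G-A``) are
accepted on input because the arrow glyphs are awkward in shell commands and
file formats; the canonical (arrow) form is always emitted.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Iterable

BASES = "ACGT"

#: IUPAC ambiguity codes as base sets (N covers all four; U normalised to T).
IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_SET_TO_CODE = {frozenset(v): k for k, v in IUPAC_SETS.items()}

SYMMETRIC = "symmetric"
ASYMMETRIC = "asymmetric"


@dataclass(frozen=True)
class Transformation:
    """One bijection of {A,C,G,T}: the identity or one of the 23 exchanges.

    ``mapping`` holds the images of (A, C, G, T) in that order.  ``kind`` is
    ``"symmetric"`` for involutions, ``"asymmetric"`` for directional cycles
    and ``"identity"`` for the identity map.  ``cycle_type`` is one of
    ``identity / 2-cycle / 2+2-cycle / 3-cycle / 4-cycle``.
    """

    name: str
    mapping: tuple[str, str, str, str]
    kind: str
    cycle_type: str

    @property
    def is_identity(self) -> bool:
        return self.mapping == tuple(BASES)

    @property
    def moved_bases(self) -> int:
        """Number of bases not fixed by the mapping (0, 2, 3 or 4)."""
        return sum(1 for b, m in zip(BASES, self.mapping) if b != m)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.name


def _cycles(mapping: tuple[str, ...]) -> list[tuple[str, ...]]:
    """Non-trivial cycles of the permutation, each starting from its
    alphabetically first base, sorted by that base."""
    image = dict(zip(BASES, mapping))
    seen: set[str] = set()
    cycles = []
    for start in BASES:
        if start in seen or image[start] == start:
            continue
        cyc = [start]
        seen.add(start)
        nxt = image[start]
        while nxt != start:
            cyc.append(nxt)
            seen.add(nxt)
            nxt = image[nxt]
        cycles.append(tuple(cyc))
    return cycles


def _canonical_name(mapping: tuple[str, ...]) -> str:
    cycles = _cycles(mapping)
    if not cycles:
        return "identity"
    if all(len(c) == 2 for c in cycles):
        return "+".join("↔".join(sorted(c)) for c in cycles)
    (cyc,) = cycles  # a single 3- or 4-cycle
    return "→".join(cyc + (cyc[0],))


def _classify(mapping: tuple[str, ...]) -> tuple[str, str]:
    cycles = _cycles(mapping)
    if not cycles:
        return "identity", "identity"
    lengths = sorted(len(c) for c in cycles)
    if lengths == [2]:
        return SYMMETRIC, "2-cycle"
    if lengths == [2, 2]:
        return SYMMETRIC, "2+2-cycle"
    if lengths == [3]:
        return ASYMMETRIC, "3-cycle"
    return ASYMMETRIC, "4-cycle"


def _make(mapping: tuple[str, ...]) -> Transformation:
    kind, cycle_type = _classify(mapping)
    return Transformation(_canonical_name(mapping), tuple(mapping), kind, cycle_type)


_ALL: dict[tuple[str, ...], Transformation] = {
    p: _make(p) for p in permutations(BASES)
}
_BY_NAME = {t.name: t for t in _ALL.values()}

IDENTITY = _ALL[tuple(BASES)]

#: The 23 exchanges in stable order: symmetric first, each group sorted by
#: canonical name.
TRANSFORMATIONS: tuple[Transformation, ...] = tuple(
    sorted(
        (t for t in _ALL.values() if not t.is_identity),
        key=lambda t: (t.kind != SYMMETRIC, t.name),
    )
)

#: Watson–Crick complement as a transformation (A↔T+C↔G).
COMPLEMENT = _BY_NAME["A↔T+C↔G"]


def enumerate_transformations() -> tuple[Transformation, ...]:
    """All 23 non-identity bijections of {A,C,G,T}, symmetric first."""
    return TRANSFORMATIONS


def parse_name(name: str) -> Transformation:
    """Resolve a transformation name to its canonical object.

    Accepts the arrow notation used in the literature (``A ↔ T``,
    ``A → T → C → G → A``) with arbitrary spacing, the ASCII aliases
    (``A<>T+C<>G``, ``A-T-C-G-A``) and ``identity``.  Raises ``ValueError``
    for anything that is not a bijection of the alphabet.
    """
    s = "".join(name.split()).upper().replace("↔", "<>").replace("→", "-")
    if s in ("IDENTITY", ""):
        return IDENTITY
    image = dict(zip(BASES, BASES))
    if "<>" in s:
        moved: set[str] = set()
        for pair in s.split("+"):
            parts = pair.split("<>")
            if len(parts) != 2 or any(p not in BASES for p in parts):
                raise ValueError(f"cannot parse transformation name {name!r}")
            x, y = parts
            if x == y or x in moved or y in moved:
                raise ValueError(f"cannot parse transformation name {name!r}")
            moved.update((x, y))
            image[x], image[y] = y, x
    elif "-" in s:
        cyc = s.split("-")
        if (cyc[0] != cyc[-1] or len(cyc) < 4
                or any(b not in BASES for b in cyc)
                or len(set(cyc[:-1])) != len(cyc) - 1):
            raise ValueError(f"cannot parse transformation name {name!r}")
        for a, b in zip(cyc[:-1], cyc[1:]):
            image[a] = b
    else:
        raise ValueError(f"cannot parse transformation name {name!r}")
    mapping = tuple(image[b] for b in BASES)
    if sorted(mapping) != list(BASES):
        raise ValueError(f"{name!r} does not describe a bijection of ACGT")
    return _ALL[mapping]


def from_mapping(mapping: Iterable[str]) -> Transformation:
    """Canonical transformation for an (A, C, G, T) image tuple."""
    key = tuple(mapping)
    if key not in _ALL:
        raise ValueError(f"{key!r} is not a bijection of ACGT")
    return _ALL[key]


def invert(t: Transformation) -> Transformation:
    """Inverse bijection; symmetric transformations are self-inverse.

    The inverse is what relates detection to transcription: a read identified
    by applying t aligns to a template that must have been transcribed with
    the inverse exchange (e.g. A→T→C→G→A detections imply A→G→C→T→A
    transcription).
    """
    inverse = {m: b for b, m in zip(BASES, t.mapping)}
    return _ALL[tuple(inverse[b] for b in BASES)]


def compose(t1: Transformation, t2: Transformation) -> Transformation:
    """t1∘t2 (apply t2 first).  Closed over the identity plus the 23."""
    img1 = dict(zip(BASES, t1.mapping))
    return _ALL[tuple(img1[m] for m in t2.mapping)]


def conjugate_by_complement(t: Transformation) -> Transformation:
    """c∘t∘c with c the complement map: the same exchange seen from the
    opposite strand."""
    return compose(COMPLEMENT, compose(t, COMPLEMENT))


def _translation_table(t: Transformation) -> dict[int, str]:
    image = dict(zip(BASES, t.mapping))
    table = {}
    for code, baseset in IUPAC_SETS.items():
        out = _SET_TO_CODE[frozenset(image[b] for b in baseset)]
        table[ord(code)] = out
        table[ord(code.lower())] = out
    table[ord("U")] = image["T"]
    table[ord("u")] = image["T"]
    return table


_TABLES = {t.mapping: str.maketrans(_translation_table(t)) for t in _ALL.values()}
_VALID = set("ACGTRYSWKMBDHVNUacgtryswkmbdhvnu")


def apply_transformation(t: Transformation | str, seq: str) -> str:
    """Apply the exchange to every base of ``seq``.

    IUPAC ambiguity codes are mapped to the code whose base set is the image
    of their base set (so N is always fixed); U is read as T; output is
    uppercase and the same length as the input.  A character outside the
    IUPAC alphabet raises ``ValueError`` naming its position.
    """
    if isinstance(t, str):
        t = parse_name(t)
    bad = next((i for i, ch in enumerate(seq) if ch not in _VALID), None)
    if bad is not None:
        raise ValueError(
            f"invalid nucleotide {seq[bad]!r} at position {bad + 1}"
        )
    return seq.translate(_TABLES[t.mapping])


def reverse_complement(seq: str) -> str:
    """Reverse complement with IUPAC-aware complementation."""
    return apply_transformation(COMPLEMENT, seq)[::-1]


def write_transformation_table(handle) -> None:
    """Tab-separated listing of the 23 exchanges (name, kind, cycle type and
    the images of A, C, G, T)."""
    handle.write("name\tkind\tcycle_type\tA\tC\tG\tT\n")
    for t in TRANSFORMATIONS:
        handle.write(f"{t.name}\t{t.kind}\t{t.cycle_type}\t" + "\t".join(t.mapping) + "\n")
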