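"""Synthetic references and planted swinger reads with known truth.

The generator emulates the EST regime the detection method targets:
single-pass cDNA reads of 100–600 nt drawn from a template, where a read
is either canonical (a verbatim fragment, up to sequencing noise) or the
product of one systematic nucleotide exchange applied during transcription.
The default class distribution mirrors the strong skew seen in real
screens — one dominant symmetric class (A↔T), one dominant asymmetric class
(A→T→C→G→A), a few singleton classes and most classes absent.

Truth records store the *generative* (template→read) transformation, so a
correct detection is one whose transcription transformation matches the
truth.  Reads are built fragment → optional reverse complement →
transformation → substitution noise; with zero noise the round trip
apply(invert(true t), orientation-corrected read) recovers the template
fragment exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import transforms
from .detect import SwingerHit

BASES = "ACGT"

TRUTH_COLUMNS = ("read_id", "ref_id", "start", "end", "strand",
                 "transformation", "n_substitutions")


def paper_like_weights() -> dict[str, float]:
    """Class skew matching a real EST screen: 219:124:2:1:1 over five
    classes (A↔T dominant symmetric, A→T→C→G→A dominant asymmetric)."""
    counts = {"A↔T": 219, "A→T→C→G→A": 124, "A↔C": 2, "C↔T": 1, "G↔T": 1}
    total = sum(counts.values())
    return {k: v / total for k, v in counts.items()}


@dataclass(frozen=True)
class SimulationConfig:
    """Reference and read-generation parameters.

    ``class_weights`` is a distribution over ``"identity"`` plus canonical
    transformation names; ``read_length`` is an inclusive (min, max) range
    defaulting to the 100–600 nt EST regime; ``gc`` defaults to the ~41%
    GC content of the human genome; ``substitution_rate`` is per-base.
    """

    n_references: int = 1
    reference_length: int = 100_000
    gc: float = 0.41
    n_reads: int = 100
    read_length: tuple[int, int] = (100, 600)
    class_weights: Mapping[str, float] = field(default_factory=paper_like_weights)
    substitution_rate: float = 0.0
    revcomp_probability: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.reference_length <= 0:
            raise ValueError("reference_length must be positive")
        if not 0 <= self.gc <= 1:
            raise ValueError("gc must be in [0, 1]")
        if not 0 <= self.substitution_rate <= 1:
            raise ValueError("substitution_rate must be in [0, 1]")
        if not 0 <= self.revcomp_probability <= 1:
            raise ValueError("revcomp_probability must be in [0, 1]")
        weights = dict(self.class_weights)
        if any(w < 0 for w in weights.values()):
            raise ValueError("class weights must be non-negative")
        if abs(sum(weights.values()) - 1.0) > 1e-9:
            raise ValueError("class weights must sum to 1")
        for name in weights:
            if name != "identity":
                transforms.parse_name(name)


@dataclass(frozen=True)
class TruthRecord:
    """Provenance of one planted read (generative transformation)."""

    read_id: str
    ref_id: str
    start: int     # 1-based inclusive on the reference
    end: int
    strand: str
    transformation: str  # template→read exchange, or "identity"
    n_substitutions: int


def generate_reference(config: SimulationConfig) -> dict[str, str]:
    """I.i.d. reference sequences at the configured GC fraction,
    bit-reproducible under the seed."""
    rng = np.random.default_rng(config.seed)
    p = np.array([(1 - config.gc) / 2, config.gc / 2,
                  config.gc / 2, (1 - config.gc) / 2])
    refs = {}
    alphabet = np.array(list(BASES))
    for i in range(config.n_references):
        draws = rng.choice(4, size=config.reference_length, p=p)
        refs[f"ref{i + 1}"] = "".join(alphabet[draws])
    return refs


def plant_reads(references: Mapping[str, str],
                config: SimulationConfig) -> tuple[list[tuple[str, str]],
                                                   list[TruthRecord]]:
    """Plant ``n_reads`` reads with known truth into the references.

    Each read is a uniformly placed fragment, optionally reverse
    complemented (the read then derives from the minus strand), transformed
    by its sampled class, then hit by i.i.d. substitution noise (always to a
    different base).  Deterministic under the config seed.
    """
    if not references:
        raise ValueError("no references to plant reads into")
    min_len, max_len = config.read_length
    shortest_ref = min(len(s) for s in references.values())
    if min_len > shortest_ref:
        raise ValueError("read length exceeds reference length")
    rng = np.random.default_rng(config.seed + 1)
    ref_ids = sorted(references)
    class_names = sorted(config.class_weights)
    class_p = np.array([config.class_weights[n] for n in class_names])
    reads: list[tuple[str, str]] = []
    truths: list[TruthRecord] = []
    for i in range(config.n_reads):
        ref_id = ref_ids[rng.integers(len(ref_ids))]
        ref_seq = references[ref_id]
        length = int(rng.integers(min_len, min(max_len, len(ref_seq)) + 1))
        start = int(rng.integers(0, len(ref_seq) - length + 1))
        fragment = ref_seq[start:start + length]
        strand = "-" if rng.random() < config.revcomp_probability else "+"
        seq = transforms.reverse_complement(fragment) if strand == "-" else fragment
        name = class_names[rng.choice(len(class_names), p=class_p)]
        if name != "identity":
            seq = transforms.apply_transformation(transforms.parse_name(name), seq)
        n_subs = 0
        if config.substitution_rate > 0:
            chars = list(seq)
            hits = np.flatnonzero(rng.random(length) < config.substitution_rate)
            for pos in hits:
                others = [b for b in BASES if b != chars[pos]]
                chars[pos] = others[rng.integers(3)]
            n_subs = len(hits)
            seq = "".join(chars)
        read_id = f"read{i + 1:05d}"
        reads.append((read_id, seq))
        truths.append(TruthRecord(read_id, ref_id, start + 1, start + length,
                                  strand, name, n_subs))
    return reads, truths


def write_truth_tsv(truths: Iterable[TruthRecord], handle) -> None:
    handle.write("\t".join(TRUTH_COLUMNS) + "\n")
    for t in truths:
        handle.write(f"{t.read_id}\t{t.ref_id}\t{t.start}\t{t.end}\t"
                     f"{t.strand}\t{t.transformation}\t{t.n_substitutions}\n")


def read_truth_tsv(handle) -> list[TruthRecord]:
    records = []
    header = handle.readline().rstrip("\n").split("\t")
    if tuple(header) != TRUTH_COLUMNS:
        raise ValueError("not a truth TSV")
    for line in handle:
        f = line.rstrip("\n").split("\t")
        records.append(TruthRecord(f[0], f[1], int(f[2]), int(f[3]), f[4],
                                   f[5], int(f[6])))
    return records


@dataclass(frozen=True)
class EvaluationReport:
    """Detection accuracy against planted truth."""

    confusion: pd.DataFrame          # true class × predicted class
    per_class: pd.DataFrame          # precision/recall per true class
    locus_accuracy: float            # ≥90% reciprocal-of-truth overlap


def _predicted_class(hit: SwingerHit) -> str:
    if hit.classification == "unidentified":
        return "unidentified"
    if hit.classification == "canonical":
        return "identity"
    return hit.transcription_transformation.name


def expected_class(truth: TruthRecord) -> str:
    """The forward-strand-canonical class a correct detection reports.

    Truth stores the exchange applied to the template strand the read was
    transcribed from.  The detector expresses every hit for the forward
    orientation, so for a minus-strand read the equivalent forward-strand
    description is the complement conjugate c∘t∘c of the generative
    exchange (strand duality); plus-strand reads keep their class as is.
    """
    if truth.transformation == "identity":
        return "identity"
    t = transforms.parse_name(truth.transformation)
    if truth.strand == "-":
        t = transforms.conjugate_by_complement(t)
    return t.name


def evaluate_detection(truths: Sequence[TruthRecord],
                       hits: Sequence[SwingerHit]) -> EvaluationReport:
    """Confusion matrix, per-class precision/recall and locus accuracy.

    A hit is class-correct when its *transcription* transformation matches
    the truth's generative exchange re-expressed for the forward strand
    (see ``expected_class``).  Locus accuracy is the fraction of aligned
    hits whose reference
    interval covers ≥ 90% of the true planted interval.  Read-id mismatch
    between the two inputs is an error listing the orphans.
    """
    truth_by_id = {t.read_id: t for t in truths}
    hit_by_id = {h.read_id: h for h in hits}
    orphans = sorted(set(truth_by_id) ^ set(hit_by_id))
    if orphans:
        raise ValueError(f"read ids do not match: {orphans[:10]}")
    labels = (["identity"] + [t.name for t in transforms.TRANSFORMATIONS]
              + ["unidentified"])
    confusion = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    n_located = n_aligned = 0
    for read_id, truth in truth_by_id.items():
        hit = hit_by_id[read_id]
        predicted = _predicted_class(hit)
        confusion.loc[expected_class(truth), predicted] += 1
        if hit.alignment is not None and hit.reference_id == truth.ref_id:
            n_aligned += 1
            overlap = (min(hit.alignment.ref_end, truth.end)
                       - max(hit.alignment.ref_start, truth.start) + 1)
            if overlap >= 0.9 * (truth.end - truth.start + 1):
                n_located += 1
        elif hit.alignment is not None:
            n_aligned += 1
    rows = []
    for label in labels[:-1]:
        n_true = int(confusion.loc[label].sum())
        n_pred = int(confusion[label].sum())
        tp = int(confusion.loc[label, label])
        rows.append({
            "class": label,
            "n_true": n_true,
            "recall": tp / n_true if n_true else float("nan"),
            "precision": tp / n_pred if n_pred else float("nan"),
        })
    per_class = pd.DataFrame(rows).set_index("class")
    locus_accuracy = n_located / n_aligned if n_aligned else float("nan")
    return EvaluationReport(confusion=confusion, per_class=per_class,
                            locus_accuracy=locus_accuracy)
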