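"""Packaged EST tables and their summaries.

Three tab-separated fixtures ship with the package, transcribing the
published lists of swinger-transformed ESTs from a human cancer-genome EST
screen: table 1 (genes seen in a single biosample), table 2 (genes seen in
more than one biosample) and table 3 (non-coding and uncharacterized
genomic regions).  Together they hold 347 records over five transformation
classes.  These tables are the in-paper inputs for the class-abundance,
regional and conservation analyses, so the loader validates the headline
tallies and fails loudly on any transcription discrepancy.

Loading notes
-------------
* e-values are carried as verbatim text (including the typographic minus
  some rows use); they are reference metadata, never recomputed or parsed
  to float.
* 5′/3′ coordinates printed with 5′ > 3′ describe minus-orientation
  alignments; they are normalised to start ≤ end with the strand flag
  retained.
* A few table-3 coordinates were mangled into European-decimal scientific
  notation upstream (e.g. ``1,21E+08``); the verbatim text is kept and the
  numeric value recovered as an approximate integer.
* Some accessions carry a trailing ``*`` in print; the flag is kept on the
  record and stripped from the accession.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from importlib import resources
from typing import Iterable

from . import transforms

PROTEIN_CODING = "protein-coding/known gene"
MITOCHONDRIAL = "mitochondrial"
NON_CODING = "non-coding region"
UNCHARACTERIZED = "uncharacterized"

CANONICAL_COLUMNS = (
    "accession", "biosample", "tissue", "est_length", "transformation",
    "template_accession", "chromosome", "gene", "aligned_length",
    "percent_identity", "evalue", "five_prime", "three_prime",
    "source_table", "starred",
)


@dataclass(frozen=True)
class ESTTableRecord:
    """One transcribed table row, orientation-normalised."""

    accession: str
    biosample: str
    tissue: str
    est_length: int
    transformation: str          # canonical name
    template_accession: str
    chromosome: str              # "1".."22", "X" or "mito"
    gene: str
    aligned_length: int
    percent_identity: float
    evalue: str                  # verbatim text
    five_prime: str              # verbatim printed coordinate
    three_prime: str
    start: int                   # normalised, start <= end
    end: int
    strand: str                  # "+" when 5' <= 3', else "-"
    source_table: str            # T1 / T2 / T3
    starred: bool
    category: str

    @property
    def gene_symbol(self) -> str:
        """Short gene label: the last parenthesised symbol when present
        (nuclear rows), otherwise the verbatim gene field (mito rows,
        non-coding regions)."""
        found = re.findall(r"\(([^()]*)\)", self.gene)
        return found[-1] if found else self.gene


def _parse_coordinate(text: str) -> int:
    s = text.strip()
    if "E+" in s.upper():  # European-decimal scientific notation artefact
        return int(float(s.replace(",", ".")))
    return int(s.replace(",", ""))


def _category(chromosome: str, gene: str) -> str:
    if chromosome.lower() == "mito":
        return MITOCHONDRIAL
    if gene.strip().lower() == "non-coding region":
        return NON_CODING
    if gene.strip().lower().startswith("uncharacterized"):
        return UNCHARACTERIZED
    return PROTEIN_CODING


def _record_from_fields(fields: list[str], source_table: str) -> ESTTableRecord:
    accession = fields[0].strip()
    starred = accession.endswith("*")
    accession = accession.rstrip("*")
    chromosome = fields[6].strip()
    if chromosome.lower() == "x":
        chromosome = "X"
    five_prime, three_prime = fields[11].strip(), fields[12].strip()
    start, end = _parse_coordinate(five_prime), _parse_coordinate(three_prime)
    strand = "+" if start <= end else "-"
    if start > end:
        start, end = end, start
    return ESTTableRecord(
        accession=accession,
        biosample=fields[1].strip(),
        tissue=fields[2].strip(),
        est_length=int(fields[3].replace(",", "")),
        transformation=transforms.parse_name(fields[4]).name,
        template_accession=fields[5].strip(),
        chromosome=chromosome,
        gene=fields[7].strip(),
        aligned_length=int(fields[8].replace(",", "")),
        percent_identity=float(fields[9]),
        evalue=fields[10].strip(),
        five_prime=five_prime,
        three_prime=three_prime,
        start=start, end=end, strand=strand,
        source_table=source_table,
        starred=starred,
        category=_category(chromosome, fields[7]),
    )


#: Expected headline tallies; any transcription drift fails the loader.
_EXPECTED_CLASS_COUNTS = {"A↔T": 219, "A→T→C→G→A": 124,
                          "A↔C": 2, "C↔T": 1, "G↔T": 1}


def load_table_fixtures(validate: bool = True) -> list[ESTTableRecord]:
    """All 347 packaged records across the three tables.

    With ``validate`` (the default) the per-class tallies and the
    symmetric-class total are checked against the published counts and a
    mismatch raises with the discrepancy spelled out.
    """
    records: list[ESTTableRecord] = []
    data = resources.files("swingerscan").joinpath("data")
    for i, fname in enumerate(("table1.tsv", "table2.tsv", "table3.tsv"), 1):
        text = data.joinpath(fname).read_text(encoding="utf8")
        lines = text.rstrip("\n").split("\n")
        n_cols = len(lines[0].split("\t"))
        for row_no, line in enumerate(lines[1:], 2):
            fields = line.split("\t")
            if len(fields) != n_cols:
                raise ValueError(f"{fname} row {row_no}: expected {n_cols} "
                                 f"columns, found {len(fields)}")
            try:
                records.append(_record_from_fields(fields, f"T{i}"))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{fname} row {row_no}: {exc}") from exc
    if validate:
        tally = Counter(r.transformation for r in records)
        if dict(tally) != _EXPECTED_CLASS_COUNTS:
            raise ValueError(
                "fixture class tallies drifted from the published counts: "
                f"got {dict(tally)}, expected {_EXPECTED_CLASS_COUNTS}")
        symmetric = sum(
            1 for r in records
            if transforms.parse_name(r.transformation).kind == "symmetric")
        if symmetric != 223:
            raise ValueError(f"expected 223 symmetric records, got {symmetric}")
    return records


@dataclass(frozen=True)
class PaperSummary:
    """Headline counts over the packaged tables."""

    total: int
    class_counts: dict[str, int]
    symmetric_count: int
    asymmetric_count: int
    mitochondrial_count: int
    mito_gene_counts: dict[str, int]
    gene_counts: dict[str, int]
    noncoding_count: int
    uncharacterized_count: int


def summarize_tables(records: Iterable[ESTTableRecord]) -> PaperSummary:
    """Deterministic counts by transformation class, category and gene."""
    records = list(records)
    class_counts = Counter(r.transformation for r in records)
    symmetric = sum(
        c for name, c in class_counts.items()
        if transforms.parse_name(name).kind == "symmetric")
    mito = [r for r in records if r.category == MITOCHONDRIAL]
    gene_counts = Counter(r.gene_symbol for r in records)
    return PaperSummary(
        total=len(records),
        class_counts=dict(class_counts),
        symmetric_count=symmetric,
        asymmetric_count=len(records) - symmetric,
        mitochondrial_count=len(mito),
        mito_gene_counts=dict(Counter(r.gene.lower() for r in mito)),
        gene_counts=dict(gene_counts),
        noncoding_count=sum(r.category == NON_CODING for r in records),
        uncharacterized_count=sum(
            r.category == UNCHARACTERIZED for r in records),
    )


def write_records_tsv(records: Iterable[ESTTableRecord], handle) -> None:
    """Canonical TSV dialect; load → write → load round-trips exactly."""
    handle.write("\t".join(CANONICAL_COLUMNS) + "\n")
    for r in records:
        handle.write("\t".join(str(v) for v in (
            r.accession, r.biosample, r.tissue, r.est_length,
            r.transformation, r.template_accession, r.chromosome, r.gene,
            r.aligned_length, f"{r.percent_identity:.3f}", r.evalue,
            r.five_prime, r.three_prime, r.source_table,
            "1" if r.starred else "0",
        )) + "\n")


def read_records_tsv(handle) -> list[ESTTableRecord]:
    header = handle.readline().rstrip("\n").split("\t")
    if tuple(header) != CANONICAL_COLUMNS:
        raise ValueError("not a canonical EST-record TSV")
    records = []
    for line in handle:
        f = line.rstrip("\n").split("\t")
        rec = _record_from_fields(
            [f[0] + ("*" if f[14] == "1" else ""), f[1], f[2], f[3], f[4],
             f[5], f[6], f[7], f[8], f[9], f[10], f[11], f[12]],
            f[13])
        records.append(rec)
    return records
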