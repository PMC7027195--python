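"""FASTA and flat-config helpers."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)


def read_fasta(path) -> dict[str, str]:
    """Sequences keyed by record id; duplicate ids are an error."""
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"duplicate FASTA id {record.id!r}")
        sequences[record.id] = str(record.seq)
    return sequences


def iter_fasta_reads(path) -> Iterator[tuple[str, str]]:
    """(id, sequence) pairs; empty records are skipped with a warning."""
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq)
        if not seq:
            logger.warning("skipping empty FASTA record %s", record.id)
            continue
        yield record.id, seq


def write_fasta(sequences: Mapping[str, str] | Iterable[tuple[str, str]],
                path) -> None:
    items = sequences.items() if hasattr(sequences, "items") else sequences
    records = (SeqRecord(Seq(seq), id=name, description="")
               for name, seq in items)
    SeqIO.write(records, str(path), "fasta")


def read_flat_config(path) -> dict[str, str]:
    """``key = value`` lines; '#' starts a comment; blank lines ignored."""
    config: dict[str, str] = {}
    for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path} line {line_no}: expected key = value")
        key, value = line.split("=", 1)
        config[key.strip()] = value.strip()
    return config
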