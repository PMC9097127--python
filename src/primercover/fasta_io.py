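"""FASTA input, stable sequence ids and the id/header/sequence conversion table.

Sequence ids are 1-based integers assigned in file order; they — not the
headers, which may collide — are the join key used by every downstream
table and by the coverage matrix columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

# IUPAC nucleotide one-letter codes, DNA only (no U).
IUPAC_DNA = frozenset("ACGTNRYSWKMBDHV")


class FastaInputError(ValueError):
    """Raised for malformed or unusable FASTA input."""


@dataclass(frozen=True)
class SequenceRecord:
    """One input target: stable 1-based id, verbatim header, uppercased sequence."""

    seq_id: int
    header: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


def _validate(seq_id: int, header: str, sequence: str) -> str:
    seq = "".join(sequence.split()).upper()
    if not seq:
        raise FastaInputError(f"record '{header}' has an empty sequence")
    bad = set(seq) - IUPAC_DNA
    if bad:
        raise FastaInputError(
            f"record '{header}' contains non-IUPAC-DNA character(s): "
            + ", ".join(sorted(bad))
        )
    return seq


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a multi-record FASTA file into SequenceRecords with ids 1..n.

    Wrapped sequence lines are concatenated and case is folded to upper.
    Duplicate headers raise a warning (ids disambiguate); an empty file,
    an empty sequence or a non-IUPAC character is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FastaInputError(f"no such file: {path}")
    records: list[SequenceRecord] = []
    seen_headers: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description
        seq = _validate(len(records) + 1, header, str(rec.seq))
        if header in seen_headers:
            warnings.warn(
                f"duplicate FASTA header '{header}'; sequence ids disambiguate",
                stacklevel=2,
            )
        seen_headers.add(header)
        records.append(SequenceRecord(len(records) + 1, header, seq))
    if not records:
        raise FastaInputError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records back to FASTA (unwrapped lines, verbatim headers)."""
    bio = [
        _BioRecord(Seq(r.sequence), id="", description=r.header) for r in records
    ]
    with open(path, "w") as fh:
        for rec in bio:
            fh.write(f">{rec.description}\n{rec.seq}\n")


def conversion_table(records: Sequence[SequenceRecord]) -> pd.DataFrame:
    """One row per record: (seq_id, header, sequence), in id order."""
    if not records:
        raise FastaInputError("conversion table requires at least one record")
    return pd.DataFrame(
        {
            "seq_id": [r.seq_id for r in records],
            "header": [r.header for r in records],
            "sequence": [r.sequence for r in records],
        }
    )
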