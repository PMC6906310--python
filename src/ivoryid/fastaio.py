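"""FASTA input/output (Biopython-backed) with nucleotide normalisation.

Sequences are upper-cased, ``U`` is mapped to ``T``, and any character
outside the IUPAC nucleotide alphabet (plus ``-`` gaps) is rejected with
the record name and offset.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FastaParseError

IUPAC_ALPHABET = frozenset("ACGTRYSWKMBDHVN-")


def _normalise(name: str, raw: str) -> str:
    seq = raw.upper().replace("U", "T")
    for i, ch in enumerate(seq):
        if ch not in IUPAC_ALPHABET:
            raise FastaParseError(
                f"record {name!r}: illegal character {ch!r} at offset {i}"
            )
    return seq


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(identifier, sequence), ...]``."""
    path = Path(path)
    records = [
        (rec.id, _normalise(rec.id, str(rec.seq)))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    """Write ``(identifier, sequence)`` pairs as FASTA."""
    seq_records = [
        SeqRecord(Seq(_normalise(name, seq)), id=name, description="")
        for name, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")
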