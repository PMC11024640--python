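"""Nucleotide sequences and FASTA input/output.

Transcript sequences are held as plain DNA strings over ``{A, C, G, T, N}``.
RNA input is accepted: ``U`` is mapped to ``T`` on ingest and case is folded,
so downstream feature code only ever sees the five-letter DNA alphabet.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_ALPHABET = frozenset("ACGTN")

_INGEST = str.maketrans("acgtunU", "ACGTTTT")


@dataclass(frozen=True)
class NucleotideSequence:
    """A named transcript sequence over the alphabet ``{A, C, G, T, N}``."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if len(self.residues) < 1:
            raise ValueError(f"{self.id}: sequence must be non-empty")
        bad = set(self.residues) - VALID_ALPHABET
        if bad:
            raise ValueError(
                f"{self.id}: invalid characters {sorted(bad)}; "
                "expected A/C/G/T/N (use from_raw for RNA or lowercase input)"
            )

    @classmethod
    def from_raw(cls, id: str, raw: str) -> "NucleotideSequence":
        """Build from arbitrary-case DNA or RNA text (U -> T)."""
        return cls(id, raw.translate(_INGEST).upper())

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def gc_fraction(self) -> float:
        """G+C over non-N residues (0.0 when the sequence is all N)."""
        n = sum(1 for c in self.residues if c != "N")
        if n == 0:
            return 0.0
        gc = self.residues.count("G") + self.residues.count("C")
        return gc / n


def read_fasta(path: str | Path) -> list[NucleotideSequence]:
    """Read a (multi-line, case-insensitive) FASTA file.

    Ids must be unique within the file; duplicated ids raise ``ValueError``.
    """
    seqs: list[NucleotideSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seqs.append(NucleotideSequence.from_raw(rec.id, str(rec.seq)))
    return seqs


def write_fasta(seqs: Iterable[NucleotideSequence], path: str | Path) -> None:
    records = (
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs
    )
    SeqIO.write(records, str(path), "fasta")


def check_unique_ids(seqs: Sequence[NucleotideSequence]) -> None:
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("sequence ids are not unique within the collection")
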