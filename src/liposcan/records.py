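"""Protein records and FASTA/TSV helpers."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass
class ProteinRecord:
    """One predicted protein from a metagenome sample."""

    protein_id: str
    sequence: str
    sample_id: str = ""
    taxonomy: dict = field(default_factory=dict)  # e.g. {"phylum": ..., "genus": ...}

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | Path, sample_id: str = "") -> list[ProteinRecord]:
    """Read a protein FASTA file into ProteinRecords."""
    records = [
        ProteinRecord(rec.id, str(rec.seq).upper(), sample_id=sample_id)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no sequences found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.protein_id, description="") for r in records]
    SeqIO.write(seqs, str(path), "fasta")
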