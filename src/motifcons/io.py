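"""FASTA and table I/O helpers (Biopython / pandas behind the scenes)."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .motifs import SequenceRecord


def read_fasta(path, role: str = "promoter") -> list[SequenceRecord]:
    """Read a (possibly aligned) FASTA file into validated records."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            SequenceRecord(id=rec.id, residues=str(rec.seq), role=role)
        )
    if not records:
        raise ValueError(f"no sequences found in {path}")
    return records


def write_fasta(
    records: Iterable[SequenceRecord],
    path,
    descriptions: Mapping[str, str] | None = None,
) -> None:
    descriptions = descriptions or {}
    bio_records = [
        BioSeqRecord(
            Seq(rec.residues), id=rec.id, description=descriptions.get(rec.id, "")
        )
        for rec in records
    ]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    SeqIO.write(bio_records, str(path), "fasta")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
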