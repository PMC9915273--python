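"""Readers and writers for the formats the pipeline touches.

FASTA for miRNA sequences (via Biopython), delimited relation tables
(compound id, SMILES, miRNA id + sequence, label), and prediction tables.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO
from rdkit import Chem
from rdkit import RDLogger

from .types import Label, MirnaRecord, RelationRecord, RelationSet, SmRecord

RDLogger.DisableLog("rdApp.*")

RELATION_COLUMNS = ["sm_id", "smiles", "mirna_id", "mirna_seq", "label"]


@dataclasses.dataclass
class ReadReport:
    """Per-read accounting of rejected records, for error surfacing."""

    n_read: int = 0
    n_rejected: int = 0
    errors: list[str] = dataclasses.field(default_factory=list)

    def reject(self, msg: str) -> None:
        self.n_rejected += 1
        self.errors.append(msg)


def read_mirna_fasta(path: str | Path, strict: bool = True) -> list[MirnaRecord]:
    """Read miRNA records from a FASTA file.

    Sequences are uppercased and wrapped lines joined. Entries containing
    characters outside A/C/G/U/T (including N, which no encoder can place
    in a composition bin) are rejected: an exception naming the record in
    strict mode (the default), silently dropped otherwise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[MirnaRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper()
        try:
            records.append(MirnaRecord(id=entry.id, sequence=seq))
        except ValueError:
            if strict:
                raise
    return records


def parse_smiles(smiles: str):
    """Return an RDKit Mol for a SMILES string, or None if unparseable."""
    if not smiles:
        return None
    return Chem.MolFromSmiles(smiles)


def read_relation_table(
    path: str | Path, sep: str = "\t"
) -> tuple[RelationSet, ReadReport]:
    """Read a delimited relation table into a RelationSet.

    Expected header columns: sm_id, smiles, mirna_id, mirna_seq, label.
    Rows with unparseable SMILES are rejected and counted on the report;
    an unknown label token raises.
    """
    df = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    missing = [c for c in RELATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"relation table missing columns: {missing}")
    report = ReadReport()
    relations: list[RelationRecord] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        report.n_read += 1
        if parse_smiles(row.smiles) is None:
            report.reject(f"row {row_no}: unparseable SMILES {row.smiles!r}")
            continue
        label = Label.parse(row.label)  # raises on unknown tokens
        try:
            mirna = MirnaRecord(id=row.mirna_id, sequence=row.mirna_seq.upper())
        except ValueError as exc:
            report.reject(f"row {row_no}: {exc}")
            continue
        relations.append(
            RelationRecord(sm=SmRecord(id=row.sm_id, smiles=row.smiles), mirna=mirna, label=label)
        )
    return RelationSet(relations), report


def write_relation_table(relations: RelationSet, path: str | Path, sep: str = "\t") -> None:
    """Write a RelationSet as a delimited table (round-trips with the reader)."""
    rows = [
        {
            "sm_id": r.sm.id,
            "smiles": r.sm.smiles,
            "mirna_id": r.mirna.id,
            "mirna_seq": r.mirna.sequence,
            "label": r.label.value,
        }
        for r in relations
    ]
    pd.DataFrame(rows, columns=RELATION_COLUMNS).to_csv(path, sep=sep, index=False)


def call_label(p_up: float, threshold: float = 0.5) -> Label:
    """Binary call from an upregulation probability.

    Strictly greater than the threshold calls UP; a score exactly at the
    threshold calls DOWN (deterministic tie rule).
    """
    return Label.UP if p_up > threshold else Label.DOWN


def write_predictions(
    records: Sequence[tuple[RelationRecord, float]],
    path: str | Path,
    sep: str = "\t",
) -> None:
    """Write scored relations as a table with columns sm_id, mirna_id, p_up, call."""
    for rel, score in records:
        if not 0.0 <= score <= 1.0:
            raise ValueError(
                f"score {score} for pair {rel.key} outside [0, 1]"
            )
    rows = [
        {
            "sm_id": rel.sm.id,
            "mirna_id": rel.mirna.id,
            "p_up": score,
            "call": call_label(score).value,
        }
        for rel, score in records
    ]
    pd.DataFrame(rows, columns=["sm_id", "mirna_id", "p_up", "call"]).to_csv(
        path, sep=sep, index=False
    )


def read_predictions(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep)
    if not {"sm_id", "mirna_id", "p_up"} <= set(df.columns):
        raise ValueError("predictions table needs columns sm_id, mirna_id, p_up")
    return df
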