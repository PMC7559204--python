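"""Raw study records: one row per (subject, medication text, reason text)."""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import List

import pandas as pd

__all__ = ["RawRecord", "read_records_tsv", "write_records_tsv"]

_COLUMNS = ["subject_id", "medication_raw", "reason_raw"]


@dataclass(frozen=True)
class RawRecord:
    """One study entry as abstracted from the source form."""

    subject_id: str
    medication_raw: str
    reason_raw: str


def read_records_tsv(path: str | Path) -> List[RawRecord]:
    """Read a records table (TSV with header subject_id / medication_raw / reason_raw)."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"records file {path} lacks columns: {missing}")
    return [
        RawRecord(row.subject_id, row.medication_raw, row.reason_raw)
        for row in frame.itertuples(index=False)
    ]


def write_records_tsv(records: List[RawRecord], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(_COLUMNS)
        for record in records:
            writer.writerow([record.subject_id, record.medication_raw, record.reason_raw])
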