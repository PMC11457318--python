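"""BLAST tabular (outfmt 6, 12 columns) reading and writing."""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from cherry_rga.io.interproscan import ParseError


@dataclass(frozen=True)
class BlastHit:
    """One HSP row of ``-outfmt 6`` output."""

    query_id: str
    subject_id: str
    percent_identity: float
    align_length: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValueError(f"percent identity {self.percent_identity} out of [0, 100]")
        if self.evalue < 0 or self.bitscore < 0:
            raise ValueError("evalue and bitscore must be non-negative")


_N_COLS = 12


def read_blast_tab(path: str | Path) -> list[BlastHit]:
    """Parse a 12-column BLAST tabular file; errors name the offending line."""
    path = Path(path)
    hits: list[BlastHit] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) != _N_COLS:
                raise ParseError(f"{path.name}:{lineno}: expected {_N_COLS} columns, got {len(row)}")
            try:
                hits.append(
                    BlastHit(
                        query_id=row[0],
                        subject_id=row[1],
                        percent_identity=float(row[2]),
                        align_length=int(row[3]),
                        mismatches=int(row[4]),
                        gap_opens=int(row[5]),
                        qstart=int(row[6]),
                        qend=int(row[7]),
                        sstart=int(row[8]),
                        send=int(row[9]),
                        evalue=float(row[10]),
                        bitscore=float(row[11]),
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path.name}:{lineno}: {exc}") from exc
    return hits


def write_blast_tab(hits: Iterable[BlastHit], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for h in hits:
            w.writerow(
                [
                    h.query_id,
                    h.subject_id,
                    f"{h.percent_identity:.3f}",
                    h.align_length,
                    h.mismatches,
                    h.gap_opens,
                    h.qstart,
                    h.qend,
                    h.sstart,
                    h.send,
                    f"{h.evalue:.2g}",
                    f"{h.bitscore:g}",
                ]
            )
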