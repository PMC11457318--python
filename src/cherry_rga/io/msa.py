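"""Aligned protein FASTA input/output.

Alignments are thin immutable wrappers over equal-length gapped rows; the
distance code consumes the byte matrix from :meth:`Alignment.to_array`.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO
from pathlib import Path

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass(frozen=True)
class Alignment:
    names: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.rows):
            raise ValueError("names and rows differ in length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate sequence names in alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment rows: lengths {sorted(lengths)}")

    @property
    def n_sequences(self) -> int:
        return len(self.names)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def to_array(self) -> np.ndarray:
        """(n_sequences, n_columns) uint8 matrix of ASCII codes."""
        return np.frombuffer("".join(self.rows).encode("ascii"), dtype=np.uint8).reshape(
            self.n_sequences, self.n_columns
        )

    def take_columns(self, idx: np.ndarray) -> "Alignment":
        """Column subset/resample (used by the bootstrap)."""
        arr = self.to_array()[:, idx]
        return Alignment(self.names, tuple(bytes(r).decode("ascii") for r in arr))


def read_alignment(path: str | Path) -> Alignment:
    aln = AlignIO.read(str(path), "fasta")
    return Alignment(
        names=tuple(rec.id for rec in aln),
        rows=tuple(str(rec.seq).upper() for rec in aln),
    )


def write_alignment(aln: Alignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(row), id=name, description="") for name, row in zip(aln.names, aln.rows)
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta-2line")


def alignment_from_string(text: str) -> Alignment:
    aln = AlignIO.read(StringIO(text), "fasta")
    return Alignment(
        names=tuple(rec.id for rec in aln),
        rows=tuple(str(rec.seq).upper() for rec in aln),
    )
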