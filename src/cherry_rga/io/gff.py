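"""GFF3 gene models: genomic positions and transcript membership per gene."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import gffutils

from cherry_rga.ids import DEFAULT_ID_PATTERN, subgenome_of, transcript_to_gene

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneRecord:
    """One gene feature with its mRNA children (1-based inclusive bp)."""

    gene_id: str
    subgenome: str  # "A", "F" or "OTHER"
    chromosome: str
    start: int
    end: int
    strand: str  # "+", "-" or "."
    transcript_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid span {self.start}..{self.end} for {self.gene_id}")
        if not self.transcript_ids:
            raise ValueError(f"gene {self.gene_id} has no transcripts")


def read_gff3(path: str | Path, id_pattern: str = DEFAULT_ID_PATTERN) -> list[GeneRecord]:
    """Parse gene and mRNA features into :class:`GeneRecord` objects.

    Every mRNA must have a gene parent; mRNA IDs must collapse to their gene's
    ID under ``id_pattern`` (the splice-variant suffix rule).
    """
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except gffutils.exceptions.EmptyInputError:
        log.warning("no features in %s; returning an empty gene list", path)
        return []
    records: list[GeneRecord] = []
    seen_mrna_parents: set[str] = set()
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        tids = [m.id for m in db.children(gene, featuretype="mRNA", order_by="start")]
        seen_mrna_parents.update(tids)
        if not tids:
            log.warning("gene %s has no mRNA children; skipped", gene.id)
            continue
        for tid in tids:
            if transcript_to_gene(tid, id_pattern) != gene.id:
                raise ValueError(
                    f"mRNA {tid} does not collapse to its parent gene {gene.id} "
                    f"under pattern {id_pattern!r}"
                )
        records.append(
            GeneRecord(
                gene_id=gene.id,
                subgenome=subgenome_of(gene.id),
                chromosome=gene.seqid,
                start=gene.start,
                end=gene.end,
                strand=gene.strand or ".",
                transcript_ids=tuple(tids),
            )
        )
    for mrna in db.features_of_type("mRNA"):
        if mrna.id not in seen_mrna_parents:
            raise ValueError(f"mRNA {mrna.id} has no parent gene feature")
    if not records:
        log.warning("no gene features parsed from %s", path)
    return records


def write_gff3(genes: Iterable[GeneRecord], path: str | Path, source: str = "cherry_rga") -> None:
    """Emit gene + mRNA features (the dialect :func:`read_gff3` consumes)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chromosome}\t{source}\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for tid in g.transcript_ids:
                fh.write(
                    f"{g.chromosome}\t{source}\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                    f"ID={tid};Parent={g.gene_id}\n"
                )
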