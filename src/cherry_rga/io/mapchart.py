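"""MapChart chromosome-map text writer.

MapChart draws linkage-group style maps from a plain text format: a ``group``
line per chromosome followed by ``locus  position`` lines.  Genomic base-pair
positions are divided by a configurable divisor (default 1e6, i.e. Mb) so the
maps are readable at chromosome scale.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

from cherry_rga.io.gff import GeneRecord


def write_mapchart(
    genes: Sequence[GeneRecord],
    classes: Mapping[str, str],
    clusters: Iterable["object"] = (),
    path: str | Path | None = None,
    divisor: float = 1e6,
) -> str:
    """Render a MapChart file of classified genes, one group per chromosome.

    Cluster members get a trailing ``C<n>`` marker in their locus label so the
    physical clusters stand out on the map.
    """
    member_of: dict[str, int] = {}
    for i, c in enumerate(clusters, start=1):
        for gid in getattr(c, "members", ()):  # duck-typed: clusters.Cluster
            member_of[gid] = i

    by_chrom: dict[tuple[str, str], list[GeneRecord]] = {}
    for g in genes:
        if g.gene_id in classes:
            by_chrom.setdefault((g.subgenome, g.chromosome), []).append(g)

    lines: list[str] = []
    for (sub, chrom) in sorted(by_chrom):
        lines.append(f"group {sub}_{chrom}")
        for g in sorted(by_chrom[(sub, chrom)], key=lambda g: g.start):
            label = f"{g.gene_id}_{classes[g.gene_id]}"
            if g.gene_id in member_of:
                label += f"_C{member_of[g.gene_id]}"
            lines.append(f"{label}\t{g.start / divisor:.3f}")
        lines.append("")
    text = "\n".join(lines)
    if path is not None:
        Path(path).write_text(text)
    return text
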