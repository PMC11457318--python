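"""Physical RGA gene clusters along chromosomes.

A cluster is a maximal chain of classified RGA genes on one chromosome in
which consecutive genes are separated by at most a window (default 200 kb,
the convention of the R-gene cluster literature), with at least two members.
Chaining is single-linkage: the gap is measured from the running end of the
open chain to the next gene's start, which makes the chains exactly the
connected components of the pairwise "within window" relation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from cherry_rga.classify import RGAClass
from cherry_rga.io.gff import GeneRecord

log = logging.getLogger(__name__)

#: Classes that participate in cluster detection.
CLUSTERABLE = frozenset(
    {RGAClass.TNL, RGAClass.CNL, RGAClass.RNL, RGAClass.RLK, RGAClass.RLP, RGAClass.LYSM}
)

DEFAULT_WINDOW_BP = 200_000


@dataclass(frozen=True)
class Cluster:
    subgenome: str
    chromosome: str
    members: tuple[str, ...]  # gene IDs ordered by start
    span_start: int
    span_end: int
    classes: frozenset[RGAClass]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a cluster needs >= 2 members")

    @property
    def size(self) -> int:
        return len(self.members)


def detect_clusters(
    genes: Sequence[GeneRecord],
    classes: Mapping[str, RGAClass],
    window: int = DEFAULT_WINDOW_BP,
    same_class_only: bool = False,
) -> list[Cluster]:
    """Chain classified genes into physical clusters per chromosome.

    Only genes with a class in :data:`CLUSTERABLE` participate.  With
    ``same_class_only`` chains are class-homogeneous.  Input order does not
    matter (genes are sorted internally); output is deterministic.
    """
    if window <= 0:
        raise ValueError(f"window must be positive, got {window}")

    by_chrom: dict[tuple[str, str], list[GeneRecord]] = {}
    for g in genes:
        cls = classes.get(g.gene_id)
        if cls in CLUSTERABLE:
            by_chrom.setdefault((g.subgenome, g.chromosome), []).append(g)

    clusters: list[Cluster] = []
    for (sub, chrom) in sorted(by_chrom):
        members = by_chrom[(sub, chrom)]
        if members != sorted(members, key=lambda g: (g.start, g.end, g.gene_id)):
            log.warning("genes on %s/%s not sorted by start; sorting internally", sub, chrom)
        members = sorted(members, key=lambda g: (g.start, g.end, g.gene_id))

        chain: list[GeneRecord] = []
        chain_end = 0
        chain_cls: RGAClass | None = None

        def flush() -> None:
            if len(chain) >= 2:
                clusters.append(
                    Cluster(
                        subgenome=sub,
                        chromosome=chrom,
                        members=tuple(g.gene_id for g in chain),
                        span_start=chain[0].start,
                        span_end=max(g.end for g in chain),
                        classes=frozenset(classes[g.gene_id] for g in chain),
                    )
                )

        for g in members:
            gap = g.start - chain_end  # <= 0 for overlapping genes
            joins = bool(chain) and gap <= window
            if joins and same_class_only and classes[g.gene_id] != chain_cls:
                joins = False
            if not joins:
                flush()
                chain = []
                chain_cls = classes[g.gene_id]
            chain.append(g)
            chain_end = max(chain_end if chain[:-1] else 0, g.end)
        flush()
    return clusters


@dataclass(frozen=True)
class ClusterReport:
    n_clusters: Mapping[str, int]  # per subgenome
    n_clustered_genes: Mapping[str, int]
    shared_class_chromosomes: tuple[tuple[str, str], ...]  # (class, chromosome)


def cluster_report(clusters: Iterable[Cluster]) -> ClusterReport:
    """Aggregate cluster counts and flag classes clustered on the same
    chromosome in both subgenomes (e.g. a shared RPW8-NB-LRR cluster)."""
    clusters = list(clusters)
    n_clusters: dict[str, int] = {}
    n_genes: dict[str, int] = {}
    where: dict[tuple[str, str], set[str]] = {}  # (class, chrom) -> subgenomes
    for c in clusters:
        n_clusters[c.subgenome] = n_clusters.get(c.subgenome, 0) + 1
        n_genes[c.subgenome] = n_genes.get(c.subgenome, 0) + c.size
        for cls in c.classes:
            where.setdefault((cls.value, c.chromosome), set()).add(c.subgenome)
    shared = tuple(sorted(k for k, subs in where.items() if len(subs) >= 2))
    for cls, chrom in shared:
        log.info("class %s forms clusters on %s in both subgenomes", cls, chrom)
    return ClusterReport(
        n_clusters=n_clusters, n_clustered_genes=n_genes, shared_class_chromosomes=shared
    )
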