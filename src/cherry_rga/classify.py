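"""RGA classification from domain architectures and per-subgenome counting.

The decision tree maps any non-empty canonical domain set to exactly one
class.  NB-ARC-bearing architectures are NB-LRR candidates: with leucine-rich
repeats present they are typed by their N-terminal domain (TIR > RPW8 > CC
precedence when several co-occur), otherwise they stay partial.  Without
NB-ARC, a lysin motif plus a transmembrane helix makes a LysM receptor;
LRR + TM + kinase a receptor-like kinase (RLK); LRR + TM without kinase a
receptor-like protein (RLP).  A signal peptide is recorded as evidence but
never required.  The five NB-LRR/receptor classes TNL, CNL, RNL, RLK and RLP
count as "complete" architectures.

Splice variants of one gene are collapsed to the gene's best-supported class
(TNL > RNL > CNL > RLK > RLP > LYSM > PARTIAL), so counts are per gene, not
per transcript.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

import pandas as pd

from cherry_rga.domains import CanonicalDomain, TranscriptDomains
from cherry_rga.ids import DEFAULT_ID_PATTERN, subgenome_of, transcript_to_gene

log = logging.getLogger(__name__)

D = CanonicalDomain


class RGAClass(str, Enum):
    TNL = "TNL"    # TIR-NB-LRR
    CNL = "CNL"    # CC-NB-LRR
    RNL = "RNL"    # RPW8-NB-LRR
    RLK = "RLK"    # receptor-like kinase
    RLP = "RLP"    # receptor-like protein
    LYSM = "LYSM"  # LysM receptor
    PARTIAL = "PARTIAL"
    UNCLASSIFIED = "UNCLASSIFIED"


#: Classes whose architecture is a full resistance-protein layout.
COMPLETE_CLASSES = frozenset({RGAClass.TNL, RGAClass.CNL, RGAClass.RNL, RGAClass.RLK, RGAClass.RLP})

#: Gene-collapse priority, most to least specific.
CLASS_PRIORITY = (
    RGAClass.TNL,
    RGAClass.RNL,
    RGAClass.CNL,
    RGAClass.RLK,
    RGAClass.RLP,
    RGAClass.LYSM,
    RGAClass.PARTIAL,
    RGAClass.UNCLASSIFIED,
)
_PRIORITY_RANK = {c: i for i, c in enumerate(CLASS_PRIORITY)}


@dataclass(frozen=True)
class TranscriptClassification:
    transcript_id: str
    rga_class: RGAClass
    complete: bool
    domains: frozenset[CanonicalDomain]

    def __post_init__(self) -> None:
        if self.complete != (self.rga_class in COMPLETE_CLASSES):
            raise ValueError("complete flag inconsistent with class")


def classify_transcript(td: TranscriptDomains) -> TranscriptClassification:
    """Assign the RGA class of one transcript from its canonical domain set."""
    d = td.domains
    if not d:
        raise ValueError(f"transcript {td.transcript_id} has an empty domain set")
    if D.NB in d:
        if D.TIR in d:
            cls = RGAClass.TNL if D.LRR in d else RGAClass.PARTIAL
            if D.RPW8 in d or D.CC in d:
                log.debug("N-terminal precedence TIR>RPW8>CC applied to %s", td.transcript_id)
        elif D.RPW8 in d:
            cls = RGAClass.RNL if D.LRR in d else RGAClass.PARTIAL
            if D.CC in d:
                log.debug("N-terminal precedence RPW8>CC applied to %s", td.transcript_id)
        elif D.CC in d:
            cls = RGAClass.CNL if D.LRR in d else RGAClass.PARTIAL
        else:
            cls = RGAClass.PARTIAL
    elif D.LYSM in d and D.TM in d:
        cls = RGAClass.LYSM
    elif D.LRR in d and D.TM in d:
        cls = RGAClass.RLK if D.KIN in d else RGAClass.RLP
    else:
        cls = RGAClass.PARTIAL
    return TranscriptClassification(
        transcript_id=td.transcript_id,
        rga_class=cls,
        complete=cls in COMPLETE_CLASSES,
        domains=d,
    )


def collapse_genes(
    classifications: Iterable[TranscriptClassification],
    id_pattern: str = DEFAULT_ID_PATTERN,
) -> dict[str, RGAClass]:
    """Collapse splice-variant classifications to one class per gene.

    The gene takes the highest-priority class among its transcripts; a gene is
    complete if any transcript is.
    """
    gene_class: dict[str, RGAClass] = {}
    for tc in classifications:
        gid = transcript_to_gene(tc.transcript_id, id_pattern)
        prev = gene_class.get(gid)
        if prev is None or _PRIORITY_RANK[tc.rga_class] < _PRIORITY_RANK[prev]:
            gene_class[gid] = tc.rga_class
    return gene_class


def completeness_percentage(n_complete: int, n_any_domain: int) -> float:
    """Share of domain-bearing transcripts with a complete architecture, in %
    rounded to one decimal (the convention the headline counts use)."""
    if n_any_domain <= 0:
        return 0.0
    return round(100.0 * n_complete / n_any_domain, 1)


@dataclass(frozen=True)
class CountsTable:
    """Per-subgenome gene counts by class plus transcript-level totals."""

    gene_counts: Mapping[str, Mapping[RGAClass, int]]
    n_any_domain: Mapping[str, int]
    n_complete: Mapping[str, int]
    pct_complete: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sub, total in self.n_any_domain.items():
            if self.n_complete.get(sub, 0) > total:
                raise ValueError(f"n_complete > n_any_domain in subgenome {sub}")

    def to_frame(self) -> pd.DataFrame:
        """Classes as rows, subgenomes as columns (the bar-chart layout)."""
        subs = sorted(self.gene_counts)
        data = {
            sub: [self.gene_counts[sub].get(c, 0) for c in CLASS_PRIORITY] for sub in subs
        }
        return pd.DataFrame(data, index=[c.value for c in CLASS_PRIORITY])


def count_by_class(
    gene_classes: Mapping[str, RGAClass],
    transcript_classifications: Iterable[TranscriptClassification] = (),
) -> CountsTable:
    """Tabulate gene counts per class per subgenome and transcript totals."""
    gene_counts: dict[str, dict[RGAClass, int]] = {}
    for gid, cls in gene_classes.items():
        sub = subgenome_of(gid)
        if sub == "OTHER":
            log.warning("gene %s has no recognizable subgenome; counted under OTHER", gid)
        per = gene_counts.setdefault(sub, {})
        per[cls] = per.get(cls, 0) + 1

    n_any: dict[str, int] = {}
    n_complete: dict[str, int] = {}
    for tc in transcript_classifications:
        sub = subgenome_of(tc.transcript_id)
        n_any[sub] = n_any.get(sub, 0) + 1
        if tc.complete:
            n_complete[sub] = n_complete.get(sub, 0) + 1
    for sub in gene_counts:
        n_any.setdefault(sub, 0)
        n_complete.setdefault(sub, 0)
    pct = {sub: completeness_percentage(n_complete.get(sub, 0), n_any[sub]) for sub in n_any}
    return CountsTable(
        gene_counts=gene_counts, n_any_domain=n_any, n_complete=n_complete, pct_complete=pct
    )
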