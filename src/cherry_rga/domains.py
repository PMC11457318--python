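"""Canonical resistance-protein domain calling from raw InterProScan hits.

Resistance gene analogs are recognized by a small set of diagnostic
signatures, one rule per canonical domain:

==========  ======================  =========================================
domain      source                  rule
==========  ======================  =========================================
CC          Pfam                    PF18052 (Rx-type coiled coil)
NB          Pfam                    PF00931 (NB-ARC)
TIR         Pfam                    PF01582
RPW8        Pfam                    PF05659
LRR         SUPERFAMILY             SSF52058 / SSF52047, or a signature
                                    description containing "leucine-rich
                                    repeat" (case-insensitive)
KIN         Pfam                    any signature annotated with the protein
                                    kinase activity GO term GO:0004672
TM / SP     Phobius                 TRANSMEMBRANE / SIGNAL_PEPTIDE labels
LYSM        ProSiteProfiles         InterPro accession IPR018392
==========  ======================  =========================================

Everything else is dropped.  The rules are presence/absence: repeated or
overlapping hits for a domain collapse into one evidence list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

from cherry_rga.io.interproscan import Analysis, DomainHit

log = logging.getLogger(__name__)


class CanonicalDomain(str, Enum):
    CC = "CC"      # coiled-coil N-terminus
    NB = "NB"      # NB-ARC nucleotide-binding domain
    TIR = "TIR"    # Toll/interleukin-1 receptor domain
    RPW8 = "RPW8"  # RPW8-type N-terminus
    LRR = "LRR"    # leucine-rich repeats
    KIN = "KIN"    # protein kinase domain
    TM = "TM"      # transmembrane helix
    SP = "SP"      # signal peptide
    LYSM = "LYSM"  # lysin motif


@dataclass(frozen=True)
class DomainRuleSet:
    """The identifier filters, overridable per field from a pipeline config.

    The RPW8 Pfam accession defaults to PF05659 (the Pfam RPW8 family); it is
    the one rule without a published identifier for this workflow, so its use
    is logged whenever it fires.
    """

    pfam_cc: frozenset[str] = frozenset({"PF18052"})
    pfam_nb: frozenset[str] = frozenset({"PF00931"})
    pfam_tir: frozenset[str] = frozenset({"PF01582"})
    rpw8_ids: frozenset[str] = frozenset({"PF05659"})
    superfamily_lrr: frozenset[str] = frozenset({"SSF52058", "SSF52047"})
    lrr_desc_substring: str = "leucine-rich repeat"
    kinase_go: str = "GO:0004672"
    kinase_go_all_analyses: bool = False  # widen GO:0004672 beyond Pfam rows
    phobius_tm: str = "TRANSMEMBRANE"
    phobius_sp: str = "SIGNAL_PEPTIDE"
    lysm_interpro: str = "IPR018392"

    def domains_of(self, hit: DomainHit) -> set[CanonicalDomain]:
        """Canonical domains a single hit is evidence for (usually 0 or 1)."""
        out: set[CanonicalDomain] = set()
        if hit.analysis is Analysis.PFAM:
            if hit.signature_id in self.pfam_cc:
                out.add(CanonicalDomain.CC)
            if hit.signature_id in self.pfam_nb:
                out.add(CanonicalDomain.NB)
            if hit.signature_id in self.pfam_tir:
                out.add(CanonicalDomain.TIR)
            if hit.signature_id in self.rpw8_ids:
                log.debug("RPW8 rule (%s) fired for %s", hit.signature_id, hit.transcript_id)
                out.add(CanonicalDomain.RPW8)
        if hit.analysis is Analysis.SUPERFAMILY and (
            hit.signature_id in self.superfamily_lrr
            or self.lrr_desc_substring in hit.signature_desc.lower()
        ):
            out.add(CanonicalDomain.LRR)
        if self.kinase_go in hit.go_terms and (
            hit.analysis is Analysis.PFAM or self.kinase_go_all_analyses
        ):
            out.add(CanonicalDomain.KIN)
        if hit.analysis is Analysis.PHOBIUS:
            if hit.signature_id == self.phobius_tm:
                out.add(CanonicalDomain.TM)
            elif hit.signature_id == self.phobius_sp:
                out.add(CanonicalDomain.SP)
        if hit.analysis is Analysis.PROSITE_PROFILES and hit.interpro_id == self.lysm_interpro:
            out.add(CanonicalDomain.LYSM)
        return out


@dataclass(frozen=True)
class TranscriptDomains:
    """Canonical domain set of one transcript, with the supporting hits."""

    transcript_id: str
    domains: frozenset[CanonicalDomain]
    evidence: Mapping[CanonicalDomain, tuple[DomainHit, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for d in self.domains:
            if not self.evidence.get(d):
                raise ValueError(f"domain {d.value} of {self.transcript_id} has no evidence")


def canonicalize(
    hits: Iterable[DomainHit], rules: DomainRuleSet | None = None
) -> dict[str, TranscriptDomains]:
    """Filter raw hits down to canonical domain sets per transcript.

    Pure presence/absence filter: non-matching hits are dropped and
    transcripts left with an empty domain set are omitted from the result.
    """
    rules = rules or DomainRuleSet()
    evidence: dict[str, dict[CanonicalDomain, list[DomainHit]]] = {}
    for hit in hits:
        for dom in rules.domains_of(hit):
            evidence.setdefault(hit.transcript_id, {}).setdefault(dom, []).append(hit)
    return {
        tid: TranscriptDomains(
            transcript_id=tid,
            domains=frozenset(ev),
            evidence={d: tuple(hs) for d, hs in ev.items()},
        )
        for tid, ev in evidence.items()
    }
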