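"""Best-hit annotation of classified transcripts from BLASTP tabular output.

Per query the single best hit is kept: maximal bitscore, ties broken by
higher percent identity and then by lexicographically smallest subject ID, so
the selection is deterministic and independent of input row order.  Bitscore
(not e-value) ranks hits because it does not depend on database size.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from cherry_rga.classify import RGAClass, TranscriptClassification
from cherry_rga.domains import CanonicalDomain
from cherry_rga.io.blast import BlastHit


@dataclass(frozen=True)
class BestHitRecord:
    query_id: str
    subject_id: str
    percent_identity: float
    bitscore: float
    evalue: float


def best_hits(
    hits: Iterable[BlastHit],
    min_bitscore: float | None = None,
    max_evalue: float | None = None,
) -> dict[str, BestHitRecord]:
    """Select the best hit per query.  No thresholds are applied by default;
    optional cutoffs drop whole queries whose best hit fails them."""
    best: dict[str, BlastHit] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None or _rank_key(h) < _rank_key(cur):
            best[h.query_id] = h
    out = {}
    for q, h in best.items():
        if min_bitscore is not None and h.bitscore < min_bitscore:
            continue
        if max_evalue is not None and h.evalue > max_evalue:
            continue
        out[q] = BestHitRecord(
            query_id=q,
            subject_id=h.subject_id,
            percent_identity=h.percent_identity,
            bitscore=h.bitscore,
            evalue=h.evalue,
        )
    return out


def _rank_key(h: BlastHit) -> tuple:
    return (-h.bitscore, -h.percent_identity, h.subject_id)


def reference_report(
    best: Mapping[str, BestHitRecord],
    classes: Mapping[str, TranscriptClassification],
    panel_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Table of references and the transcripts that best-hit them.

    One row per (reference, query) pair whose best subject is that reference;
    columns: reference, transcript, type, percent identity (3 decimals).  The
    type is the query's RGA class, suffixed "+LysM" when lysin-motif evidence
    coexists with a non-LysM class.  ``panel_order`` fixes the row order to
    the reference panel's; otherwise rows sort by reference then transcript.
    """
    rows = []
    for q, rec in best.items():
        tc = classes.get(q)
        if tc is None:
            type_label = RGAClass.UNCLASSIFIED.value
        else:
            type_label = tc.rga_class.value
            if tc.rga_class is not RGAClass.LYSM and CanonicalDomain.LYSM in tc.domains:
                type_label += "+LysM"
        rows.append(
            {
                "reference": rec.subject_id,
                "transcript": q,
                "type": type_label,
                "percent_identity": round(rec.percent_identity, 3),
            }
        )
    df = pd.DataFrame(rows, columns=["reference", "transcript", "type", "percent_identity"])
    if panel_order is not None:
        order = {r: i for i, r in enumerate(panel_order)}
        df["_o"] = df["reference"].map(lambda r: order.get(r, len(order)))
        df = df.sort_values(["_o", "transcript"]).drop(columns="_o")
    else:
        df = df.sort_values(["reference", "transcript"])
    return df.reset_index(drop=True)


def load_reference_panel(path: str | Path | None = None) -> pd.DataFrame:
    """Load a reference RLK/RLP panel table.

    Without a path, the packaged panel of 22 functionally characterized
    RLK/RLP reference proteins (with the sour cherry transcripts and percent
    identities reported for the 'Schattenmorelle' assembly) is returned.
    Columns: reference, transcript, type, percent_identity.
    """
    if path is None:
        ref = resources.files("cherry_rga.data").joinpath("reference_rlk_rlp_panel.tsv")
        with resources.as_file(ref) as p:
            return pd.read_csv(p, sep="\t")
    return pd.read_csv(path, sep="\t")
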