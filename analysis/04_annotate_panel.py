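#!/usr/bin/env python
"""Best-hit annotation against the 22-reference RLK/RLP panel.

Builds a BLAST tabular file whose planted dominant hits are the published
panel rows (reference protein, sour cherry transcript, percent identity),
runs best-hit selection (max bitscore, identity and subject-ID tie-breaks)
and writes the resulting report, confirming the 18 distinct transcripts and
the top identities (Pti1 83.728%, PBS1 81.699%).
"""

from pathlib import Path

import numpy as np

from cherry_rga.annotate import best_hits, load_reference_panel, reference_report
from cherry_rga.io import write_blast_tab
from cherry_rga.synthetic import planted_blast_table

SEED = 20240
RES = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    panel = load_reference_panel()
    rng = np.random.default_rng(SEED)
    best_per_query: dict[str, tuple[str, float]] = {}
    for row in panel.itertuples(index=False):
        q, r, p = row.transcript, row.reference, float(row.percent_identity)
        if q not in best_per_query or p > best_per_query[q][1]:
            best_per_query[q] = (r, p)
    rows, truth = planted_blast_table(
        [(q, r, p) for q, (r, p) in best_per_query.items()],
        rng,
        decoy_subjects=tuple(panel["reference"]),
    )
    blast_path = RES / "panel_blast.tsv"
    RES.mkdir(exist_ok=True)
    write_blast_tab(rows, blast_path)

    best = best_hits(rows)
    table = reference_report(best, {}, panel_order=list(panel["reference"]))
    out = RES / "panel_best_hits.tsv"
    table.to_csv(out, sep="\t", index=False, float_format="%.3f")

    recovered = all(best[q].subject_id == s for q, (s, _) in truth.items())
    top = table.loc[table["percent_identity"].idxmax()]
    print(f"panel: {len(panel)} references, {panel['transcript'].nunique()} distinct transcripts")
    print(f"planted dominant hits recovered for all queries: {recovered}")
    print(f"highest identity: {top['transcript']} -> {top['reference']} "
          f"({top['percent_identity']:.3f}%)")
    print(f"wrote {blast_path} and {out}")


if __name__ == "__main__":
    main()
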