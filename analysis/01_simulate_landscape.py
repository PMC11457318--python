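#!/usr/bin/env python
"""Generate the study-scale synthetic RGA landscape.

Plants the published per-class gene counts of the two sour cherry subgenomes
(A = *P. avium*-like, F = *P. fruticosa*-like), 16 + 18 physical clusters
with an RPW8-NB-LRR pair on chromosome 7 of each subgenome, splice variants,
partial genes and decoys, then emits the standard input files
(InterProScan TSV, GFF3, aligned NB-LRR FASTA, BLAST tabular) under
results/landscape/ together with the ground-truth tables.
"""

from pathlib import Path

from cherry_rga.synthetic import SyntheticConfig, generate

SEED = 20240
OUT = Path(__file__).resolve().parent.parent / "results" / "landscape"


def main() -> None:
    ds = generate(SyntheticConfig.landscape(seed=SEED))
    paths = ds.write(OUT)

    truth = OUT / "truth_gene_classes.tsv"
    with open(truth, "w") as fh:
        fh.write("gene_id\trga_class\n")
        for gid in sorted(ds.truth_gene_class):
            fh.write(f"{gid}\t{ds.truth_gene_class[gid].value}\n")

    n_tx = sum(len(g.transcript_ids) for g in ds.genes)
    print(f"planted {len(ds.genes)} genes ({n_tx} transcripts), "
          f"{len(ds.truth_clusters)} clusters, {len(ds.hits)} annotation rows")
    for k, p in paths.items():
        print(f"  {k}: {p}")
    print(f"  truth: {truth}")


if __name__ == "__main__":
    main()
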