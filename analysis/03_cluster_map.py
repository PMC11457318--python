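#!/usr/bin/env python
"""Physical cluster detection and the chromosome map.

Chains classified genes within a 200 kb window per chromosome, reports the
per-subgenome cluster counts, flags classes that cluster on the same
chromosome in both subgenomes (the RPW8-NB-LRR signal on chromosome 7), and
writes the MapChart input file.
"""

from pathlib import Path

from cherry_rga.classify import CLASS_PRIORITY, RGAClass
from cherry_rga.clusters import cluster_report, detect_clusters
from cherry_rga.io import read_gff3, write_mapchart
from cherry_rga.ids import transcript_to_gene

RES = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    genes = read_gff3(RES / "landscape" / "genes.gff3")
    gene_classes = {}
    for line in (RES / "classes.tsv").read_text().splitlines()[1:]:
        tid, cls, _ = line.split("\t")
        gid = transcript_to_gene(tid)
        cand = RGAClass(cls)
        prev = gene_classes.get(gid)
        if prev is None or CLASS_PRIORITY.index(cand) < CLASS_PRIORITY.index(prev):
            gene_classes[gid] = cand

    clusters = detect_clusters(genes, gene_classes, window=200_000)
    report = cluster_report(clusters)

    out = RES / "clusters.tsv"
    with open(out, "w") as fh:
        fh.write("subgenome\tchromosome\tn_genes\tspan_start\tspan_end\tclasses\tmembers\n")
        for c in clusters:
            fh.write(
                f"{c.subgenome}\t{c.chromosome}\t{c.size}\t{c.span_start}\t{c.span_end}\t"
                f"{','.join(sorted(x.value for x in c.classes))}\t{','.join(c.members)}\n"
            )
    write_mapchart(
        genes, {g: c.value for g, c in gene_classes.items()}, clusters, RES / "mapchart.txt"
    )

    print(f"clusters (>=2 genes) per subgenome: {dict(report.n_clusters)}")
    shared = [x for x in report.shared_class_chromosomes]
    print(f"classes clustering on the same chromosome in both subgenomes: {shared}")
    print(f"wrote {out} and {RES / 'mapchart.txt'}")


if __name__ == "__main__":
    main()
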