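"""End-to-end orchestration: scan -> classify -> clusters -> annotate -> tree.

A single YAML (or in-memory) config drives the run; every stage writes its
table under the output directory and the run ends with a JSON manifest
recording parameters, seed, per-file SHA-256 checksums and the package
version, so identical config + inputs + seed give byte-identical outputs.
Stages whose inputs are absent are skipped with a log message.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

import cherry_rga
from cherry_rga.annotate import best_hits, load_reference_panel, reference_report
from cherry_rga.classify import (
    classify_transcript,
    collapse_genes,
    count_by_class,
)
from cherry_rga.clusters import DEFAULT_WINDOW_BP, cluster_report, detect_clusters
from cherry_rga.domains import DomainRuleSet, canonicalize
from cherry_rga.io.blast import read_blast_tab
from cherry_rga.io.gff import read_gff3
from cherry_rga.io.interproscan import read_interproscan
from cherry_rga.io.itol import write_itol_colors
from cherry_rga.io.mapchart import write_mapchart
from cherry_rga.io.msa import read_alignment
from cherry_rga.io.trees import write_newick_file
from cherry_rga.phylo import PhyloConfig, bootstrap_support, midpoint_root

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Input paths (any may be None -> the dependent stage is skipped) plus
    the tunables of each stage."""

    out_dir: Path
    interproscan: Path | None = None
    gff3: Path | None = None
    alignment: Path | None = None
    blast: Path | None = None
    reference_panel: Path | None = None
    rules: DomainRuleSet = field(default_factory=DomainRuleSet)
    cluster_window: int = DEFAULT_WINDOW_BP
    same_class_only: bool = False
    phylo: PhyloConfig = field(default_factory=PhyloConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "out_dir" not in raw:
            raise ValueError("pipeline config needs an out_dir")
        kwargs: dict = {"out_dir": Path(raw["out_dir"])}
        for key in ("interproscan", "gff3", "alignment", "blast", "reference_panel"):
            if raw.get(key):
                kwargs[key] = Path(raw[key])
        if "rules" in raw:
            r = dict(raw["rules"])
            for k in ("pfam_cc", "pfam_nb", "pfam_tir", "rpw8_ids", "superfamily_lrr"):
                if k in r:
                    r[k] = frozenset(r[k])
            kwargs["rules"] = DomainRuleSet(**r)
        if "cluster_window" in raw:
            kwargs["cluster_window"] = int(raw["cluster_window"])
        if "same_class_only" in raw:
            kwargs["same_class_only"] = bool(raw["same_class_only"])
        if "phylo" in raw:
            kwargs["phylo"] = PhyloConfig(**raw["phylo"])
        return cls(**kwargs)


def run_all(config: PipelineConfig) -> dict:
    """Run every stage whose inputs exist; return the manifest dict (also
    written to ``<out_dir>/manifest.json``)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": cherry_rga.__version__,
        "parameters": {
            "rules": _jsonable(dataclasses.asdict(config.rules)),
            "cluster_window": config.cluster_window,
            "same_class_only": config.same_class_only,
            "phylo": dataclasses.asdict(config.phylo),
        },
        "seed": config.phylo.seed,
        "stages": {},
    }

    classifications = {}
    gene_classes = {}

    # --- scan + classify ---------------------------------------------------
    domains_tsv = out / "domains.tsv"
    classes_tsv = out / "classes.tsv"
    counts_tsv = out / "counts.tsv"
    if config.interproscan is not None:
        try:
            hits = read_interproscan(config.interproscan)
            per_transcript = canonicalize(hits, config.rules)
            classifications = {
                tid: classify_transcript(td) for tid, td in per_transcript.items()
            }
            gene_classes = collapse_genes(classifications.values())
            counts = count_by_class(gene_classes, classifications.values())

            with open(domains_tsv, "w") as fh:
                fh.write("transcript_id\tdomains\n")
                for tid in sorted(per_transcript):
                    doms = ",".join(sorted(d.value for d in per_transcript[tid].domains))
                    fh.write(f"{tid}\t{doms}\n")
            with open(classes_tsv, "w") as fh:
                fh.write("transcript_id\trga_class\tcomplete\n")
                for tid in sorted(classifications):
                    tc = classifications[tid]
                    fh.write(f"{tid}\t{tc.rga_class.value}\t{int(tc.complete)}\n")
            counts.to_frame().to_csv(counts_tsv, sep="\t", index_label="rga_class")
            manifest["stages"]["classify"] = {
                "outputs": _checksums(domains_tsv, classes_tsv, counts_tsv),
                "n_transcripts": len(classifications),
                "n_genes": len(gene_classes),
                "pct_complete": dict(counts.pct_complete),
            }
        except Exception as exc:  # noqa: BLE001
            _fail("classify", exc, domains_tsv, classes_tsv, counts_tsv)
    else:
        log.info("no InterProScan input; scan/classify skipped")
        manifest["stages"]["classify"] = "skipped"

    # --- clusters ----------------------------------------------------------
    clusters_tsv = out / "clusters.tsv"
    map_txt = out / "mapchart.txt"
    if config.gff3 is not None and gene_classes:
        try:
            genes = read_gff3(config.gff3)
            clusters = detect_clusters(
                genes, gene_classes, window=config.cluster_window,
                same_class_only=config.same_class_only,
            )
            report = cluster_report(clusters)
            with open(clusters_tsv, "w") as fh:
                fh.write("subgenome\tchromosome\tn_genes\tspan_start\tspan_end\tclasses\tmembers\n")
                for c in clusters:
                    fh.write(
                        f"{c.subgenome}\t{c.chromosome}\t{c.size}\t{c.span_start}\t"
                        f"{c.span_end}\t{','.join(sorted(x.value for x in c.classes))}\t"
                        f"{','.join(c.members)}\n"
                    )
            write_mapchart(
                genes, {g: c.value for g, c in gene_classes.items()}, clusters, map_txt
            )
            manifest["stages"]["clusters"] = {
                "outputs": _checksums(clusters_tsv, map_txt),
                "n_clusters": dict(report.n_clusters),
                "shared_class_chromosomes": [list(x) for x in report.shared_class_chromosomes],
            }
        except Exception as exc:  # noqa: BLE001
            _fail("clusters", exc, clusters_tsv, map_txt)
    else:
        log.info("no GFF3 input (or no classes); cluster stage skipped")
        manifest["stages"]["clusters"] = "skipped"

    # --- annotate ----------------------------------------------------------
    table1_tsv = out / "best_hits.tsv"
    if config.blast is not None:
        try:
            blast = read_blast_tab(config.blast)
            best = best_hits(blast)
            panel_order = None
            if config.reference_panel is not None:
                panel_order = list(load_reference_panel(config.reference_panel)["reference"])
            table = reference_report(best, classifications, panel_order)
            table.to_csv(table1_tsv, sep="\t", index=False, float_format="%.3f")
            manifest["stages"]["annotate"] = {
                "outputs": _checksums(table1_tsv),
                "n_queries_with_hits": len(best),
                "n_distinct_transcripts": int(table["transcript"].nunique()),
            }
        except Exception as exc:  # noqa: BLE001
            _fail("annotate", exc, table1_tsv)
    else:
        log.info("no BLAST input; annotate stage skipped")
        manifest["stages"]["annotate"] = "skipped"

    # --- tree --------------------------------------------------------------
    tree_nwk = out / "tree.nwk"
    itol_txt = out / "itol_colors.txt"
    if config.alignment is not None:
        try:
            aln = read_alignment(config.alignment)
            tree = bootstrap_support(aln, config.phylo)
            rooted = midpoint_root(tree)
            write_newick_file(rooted, tree_nwk)
            class_map = {
                name: classifications[name].rga_class.value
                for name in aln.names
                if name in classifications
            }
            write_itol_colors(class_map, itol_txt)
            manifest["stages"]["tree"] = {
                "outputs": _checksums(tree_nwk, itol_txt),
                "n_leaves": aln.n_sequences,
                "n_bootstrap": config.phylo.n_bootstrap,
            }
        except Exception as exc:  # noqa: BLE001
            _fail("tree", exc, tree_nwk, itol_txt)
    else:
        log.info("no alignment input; tree stage skipped")
        manifest["stages"]["tree"] = "skipped"

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _fail(stage: str, exc: Exception, *outputs: Path) -> None:
    """Keep any half-written outputs of the failing stage under a .partial
    suffix, then abort naming the stage."""
    for p in outputs:
        if p.exists():
            p.rename(p.with_name(p.name + ".partial"))
    raise StageError(f"stage {stage!r} failed: {exc}") from exc


def _checksums(*paths: Path) -> dict[str, str]:
    return {p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in paths}


def _jsonable(obj):
    if isinstance(obj, frozenset):
        return sorted(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    return obj
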