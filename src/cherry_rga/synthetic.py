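"""Ground-truth-labeled synthetic inputs for every pipeline stage.

The generator plants a resistance-gene landscape on a pair of subgenomes —
genes of known RGA class with splice variants, physical clusters versus
isolated genes, decoys with irrelevant domains — and emits the files the real
analysis consumes (InterProScan TSV, GFF3, aligned protein FASTA, BLAST
tabular), together with truth tables.  Canonicalizing and classifying the
emitted annotation must recover every planted label exactly at zero noise;
cluster detection must recover the planted partition whenever the window lies
between the intra- and inter-cluster gaps; NJ on the evolved alignment must
recover the true topology at low substitution rates.

Sequences are proteins over the 20-letter alphabet evolved by uniform
per-site substitution without indels, which keeps p-distance expectations
analytic.  Defaults are desk-sized; :meth:`SyntheticConfig.landscape` scales
the planted gene counts and cluster numbers to the published sour cherry
landscape.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from skbio import TreeNode

from cherry_rga import reference
from cherry_rga.classify import RGAClass
from cherry_rga.domains import CanonicalDomain
from cherry_rga.io.blast import BlastHit, write_blast_tab
from cherry_rga.io.gff import GeneRecord, write_gff3
from cherry_rga.io.interproscan import Analysis, DomainHit, write_interproscan_tsv
from cherry_rga.io.msa import Alignment, write_alignment
from cherry_rga.io.trees import write_newick_file

log = logging.getLogger(__name__)

D = CanonicalDomain
C = RGAClass

AMINO_ACIDS = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype=np.uint8)

#: Domain layout each class is built from (the first variant of a gene).
CLASS_DOMAINS: Mapping[RGAClass, frozenset[CanonicalDomain]] = {
    C.TNL: frozenset({D.TIR, D.NB, D.LRR}),
    C.CNL: frozenset({D.CC, D.NB, D.LRR}),
    C.RNL: frozenset({D.RPW8, D.NB, D.LRR}),
    C.RLK: frozenset({D.LRR, D.TM, D.KIN}),
    C.RLP: frozenset({D.LRR, D.TM}),
    C.LYSM: frozenset({D.LYSM, D.TM}),
}

#: Domains whose loss turns the class into PARTIAL (truncation menu).
_TRUNCATABLE: Mapping[RGAClass, tuple[CanonicalDomain, ...]] = {
    C.TNL: (D.TIR, D.NB, D.LRR),
    C.CNL: (D.CC, D.NB, D.LRR),
    C.RNL: (D.RPW8, D.NB, D.LRR),
    C.RLK: (D.LRR, D.TM),
    C.RLP: (D.LRR, D.TM),
    C.LYSM: (D.LYSM, D.TM),
}

#: Architectures planted for PARTIAL genes (all map to PARTIAL).
_PARTIAL_MENU: tuple[frozenset[CanonicalDomain], ...] = (
    frozenset({D.NB}),
    frozenset({D.NB, D.LRR}),
    frozenset({D.TIR, D.NB}),
    frozenset({D.LRR}),
    frozenset({D.TM}),
    frozenset({D.KIN}),
    frozenset({D.LRR, D.KIN}),
)

_DEFAULT_BLAST_REFERENCES = tuple(f"REF_RLKRLP_{i:02d}" for i in range(1, 13))


@dataclass(frozen=True)
class ClusterSpec:
    """One planted physical cluster of >= 2 clusterable genes."""

    subgenome: str
    size: int = 2
    chromosome: str | None = None  # None: assigned round-robin
    rga_class: RGAClass | None = None  # None: drawn from the remaining pool

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ValueError("planted clusters need >= 2 genes")


def _default_chromosomes() -> dict[str, dict[str, int]]:
    return {
        "A": {"Chro1": 8_000_000, "Chro7": 8_000_000},
        "F": {"Chro1": 8_000_000, "Chro7": 8_000_000},
    }


def _default_class_counts() -> dict[str, dict[RGAClass, int]]:
    per = {C.TNL: 3, C.CNL: 3, C.RNL: 2, C.RLK: 4, C.RLP: 3, C.LYSM: 2}
    return {"A": dict(per), "F": dict(per)}


def _default_clusters() -> tuple[ClusterSpec, ...]:
    return (
        ClusterSpec("A", 2, "Chro7", C.RNL),
        ClusterSpec("A", 3),
        ClusterSpec("A", 2),
        ClusterSpec("F", 2, "Chro7", C.RNL),
        ClusterSpec("F", 3),
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Everything the generator needs; all sizes/rates in one place.

    ``intra_cluster_gap`` must stay below ``inter_gene_gap`` so that a
    detection window between the two recovers the planted clusters exactly.
    """

    seed: int = 20240
    chromosomes: Mapping[str, Mapping[str, int]] = field(default_factory=_default_chromosomes)
    class_counts: Mapping[str, Mapping[RGAClass, int]] = field(
        default_factory=_default_class_counts
    )
    n_partial: Mapping[str, int] = field(default_factory=lambda: {"A": 2, "F": 2})
    n_decoy: Mapping[str, int] = field(default_factory=lambda: {"A": 2, "F": 2})
    clusters: tuple[ClusterSpec, ...] = field(default_factory=_default_clusters)
    splice_variants: tuple[int, int] = (1, 3)  # uniform inclusive range per gene
    truncated_variant_prob: float = 0.35
    intra_cluster_gap: int = 50_000  # bp, max gap inside a planted cluster
    inter_gene_gap: int = 500_000  # bp, min gap between clusterable neighbors
    gene_length: tuple[int, int] = (3_000, 6_000)
    filler_gap: int = 15_000  # spacing of partial/decoy genes
    filler_margin: int = 25_000  # clearance around clusterable genes
    max_tree_taxa: int = 60
    seq_length: int = 300
    branch_length_range: tuple[float, float] = (0.02, 0.10)
    blast_references: tuple[str, ...] = _DEFAULT_BLAST_REFERENCES

    def __post_init__(self) -> None:
        if self.intra_cluster_gap >= self.inter_gene_gap:
            raise ValueError("intra-cluster gap must be smaller than the inter-gene gap")
        for sub, counts in self.class_counts.items():
            if any(v < 0 for v in counts.values()):
                raise ValueError(f"negative class count in subgenome {sub}")

    @classmethod
    def landscape(cls, seed: int = 20240) -> "SyntheticConfig":
        """Study-scale configuration: the published per-class gene counts of
        the two sour cherry subgenomes, 16 + 18 planted clusters with an
        RPW8-NB-LRR cluster on chromosome 7 of each subgenome."""
        rng = np.random.default_rng(seed)
        chroms = {
            sub: {f"Chro{i}": 42_000_000 for i in range(1, 9)} for sub in ("A", "F")
        }
        clusters: list[ClusterSpec] = []
        for sub, n in reference.CLUSTER_COUNTS.items():
            clusters.append(ClusterSpec(sub, 2, reference.SHARED_RNL_CLUSTER_CHROMOSOME, C.RNL))
            for _ in range(n - 1):
                clusters.append(ClusterSpec(sub, int(rng.integers(2, 5))))
        return cls(
            seed=seed,
            chromosomes=chroms,
            class_counts={s: dict(c) for s, c in reference.GENE_COUNTS.items()},
            n_partial={"A": 600, "F": 600},
            n_decoy={"A": 300, "F": 300},
            clusters=tuple(clusters),
        )


@dataclass
class _GenePlan:
    subgenome: str
    rga_class: RGAClass | None  # None: decoy (no canonical domains at all)
    cluster_id: int | None = None
    partial_domains: frozenset[CanonicalDomain] | None = None
    chromosome: str = ""
    start: int = 0
    end: int = 0
    strand: str = "+"
    gene_id: str = ""


@dataclass
class SyntheticDataset:
    """Planted ground truth plus everything needed to emit the input files."""

    config: SyntheticConfig
    genes: list[GeneRecord]
    hits: list[DomainHit]
    blast: list[BlastHit]
    alignment: Alignment | None
    true_tree: TreeNode | None
    truth_gene_class: dict[str, RGAClass]  # decoys absent
    truth_transcript_class: dict[str, RGAClass]
    truth_transcript_domains: dict[str, frozenset[CanonicalDomain]]
    truth_clusters: list[frozenset[str]]  # partition of planted cluster members
    truth_best_hits: dict[str, tuple[str, float]]  # query -> (subject, pident)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit the standard-format files; returns stage-name -> path."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "interproscan": outdir / "interproscan.tsv",
            "gff3": outdir / "genes.gff3",
            "blast": outdir / "blast.tsv",
        }
        write_interproscan_tsv(self.hits, paths["interproscan"])
        write_gff3(self.genes, paths["gff3"])
        write_blast_tab(self.blast, paths["blast"])
        if self.alignment is not None:
            paths["alignment"] = outdir / "nblrr_alignment.faa"
            write_alignment(self.alignment, paths["alignment"])
        if self.true_tree is not None:
            paths["true_tree"] = outdir / "true_tree.nwk"
            write_newick_file(self.true_tree, paths["true_tree"])
        return paths


# ---------------------------------------------------------------------------
# generation


def generate(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Generate a complete labeled dataset from ``config`` (deterministic per
    seed)."""
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)

    plans = _plan_genes(config, rng)
    _place_genes(plans, config, rng)
    genes, truth_gene_class, truth_clusters = _materialize_genes(plans, config, rng)

    hits: list[DomainHit] = []
    truth_t_class: dict[str, RGAClass] = {}
    truth_t_domains: dict[str, frozenset[CanonicalDomain]] = {}
    for plan, gene in zip(plans, genes):
        for tid in gene.transcript_ids:
            dset, tcls = _transcript_architecture(
                plan, rng, first=tid.endswith(".1"), trunc_prob=config.truncated_variant_prob
            )
            if dset is not None:
                truth_t_domains[tid] = dset
                truth_t_class[tid] = tcls
                hits.extend(_emit_domain_hits(tid, dset, rng))
            hits.extend(_emit_noise_hits(tid, rng))

    alignment, true_tree = _evolve_alignment(truth_t_class, config, rng)
    blast, truth_best = _plant_blast(truth_t_class, config, rng)

    return SyntheticDataset(
        config=config,
        genes=genes,
        hits=hits,
        blast=blast,
        alignment=alignment,
        true_tree=true_tree,
        truth_gene_class=truth_gene_class,
        truth_transcript_class=truth_t_class,
        truth_transcript_domains=truth_t_domains,
        truth_clusters=truth_clusters,
        truth_best_hits=truth_best,
    )


def fixture_small(seed: int = 20240) -> SyntheticDataset:
    """The deterministic mini-dataset used across the test suite (~40 genes,
    2 subgenomes x 2 chromosomes)."""
    return generate(SyntheticConfig(seed=seed))


def _plan_genes(config: SyntheticConfig, rng: np.random.Generator) -> list[_GenePlan]:
    plans: list[_GenePlan] = []
    cluster_id = 0
    for sub in sorted(config.chromosomes):
        pool: dict[RGAClass, int] = dict(config.class_counts.get(sub, {}))
        sub_plans: list[_GenePlan] = []

        # clusters first: they consume genes from the class pool
        for spec in config.clusters:
            if spec.subgenome != sub:
                continue
            cluster_id += 1
            for k in range(spec.size):
                if spec.rga_class is not None:
                    cls = spec.rga_class
                else:  # draw the currently most abundant class (deterministic)
                    avail = [c for c, n in sorted(pool.items(), key=lambda kv: kv[0].value) if n > 0]
                    if not avail:
                        raise ValueError(f"cluster spec exceeds class pool in subgenome {sub}")
                    cls = max(avail, key=lambda c: (pool[c], c.value))
                if pool.get(cls, 0) <= 0:
                    raise ValueError(
                        f"cluster spec needs a {cls.value} gene but the pool is empty ({sub})"
                    )
                pool[cls] -= 1
                sub_plans.append(_GenePlan(sub, cls, cluster_id=cluster_id))
        # isolated clusterable genes
        for cls in sorted(pool, key=lambda c: c.value):
            sub_plans.extend(_GenePlan(sub, cls) for _ in range(pool[cls]))
        # partial genes with a fixed planted architecture
        for _ in range(config.n_partial.get(sub, 0)):
            arch = _PARTIAL_MENU[int(rng.integers(len(_PARTIAL_MENU)))]
            sub_plans.append(_GenePlan(sub, C.PARTIAL, partial_domains=arch))
        # decoys carry no canonical domain at all
        sub_plans.extend(_GenePlan(sub, None) for _ in range(config.n_decoy.get(sub, 0)))
        plans.extend(sub_plans)
    return plans


def _place_genes(plans: list[_GenePlan], config: SyntheticConfig, rng: np.random.Generator) -> None:
    """Assign chromosome + coordinates in place.

    Clusterable genes (complete classes + LysM) get >= ``inter_gene_gap``
    spacing except inside planted clusters; partial/decoy genes fill the wide
    gaps so they never join (or bridge) a cluster.
    """
    lo_len, hi_len = config.gene_length
    for sub in sorted(config.chromosomes):
        chrom_names = sorted(config.chromosomes[sub])
        sub_plans = [p for p in plans if p.subgenome == sub]

        # items: one per cluster, one per isolated clusterable gene
        items: list[list[_GenePlan]] = []
        by_cluster: dict[int, list[_GenePlan]] = {}
        for p in sub_plans:
            if p.cluster_id is not None:
                by_cluster.setdefault(p.cluster_id, []).append(p)
            elif p.rga_class in CLASS_DOMAINS:
                items.append([p])
        # pin clusters to their configured chromosome (cluster ids were
        # assigned in spec order, so the sorted ids align with the specs)
        pinned: dict[str, list[list[_GenePlan]]] = {c: [] for c in chrom_names}
        floating: list[list[_GenePlan]] = []
        ordered_specs = [s for s in config.clusters if s.subgenome == sub]
        for spec, cid in zip(ordered_specs, sorted(by_cluster)):
            members = by_cluster[cid]
            if spec.chromosome is not None:
                if spec.chromosome not in pinned:
                    raise ValueError(f"unknown chromosome {spec.chromosome} in cluster spec")
                pinned[spec.chromosome].append(members)
            else:
                floating.append(members)

        order = rng.permutation(len(items)).tolist()
        items = [items[i] for i in order]
        per_chrom: dict[str, list[list[_GenePlan]]] = {c: list(pinned[c]) for c in chrom_names}
        for i, members in enumerate(floating):
            per_chrom[chrom_names[i % len(chrom_names)]].append(members)
        for i, item in enumerate(items):
            per_chrom[chrom_names[i % len(chrom_names)]].append(item)

        filler_queue = [
            p for p in sub_plans if p.cluster_id is None and p.rga_class not in CLASS_DOMAINS
        ]
        forder = rng.permutation(len(filler_queue)).tolist()
        filler_queue = [filler_queue[i] for i in forder]  # mix partial and decoy genes

        filler_idx = 0
        for chrom in chrom_names:
            chrom_len = config.chromosomes[sub][chrom]
            blocks = per_chrom[chrom]
            border = rng.permutation(len(blocks)).tolist()
            blocks = [blocks[i] for i in border]
            cursor = 150_000 + int(rng.integers(0, 100_000))
            placed_spans: list[tuple[int, int]] = []
            for block in blocks:
                for k, p in enumerate(block):
                    if k > 0:
                        cursor += int(rng.integers(2_000, config.intra_cluster_gap + 1))
                    length = int(rng.integers(lo_len, hi_len + 1))
                    p.chromosome = chrom
                    p.start = cursor
                    p.end = cursor + length - 1
                    p.strand = "+" if rng.random() < 0.5 else "-"
                    placed_spans.append((p.start, p.end))
                    cursor = p.end + 1
                cursor += config.inter_gene_gap + int(rng.integers(0, 100_000))
            if placed_spans and placed_spans[-1][1] > chrom_len:
                raise ValueError(
                    f"infeasible placement: {sub}/{chrom} needs {placed_spans[-1][1]} bp "
                    f"but is {chrom_len} bp long"
                )
            # drop fillers into the wide gaps, clear of clusterable genes
            gaps: list[tuple[int, int]] = []
            prev_end = 50_000
            for s, e in placed_spans + [(chrom_len - 50_000, chrom_len)]:
                lo = prev_end + config.filler_margin
                hi = s - config.filler_margin
                if hi - lo > hi_len:
                    gaps.append((lo, hi))
                prev_end = e
            for lo, hi in gaps:
                pos = lo
                while filler_idx < len(filler_queue) and pos + hi_len < hi:
                    p = filler_queue[filler_idx]
                    length = int(rng.integers(2_000, 4_001))
                    p.chromosome = chrom
                    p.start = pos
                    p.end = pos + length - 1
                    p.strand = "+" if rng.random() < 0.5 else "-"
                    filler_idx += 1
                    pos = p.end + 1 + config.filler_gap
                if filler_idx >= len(filler_queue):
                    break
        if filler_idx < len(filler_queue):
            raise ValueError(
                f"infeasible placement: {len(filler_queue) - filler_idx} partial/decoy genes "
                f"did not fit on subgenome {sub}"
            )


def _materialize_genes(
    plans: list[_GenePlan], config: SyntheticConfig, rng: np.random.Generator
) -> tuple[list[GeneRecord], dict[str, RGAClass], list[frozenset[str]]]:
    lo_v, hi_v = config.splice_variants
    genes: list[GeneRecord] = []
    truth_gene: dict[str, RGAClass] = {}
    cluster_members: dict[int, set[str]] = {}

    plans.sort(key=lambda p: (p.subgenome, p.chromosome, p.start))
    counter: dict[tuple[str, str], int] = {}
    for p in plans:
        key = (p.subgenome, p.chromosome)
        counter[key] = counter.get(key, 0) + 1
        p.gene_id = f"PCE_{p.subgenome}_{p.chromosome}G{counter[key] * 100:07d}"
        n_var = int(rng.integers(lo_v, hi_v + 1))
        tids = tuple(f"{p.gene_id}.{k}" for k in range(1, n_var + 1))
        genes.append(
            GeneRecord(
                gene_id=p.gene_id,
                subgenome=p.subgenome,
                chromosome=p.chromosome,
                start=p.start,
                end=p.end,
                strand=p.strand,
                transcript_ids=tids,
            )
        )
        if p.rga_class is not None:
            truth_gene[p.gene_id] = p.rga_class
        if p.cluster_id is not None:
            cluster_members.setdefault(p.cluster_id, set()).add(p.gene_id)
    truth_clusters = [frozenset(m) for _, m in sorted(cluster_members.items())]
    return genes, truth_gene, truth_clusters


def _transcript_architecture(
    plan: _GenePlan, rng: np.random.Generator, first: bool, trunc_prob: float = 0.35
) -> tuple[frozenset[CanonicalDomain] | None, RGAClass]:
    """Domain set and truth class of one splice variant (None for decoys)."""
    if plan.rga_class is None:
        return None, C.UNCLASSIFIED
    if plan.rga_class is C.PARTIAL:
        return plan.partial_domains, C.PARTIAL
    base = set(CLASS_DOMAINS[plan.rga_class])
    # receptors may additionally carry a signal peptide (never required)
    if plan.rga_class in (C.RLK, C.RLP, C.LYSM) and rng.random() < 0.5:
        base.add(D.SP)
    if not first and rng.random() < trunc_prob:
        lost = _TRUNCATABLE[plan.rga_class][int(rng.integers(len(_TRUNCATABLE[plan.rga_class])))]
        base.discard(lost)
        return frozenset(base), C.PARTIAL
    return frozenset(base), plan.rga_class


# signature templates per canonical domain
_DOMAIN_ROWS = {
    D.CC: (Analysis.PFAM, "PF18052", "Rx N-terminal CC domain", "", (1, 120)),
    D.NB: (Analysis.PFAM, "PF00931", "NB-ARC domain", "IPR002182", (160, 470)),
    D.TIR: (Analysis.PFAM, "PF01582", "TIR domain", "IPR000157", (1, 150)),
    D.RPW8: (Analysis.PFAM, "PF05659", "RPW8 domain", "IPR008808", (1, 140)),
    D.KIN: (
        Analysis.PFAM,
        "PF07714",
        "Protein tyrosine and serine/threonine kinase",
        "IPR001245",
        (620, 900),
    ),
    D.TM: (Analysis.PHOBIUS, "TRANSMEMBRANE", "Region of a membrane-bound protein", "", (560, 582)),
    D.SP: (Analysis.PHOBIUS, "SIGNAL_PEPTIDE", "Signal peptide region", "", (1, 24)),
    D.LYSM: (Analysis.PROSITE_PROFILES, "PS51782", "LysM domain profile", "IPR018392", (40, 90)),
}

_NOISE_ROWS = (
    (Analysis.PFAM, "PF00067", "Cytochrome P450", "IPR001128", ()),
    (Analysis.PFAM, "PF07690", "Major facilitator superfamily", "IPR011701", ()),
    (Analysis.SUPERFAMILY, "SSF48371", "ARM repeat", "IPR016024", ()),
    (Analysis.PHOBIUS, "CYTOPLASMIC_DOMAIN", "Region of a membrane-bound protein", "", ()),
    (Analysis.PROSITE_PROFILES, "PS50011", "Protein kinase domain profile", "IPR000719", ()),
    (Analysis.OTHER, "PTHR24420", "Panther family", "", ()),
)


def _emit_domain_hits(
    tid: str, domains: frozenset[CanonicalDomain], rng: np.random.Generator
) -> list[DomainHit]:
    hits = []
    for dom in sorted(domains, key=lambda d: d.value):
        if dom is D.LRR:
            # exercise both LRR rules: accession match or description substring
            if rng.random() < 0.25:
                sig, desc = "SSF12345", "Plant leucine-rich repeat-like domain"
            else:
                sig = "SSF52058" if rng.random() < 0.5 else "SSF52047"
                desc = "Leucine-rich repeat domain superfamily"
            start = 480 + int(rng.integers(0, 40))
            hits.append(
                DomainHit(
                    transcript_id=tid,
                    analysis=Analysis.SUPERFAMILY,
                    signature_id=sig,
                    signature_desc=desc,
                    start=start,
                    end=start + int(rng.integers(200, 420)),
                    interpro_id="IPR032675",
                )
            )
            continue
        analysis, sig, desc, ipr, (lo, hi) = _DOMAIN_ROWS[dom]
        start = lo + int(rng.integers(0, 20))
        go = frozenset({"GO:0004672", "GO:0005524"}) if dom is D.KIN else frozenset()
        hits.append(
            DomainHit(
                transcript_id=tid,
                analysis=analysis,
                signature_id=sig,
                signature_desc=desc,
                start=start,
                end=max(start, hi) + int(rng.integers(0, 15)),
                interpro_id=ipr,
                go_terms=go,
            )
        )
    return hits


def _emit_noise_hits(tid: str, rng: np.random.Generator) -> list[DomainHit]:
    hits = []
    for _ in range(int(rng.integers(0, 3))):
        analysis, sig, desc, ipr, _ = _NOISE_ROWS[int(rng.integers(len(_NOISE_ROWS)))]
        start = 1 + int(rng.integers(0, 500))
        hits.append(
            DomainHit(
                transcript_id=tid,
                analysis=analysis,
                signature_id=sig,
                signature_desc=desc,
                start=start,
                end=start + int(rng.integers(30, 300)),
                interpro_id=ipr,
            )
        )
    return hits


# ---------------------------------------------------------------------------
# alignment evolved down a known tree


def random_binary_tree(names: Sequence[str], rng: np.random.Generator,
                       branch_length_range: tuple[float, float] = (0.02, 0.10)) -> TreeNode:
    """Random rooted binary tree over ``names`` with uniform branch lengths."""
    lo, hi = branch_length_range
    nodes = [TreeNode(name=n) for n in names]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False).tolist())
        a, b = nodes[i], nodes[j]
        a.length = float(rng.uniform(lo, hi))
        b.length = float(rng.uniform(lo, hi))
        parent = TreeNode(children=[a, b])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    return nodes[0]


def evolve_alignment(tree: TreeNode, seq_length: int, rng: np.random.Generator) -> Alignment:
    """Evolve a protein alignment down ``tree``: each branch substitutes every
    site independently with probability equal to the branch length (uniform
    replacement among the other 19 residues); no indels."""
    root_seq = AMINO_ACIDS[rng.integers(0, 20, size=seq_length)]
    rows: dict[str, str] = {}

    def descend(node: TreeNode, seq: np.ndarray) -> None:
        for child in node.children:
            p = min(max(child.length or 0.0, 0.0), 0.95)
            mutate = rng.random(seq_length) < p
            new = seq.copy()
            if mutate.any():
                # uniform among the 19 other residues
                repl = AMINO_ACIDS[rng.integers(0, 20, size=int(mutate.sum()))]
                cur = new[mutate]
                clash = repl == cur
                while clash.any():
                    repl[clash] = AMINO_ACIDS[rng.integers(0, 20, size=int(clash.sum()))]
                    clash = repl == cur
                new[mutate] = repl
            if child.is_tip():
                rows[child.name] = bytes(new).decode("ascii")
            else:
                descend(child, new)

    descend(tree, root_seq)
    names = tuple(t.name for t in tree.tips())
    return Alignment(names=names, rows=tuple(rows[n] for n in names))


def _evolve_alignment(
    truth_t_class: Mapping[str, RGAClass],
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> tuple[Alignment | None, TreeNode | None]:
    nblrr = sorted(
        t for t, c in truth_t_class.items() if c in (C.TNL, C.CNL, C.RNL)
    )
    if len(nblrr) < 3:
        log.warning("fewer than 3 NB-LRR transcripts; no alignment generated")
        return None, None
    if len(nblrr) > config.max_tree_taxa:
        pick = rng.choice(len(nblrr), size=config.max_tree_taxa, replace=False)
        nblrr = sorted(nblrr[i] for i in pick)
    tree = random_binary_tree(nblrr, rng, config.branch_length_range)
    aln = evolve_alignment(tree, config.seq_length, rng)
    return aln, tree


# ---------------------------------------------------------------------------
# planted BLAST table


def _plant_blast(
    truth_t_class: Mapping[str, RGAClass],
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> tuple[list[BlastHit], dict[str, tuple[str, float]]]:
    queries = sorted(t for t, c in truth_t_class.items() if c in (C.RLK, C.RLP))
    refs = config.blast_references
    if not queries or not refs:
        return [], {}
    planted = [
        (q, refs[i % len(refs)], float(np.round(rng.uniform(28.0, 88.0), 3)))
        for i, q in enumerate(queries)
    ]
    return planted_blast_table(planted, rng, decoy_subjects=refs)


def planted_blast_table(
    planted: Sequence[tuple[str, str, float]],
    rng: np.random.Generator,
    decoy_subjects: Sequence[str] = (),
) -> tuple[list[BlastHit], dict[str, tuple[str, float]]]:
    """Build a BLAST outfmt-6 table with a strictly dominant planted best hit
    per query plus lower-scoring decoy hits.

    ``planted`` rows are (query, subject, percent_identity).  Returns the hit
    rows (shuffled) and the truth map query -> (subject, identity).
    """
    hits: list[BlastHit] = []
    truth: dict[str, tuple[str, float]] = {}
    for q, subj, pid in planted:
        best_score = float(np.round(rng.uniform(180.0, 420.0), 1))
        truth[q] = (subj, pid)
        hits.append(_blast_row(q, subj, pid, best_score, rng))
        others = [s for s in decoy_subjects if s != subj]
        for _ in range(int(rng.integers(1, 4))):
            if not others:
                break
            s = others[int(rng.integers(len(others)))]
            score = best_score - float(np.round(rng.uniform(5.0, 80.0), 1))
            dpid = max(10.0, pid - float(np.round(rng.uniform(1.0, 15.0), 3)))
            hits.append(_blast_row(q, s, dpid, max(score, 25.0), rng))
    order = rng.permutation(len(hits)).tolist()
    return [hits[i] for i in order], truth


def _blast_row(
    q: str, subj: str, pid: float, score: float, rng: np.random.Generator
) -> BlastHit:
    score = round(score, 1)
    alen = int(rng.integers(150, 500))
    mism = int(round(alen * (1.0 - pid / 100.0)))
    qstart = int(rng.integers(1, 40))
    sstart = int(rng.integers(1, 40))
    return BlastHit(
        query_id=q,
        subject_id=subj,
        percent_identity=round(pid, 3),
        align_length=alen,
        mismatches=min(mism, alen),
        gap_opens=int(rng.integers(0, 5)),
        qstart=qstart,
        qend=qstart + alen - 1,
        sstart=sstart,
        send=sstart + alen - 1,
        evalue=float(10.0 ** -rng.integers(20, 120)),
        bitscore=score,
    )
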