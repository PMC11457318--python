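"""The generator: label recovery, cluster recovery, file validity, goldens."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from cherry_rga import reference
from cherry_rga.classify import RGAClass as C
from cherry_rga.classify import classify_transcript, collapse_genes, count_by_class
from cherry_rga.clusters import detect_clusters
from cherry_rga.domains import canonicalize
from cherry_rga.io import read_blast_tab, read_gff3, read_interproscan
from cherry_rga.io.msa import read_alignment
from cherry_rga.io.trees import read_newick_file
from cherry_rga.phylo import nj_tree, p_distance_matrix
from cherry_rga.synthetic import ClusterSpec, SyntheticConfig, fixture_small, generate

GOLDEN = Path(__file__).parent / "golden"


def _classify_dataset(ds):
    per = canonicalize(ds.hits)
    tcs = {t: classify_transcript(td) for t, td in per.items()}
    return per, tcs, collapse_genes(tcs.values())


@pytest.mark.parametrize("seed", range(20))
def test_label_recovery_over_seeds(seed):
    """classify(canonicalize(emitted annotation)) reproduces every planted
    transcript domain set, transcript class and gene class, for 20 seeds."""
    rng = np.random.default_rng(seed)
    per_sub = {
        cls: int(rng.integers(0, 5))
        for cls in (C.TNL, C.CNL, C.RNL, C.RLK, C.RLP, C.LYSM)
    }
    per_sub[C.RNL] = max(per_sub[C.RNL], 2)  # keep the pinned cluster feasible
    cfg = SyntheticConfig(
        seed=seed,
        class_counts={"A": dict(per_sub), "F": dict(per_sub)},
        n_partial={"A": int(rng.integers(0, 4)), "F": 1},
        n_decoy={"A": 1, "F": int(rng.integers(0, 4))},
        clusters=(ClusterSpec("A", 2, "Chro7", C.RNL),),
    )
    ds = generate(cfg)
    per, tcs, genes = _classify_dataset(ds)
    assert {t: td.domains for t, td in per.items()} == dict(ds.truth_transcript_domains)
    assert {t: x.rga_class for t, x in tcs.items()} == dict(ds.truth_transcript_class)
    assert genes == dict(ds.truth_gene_class)
    # per-class gene counts equal the planted counts exactly
    counts = count_by_class(genes, tcs.values())
    for sub in ("A", "F"):
        for cls, expected in per_sub.items():
            assert counts.gene_counts.get(sub, {}).get(cls, 0) == expected


def test_cluster_recovery_when_window_between_gaps(small_dataset):
    cfg = small_dataset.config
    _, _, genes = _classify_dataset(small_dataset)
    for window in (cfg.intra_cluster_gap, 200_000, cfg.inter_gene_gap - 1):
        found = detect_clusters(small_dataset.genes, genes, window=window)
        assert {frozenset(c.members) for c in found} == set(small_dataset.truth_clusters)


def test_emitted_files_reparse_to_truth(small_files, small_dataset):
    hits = read_interproscan(small_files["interproscan"])
    assert hits == small_dataset.hits
    genes = read_gff3(small_files["gff3"])
    assert set(genes) == set(small_dataset.genes)
    blast = read_blast_tab(small_files["blast"])
    assert {(h.query_id, h.subject_id, h.bitscore) for h in blast} == {
        (h.query_id, h.subject_id, h.bitscore) for h in small_dataset.blast
    }
    aln = read_alignment(small_files["alignment"])
    assert aln == small_dataset.alignment
    tree = read_newick_file(small_files["true_tree"])
    assert {t.name for t in tree.tips()} == set(small_dataset.alignment.names)


def _splits(tree):
    names = frozenset(t.name for t in tree.tips())
    out = set()
    for node in tree.non_tips(include_self=False):
        s = frozenset(t.name for t in node.tips())
        if 1 < len(s) < len(names) - 1 or 1 < len(names - s) < len(names) - 1:
            out.add(min(s, names - s, key=lambda f: tuple(sorted(f))))
    return out


def test_nj_recovers_true_topology_at_low_rate():
    rng_cfg = SyntheticConfig(seed=99, branch_length_range=(0.01, 0.04), seq_length=2000)
    ds = generate(rng_cfg)
    mine = nj_tree(p_distance_matrix(ds.alignment))
    assert _splits(mine) == _splits(ds.true_tree)


def test_infeasible_placement_raises():
    cfg = SyntheticConfig(
        chromosomes={"A": {"Chro1": 900_000}, "F": {"Chro1": 900_000}},
        clusters=(),
    )
    with pytest.raises(ValueError, match="infeasible"):
        generate(cfg)


def test_landscape_config_mirrors_published_counts():
    ds = generate(SyntheticConfig.landscape(seed=1))
    _, tcs, genes = _classify_dataset(ds)
    counts = count_by_class(genes, tcs.values())
    for sub, per_class in reference.GENE_COUNTS.items():
        for cls, expected in per_class.items():
            assert counts.gene_counts[sub][cls] == expected
    found = detect_clusters(ds.genes, genes)
    per_sub = {}
    for c in found:
        per_sub[c.subgenome] = per_sub.get(c.subgenome, 0) + 1
    assert per_sub == reference.CLUSTER_COUNTS


class TestFixtureGoldens:
    def test_fixture_counts_match_golden(self, small_dataset):
        _, tcs, genes = _classify_dataset(small_dataset)
        frame = count_by_class(genes, tcs.values()).to_frame()
        expected = (GOLDEN / "fixture_counts.tsv").read_text()
        assert frame.to_csv(sep="\t", index_label="rga_class") == expected

    def test_fixture_tree_matches_golden(self, small_dataset):
        from cherry_rga.io.trees import write_newick

        tree = nj_tree(p_distance_matrix(small_dataset.alignment))
        expected = (GOLDEN / "fixture_tree.nwk").read_text().strip()
        assert write_newick(tree) == expected

    def test_fixture_completeness_matches_golden(self, small_dataset):
        _, tcs, genes = _classify_dataset(small_dataset)
        counts = count_by_class(genes, tcs.values())
        expected = (GOLDEN / "fixture_pct_complete.txt").read_text().split()
        assert [f"{counts.pct_complete[s]:.1f}" for s in ("A", "F")] == expected

    def test_regeneration_is_deterministic(self, small_dataset):
        again = fixture_small()
        assert again.genes == small_dataset.genes
        assert again.hits == small_dataset.hits
        assert again.alignment == small_dataset.alignment
        assert again.truth_gene_class == small_dataset.truth_gene_class
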