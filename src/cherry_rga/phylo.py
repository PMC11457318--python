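"""Distance-based phylogeny of RGA proteins: p-distances, neighbor-joining,
bootstrap supports, midpoint rooting.

The distance model is the proportion of differing amino acids over comparable
sites (p-distance).  Sites gapped or ambiguous ('X') in either sequence of a
pair are excluded under pairwise deletion (the default); complete deletion
drops any column with a gap/'X' in any sequence.  Trees are built with the
Saitou–Nei neighbor-joining agglomeration, which recovers the true tree
exactly whenever the input distances are additive.  Branch supports come from
the standard nonparametric bootstrap: alignment columns are resampled with
replacement, the tree is rebuilt, and each internal edge of the original tree
is labelled with the percentage of replicates containing its leaf
bipartition.  All tie-breaks (Q-matrix minima, the midpoint path) are
lexicographic on taxon names, so every result is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from skbio import DistanceMatrix, TreeNode

from cherry_rga.io.msa import Alignment

log = logging.getLogger(__name__)

_EXCLUDED = frozenset(b"-X")


@dataclass(frozen=True)
class PhyloConfig:
    """Knobs of the tree-building stage.

    ``n_bootstrap`` is the number of column-resampling replicates (0 disables
    supports); ``gap_handling`` is ``"pairwise"`` or ``"complete"`` deletion.
    """

    n_bootstrap: int = 1000
    seed: int = 42
    gap_handling: str = "pairwise"

    def __post_init__(self) -> None:
        if self.n_bootstrap < 0:
            raise ValueError("n_bootstrap must be >= 0")
        if self.gap_handling not in ("pairwise", "complete"):
            raise ValueError(f"unknown gap handling {self.gap_handling!r}")


# ---------------------------------------------------------------------------
# distances


def p_distance_matrix(aln: Alignment, gap_handling: str = "pairwise") -> DistanceMatrix:
    """Pairwise p-distances of an aligned protein set.

    Raises if some pair shares no comparable site (its distance would be
    undefined), naming the pair.
    """
    if aln.n_sequences < 2:
        raise ValueError("need at least 2 sequences")
    arr = aln.to_array()
    valid = ~(np.isin(arr, np.frombuffer(b"-X", dtype=np.uint8)))
    if gap_handling == "complete":
        keep = valid.all(axis=0)
        arr = arr[:, keep]
        valid = valid[:, keep]
    elif gap_handling != "pairwise":
        raise ValueError(f"unknown gap handling {gap_handling!r}")

    n = aln.n_sequences
    d = np.zeros((n, n))
    fv = valid.astype(np.float64)
    # comparable sites per pair
    comp = fv @ fv.T
    for i in range(n):
        both = valid[i] & valid
        diff = (arr[i] != arr) & both
        d[i] = diff.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(comp > 0, d / np.maximum(comp, 1), np.nan)
    np.fill_diagonal(d, 0.0)
    if np.isnan(d).any():
        i, j = np.argwhere(np.isnan(d))[0]
        raise ValueError(
            f"no comparable sites between {aln.names[i]!r} and {aln.names[j]!r}"
        )
    return DistanceMatrix(d, ids=list(aln.names))


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining; returns an unrooted tree (trifurcating
    root for n >= 3).

    At each step the pair (i, j) minimizing
    ``Q(i, j) = (n - 2) d(i, j) - r_i - r_j`` (``r_i`` the row sum) is joined;
    among equal Q the lexicographically smallest sorted name pair wins.
    Negative branch lengths are clamped to zero (the deficit is logged).
    Exact on additive matrices.
    """
    d = np.asarray(dm.data, dtype=np.float64)
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix is not symmetric")
    if (d < 0).any():
        raise ValueError("negative distances")
    names = list(dm.ids)
    n = len(names)
    if n < 2:
        raise ValueError("need at least 2 taxa")

    nodes: list[TreeNode] = [TreeNode(name=nm) for nm in names]
    # lexicographic key per live node: smallest leaf name under it
    keys: list[str] = list(names)
    d = d.copy()

    if n == 2:
        half = d[0, 1] / 2.0
        for nd in nodes:
            nd.length = half
        return TreeNode(children=nodes)

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        cand = np.argwhere(np.isclose(q, qmin, rtol=0.0, atol=1e-12))
        i, j = min(
            ((int(a), int(b)) for a, b in cand if a < b),
            key=lambda ij: tuple(sorted((keys[ij[0]], keys[ij[1]]))),
        )
        dij = d[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = _clamp(li, keys[i]), _clamp(lj, keys[j])
        new = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length, nodes[j].length = li, lj

        du = 0.5 * (d[i] + d[j] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        d_new = np.empty((m - 1, m - 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = d_new[:-1, -1] = du[keep]
        d_new[-1, -1] = 0.0
        d = d_new
        nodes = [nodes[k] for k in keep] + [new]
        keys = [keys[k] for k in keep] + [min(keys[i], keys[j])]

    # terminal join: star of the last three nodes with three-point lengths
    (d01, d02, d12) = (d[0, 1], d[0, 2], d[1, 2])
    l0 = _clamp(0.5 * (d01 + d02 - d12), keys[0])
    l1 = _clamp(0.5 * (d01 + d12 - d02), keys[1])
    l2 = _clamp(0.5 * (d02 + d12 - d01), keys[2])
    for nd, ln in zip(nodes, (l0, l1, l2)):
        nd.length = ln
    return TreeNode(children=list(nodes))


def _clamp(length: float, who: str) -> float:
    if length < 0:
        log.debug("negative branch length %.3g at %s clamped to 0", length, who)
        return 0.0
    return float(length)


# ---------------------------------------------------------------------------
# bipartitions & bootstrap


def leaf_bipartitions(tree: TreeNode) -> dict[TreeNode, frozenset[str]]:
    """Map each internal (non-root) node to its bipartition, normalized to the
    side not containing the lexicographically smallest leaf."""
    all_leaves = frozenset(t.name for t in tree.tips())
    anchor = min(all_leaves)
    out: dict[TreeNode, frozenset[str]] = {}
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if anchor in side:
            side = all_leaves - side
        if 0 < len(side) < len(all_leaves) - 1:  # non-trivial splits only
            out[node] = side
    return out


def bootstrap_support(aln: Alignment, config: PhyloConfig | None = None) -> TreeNode:
    """NJ tree of the full alignment with bootstrap supports on internal edges.

    Supports are integer percentages of replicates containing each original
    bipartition, stored as internal node names (the Newick convention).
    Replicates whose resampled columns leave some pair with no comparable
    sites are discarded; more than 10% discarded is an error.
    """
    config = config or PhyloConfig()
    dm = p_distance_matrix(aln, config.gap_handling)
    tree = nj_tree(dm)
    if config.n_bootstrap == 0:
        return tree

    biparts = leaf_bipartitions(tree)
    counts = {node: 0 for node in biparts}
    rng = np.random.default_rng(config.seed)
    n_cols = aln.n_columns
    discarded = 0
    for _ in range(config.n_bootstrap):
        idx = rng.integers(0, n_cols, size=n_cols)
        try:
            rep_dm = p_distance_matrix(aln.take_columns(idx), config.gap_handling)
        except ValueError:
            discarded += 1
            continue
        rep_splits = set(leaf_bipartitions(nj_tree(rep_dm)).values())
        for node, split in biparts.items():
            if split in rep_splits:
                counts[node] += 1
    if discarded > 0.1 * config.n_bootstrap:
        raise ValueError(
            f"{discarded}/{config.n_bootstrap} bootstrap replicates had undefined distances"
        )
    if discarded:
        log.warning("discarded %d bootstrap replicates with undefined distances", discarded)
    effective = config.n_bootstrap - discarded
    for node in biparts:
        node.name = str(int(round(100.0 * counts[node] / effective)))
    return tree


# ---------------------------------------------------------------------------
# midpoint rooting


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Root at the midpoint of the longest leaf-to-leaf path.

    Ties on the path length are broken by the lexicographically smallest
    sorted leaf-name pair.  Rooting preserves all pairwise path distances.
    Integer internal-node names (bootstrap supports) stay attached to their
    bipartition across the rerooting.
    """
    tree = tree.copy()
    if len(list(tree.tips())) < 2:
        return tree
    dm = tree.tip_tip_distances()
    d = np.asarray(dm.data)
    ids = list(dm.ids)
    dmax = float(d.max())
    _names_to_supports(tree)
    if dmax <= 0:
        log.warning("all branch lengths zero; rooting on the first edge")
        first = tree.find(sorted(ids)[0])
        return _supports_to_names(first.parent.root_at(reset=True))
    cand = np.argwhere(np.isclose(d, dmax, rtol=0.0, atol=1e-12))
    pair = min(tuple(sorted((ids[int(a)], ids[int(b)]))) for a, b in cand if a != b)
    a_node = tree.find(pair[0])
    b_node = tree.find(pair[1])

    # Walk the a->b path and find the edge straddling half the path length.
    half = dmax / 2.0
    acc = 0.0
    for u, v in _path_edges(_path(a_node, b_node)):
        child = v if v.parent is u else u  # lower endpoint of this edge
        length = child.length or 0.0
        if acc + length >= half - 1e-12:
            dist_a_to_child = acc if child is u else acc + length
            x = abs(dist_a_to_child - half)  # root offset from the child end
            x = min(max(x, 0.0), length)
            if x <= 1e-12 or length == 0.0:
                target = child if not child.is_tip() else child.parent
                return _supports_to_names(tree.root_at(target, reset=True))
            return _supports_to_names(tree.root_at(child, above=x, reset=True))
        acc += length
    raise AssertionError("midpoint not located on the a-b path")  # pragma: no cover


def _names_to_supports(tree: TreeNode) -> None:
    """Move integer internal-node names into the ``support`` branch attribute
    (scikit-bio treats it as a branch property during rerooting)."""
    for node in tree.non_tips(include_self=True):
        if node.name is not None and node.name.lstrip("-").isdigit():
            node.support = int(node.name)
            node.name = None


def _supports_to_names(tree: TreeNode) -> TreeNode:
    """Inverse of :func:`_names_to_supports`, applied after rerooting."""
    for node in tree.non_tips(include_self=True):
        support = getattr(node, "support", None)
        if support is not None:
            node.name = str(int(support))
        node.support = None
    return tree


def _path(a: TreeNode, b: TreeNode) -> list[TreeNode]:
    """Node sequence from tip a to tip b through their common ancestor."""
    a_anc = [a] + list(a.ancestors())
    seen = {id(n): i for i, n in enumerate(a_anc)}
    b_branch: list[TreeNode] = []
    node = b
    while id(node) not in seen:
        b_branch.append(node)
        node = node.parent
    return a_anc[: seen[id(node)] + 1] + b_branch[::-1]


def _path_edges(path: list[TreeNode]):
    for u, v in zip(path, path[1:]):
        yield u, v
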