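"""Newick tree input/output.

Trees are scikit-bio :class:`~skbio.TreeNode` objects throughout the package.
Integer bootstrap supports travel as internal node names, the convention MEGA
and most Newick consumers share; :func:`write_newick` and :func:`parse_newick`
round-trip topology, branch lengths and supports.
"""

from __future__ import annotations

from io import StringIO
from pathlib import Path

from skbio import TreeNode


def parse_newick(text: str) -> TreeNode:
    return TreeNode.read(StringIO(text))


def write_newick(tree: TreeNode) -> str:
    buf = StringIO()
    tree.write(buf)
    return buf.getvalue().strip()


def read_newick_file(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path))


def write_newick_file(tree: TreeNode, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(write_newick(tree) + "\n")
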