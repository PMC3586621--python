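"""Neighbour-joining tree construction, newick I/O and monophyly reports.

The agglomeration is the Saitou–Nei algorithm with the rate-corrected Q
criterion.  NJ is consistent on additive matrices: when the input distances
are exactly the path lengths of some tree, that tree (topology and branch
lengths) is recovered.  Trees are unrooted; they are represented as a
:class:`skbio.TreeNode` whose root is the final trifurcation.
"""

from __future__ import annotations

import io

import numpy as np
from skbio import TreeNode

from .alignment import InputError
from .distances import DistanceMatrix

__all__ = [
    "SaturatedMatrixError",
    "NewickParseError",
    "build_nj_tree",
    "to_newick",
    "read_newick",
    "total_branch_length",
    "leaf_clusters",
]


class SaturatedMatrixError(ValueError):
    """The distance matrix contains saturated pairs and cannot seed NJ."""

    def __init__(self, pairs):
        self.pairs = list(pairs)
        super().__init__(f"saturated pairs present: {self.pairs}")


class NewickParseError(ValueError):
    pass


def _leaf(name: str) -> TreeNode:
    node = TreeNode(name=name)
    node.raw_length = None
    return node


def _attach(parent: TreeNode, child: TreeNode, length: float, raw: float) -> None:
    child.length = float(length)
    child.raw_length = float(raw)
    parent.append(child)


def build_nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbour-joining over a distance matrix.

    Deterministic for a fixed matrix: ties in the Q criterion are broken by
    the lexicographically smallest (row, column) pair in current matrix
    order.  Negative branch lengths are clamped to zero with the deficit
    transferred to the sister branch of the same join, so each cherry's
    summed length is preserved; the unclamped value is kept on each node as
    ``raw_length``.

    Raises :class:`SaturatedMatrixError` if any pair is flagged saturated —
    substituting arbitrary large values would silently distort the tree.
    """
    n = len(dm.labels)
    if n < 3:
        raise InputError("neighbour joining needs at least 3 taxa")
    if dm.flags.any():
        raise SaturatedMatrixError(dm.saturated_pairs)

    D = dm.values.astype(float).copy()
    nodes: list[TreeNode] = [_leaf(label) for label in dm.labels]

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        # strict < keeps the lexicographically first pair on exact ties
        best, best_q = None, np.inf
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * D[i, j] - r[i] - r[j]
                if q < best_q:
                    best_q, best = q, (i, j)
        i, j = best
        li_raw = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj_raw = D[i, j] - li_raw
        li, lj = li_raw, lj_raw
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = TreeNode()
        parent.raw_length = None
        _attach(parent, nodes[i], li, li_raw)
        _attach(parent, nodes[j], lj, lj_raw)

        new_row = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D_new = np.zeros((m - 1, m - 1))
        D_new[1:, 1:] = D[np.ix_(keep, keep)]
        D_new[0, 1:] = D_new[1:, 0] = new_row[keep]
        D = D_new
        nodes = [parent] + [nodes[k] for k in keep]

    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    raw = [
        0.5 * (d01 + d02 - d12),
        0.5 * (d01 + d12 - d02),
        0.5 * (d02 + d12 - d01),
    ]
    root = TreeNode()
    root.raw_length = None
    for node, length in zip(nodes, raw):
        _attach(root, node, max(length, 0.0), length)
    return root


def total_branch_length(tree: TreeNode) -> float:
    return sum(node.length or 0.0 for node in tree.traverse() if node is not tree)


def _fmt_length(length: float, precision: int) -> str:
    text = f"{length:.{precision}f}".rstrip("0").rstrip(".")
    return text if text else "0"


def _newick_node(node: TreeNode, precision: int) -> str:
    if node.is_tip():
        label = node.name or ""
    else:
        label = "(" + ",".join(_newick_node(c, precision) for c in node.children) + ")"
        if node.name:
            label += node.name
    if node.length is not None:
        label += ":" + _fmt_length(node.length, precision)
    return label


def to_newick(tree: TreeNode, precision: int = 6) -> str:
    """Serialise to newick with branch lengths at the given precision."""
    return _newick_node(tree, precision) + ";"


def read_newick(text: str) -> TreeNode:
    """Parse a newick string; malformed input raises :class:`NewickParseError`
    naming the offending character position."""
    depth = 0
    for pos, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickParseError(f"unbalanced ')' at position {pos}")
    if depth != 0:
        raise NewickParseError(f"unbalanced '(': {depth} unclosed at end of input")
    try:
        return TreeNode.read(io.StringIO(text), format="newick")
    except Exception as exc:  # skbio raises its own format error hierarchy
        raise NewickParseError(str(exc)) from exc


def _subtree_leaf_sets(tree: TreeNode) -> list[frozenset[str]]:
    sets = []
    for node in tree.postorder():
        if node is tree:
            continue
        if node.is_tip():
            sets.append(frozenset([node.name]))
        else:
            sets.append(frozenset(tip.name for tip in node.tips()))
    return sets


def leaf_clusters(tree: TreeNode, reference_labels: dict[str, str]) -> dict[str, bool]:
    """Per-clade monophyly on an unrooted tree.

    ``reference_labels`` maps every leaf name to a clade name.  A clade is
    monophyletic when some edge of the tree separates exactly its leaves
    from all others (equivalently, the clade's leaf set or its complement
    is a subtree leaf set).  Singleton clades and a clade covering the
    whole tree are trivially monophyletic.
    """
    leaves = frozenset(tip.name for tip in tree.tips())
    missing = leaves - set(reference_labels)
    if missing:
        raise InputError(f"leaves without a clade label: {sorted(missing)}")
    clades: dict[str, set[str]] = {}
    for leaf in leaves:
        clades.setdefault(reference_labels[leaf], set()).add(leaf)
    splits = set(_subtree_leaf_sets(tree))
    report: dict[str, bool] = {}
    for clade, members in clades.items():
        members_f = frozenset(members)
        report[clade] = (
            len(members_f) == 1
            or members_f == leaves
            or members_f in splits
            or (leaves - members_f) in splits
        )
    return report
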