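"""Neighbor-joining tree construction and Newick serialization.

The Saitou-Nei agglomeration with the Studier-Keppler Q-criterion is run
to completion, leaving an unrooted binary tree represented with a single
trifurcating "root" node (the standard unrooted-Newick convention: every
internal node of the tree has degree 3).  On additive distance matrices
the algorithm recovers the generating tree exactly, topology and branch
lengths both.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .distances import DistanceMatrix
from .errors import ValidationError

__all__ = ["TreeNode", "Tree", "neighbor_joining", "to_newick", "parse_newick"]


@dataclass
class TreeNode:
    label: Optional[str] = None
    length: float = 0.0           # branch length to parent
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Tree:
    """Unrooted tree stored with a trifurcating top node.

    For >= 3 leaves every internal node has degree 3 (the top node has
    three children and no parent edge), giving 2*n_leaves - 3 edges.
    """

    root: TreeNode

    def leaves(self) -> list[TreeNode]:
        out = []

        def walk(node: TreeNode) -> None:
            if node.is_leaf:
                out.append(node)
            for child in node.children:
                walk(child)

        walk(self.root)
        return out

    def leaf_labels(self) -> list[str]:
        return [leaf.label for leaf in self.leaves()]

    def n_edges(self) -> int:
        def count(node: TreeNode) -> int:
            return len(node.children) + sum(count(c) for c in node.children)

        return count(self.root)

    def distance_matrix(self) -> DistanceMatrix:
        """Leaf-to-leaf path-length distances (for additivity checks)."""
        labels = self.leaf_labels()
        index = {lab: i for i, lab in enumerate(labels)}
        k = len(labels)
        values = np.zeros((k, k))
        done: set[tuple[int, int]] = set()

        def leaf_dists(node: TreeNode) -> dict[str, float]:
            if node.is_leaf:
                return {node.label: 0.0}
            merged: dict[str, float] = {}
            for child in node.children:
                sub = leaf_dists(child)
                for lab, d in sub.items():
                    merged[lab] = d + child.length
            for (a, da), (b, db) in itertools.combinations(merged.items(), 2):
                i, j = index[a], index[b]
                # a pair's distance is fixed where the two leaves first
                # meet, i.e. at their lowest common ancestor
                if (min(i, j), max(i, j)) not in done:
                    done.add((min(i, j), max(i, j)))
                    values[i, j] = values[j, i] = da + db
            return merged

        leaf_dists(self.root)
        return DistanceMatrix(labels=labels, values=values)


_NEEDS_QUOTING = re.compile(r"[\s()\[\]{}:;,']")


def _quote(label: str) -> str:
    if _NEEDS_QUOTING.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(tree: Tree, precision: int = 6) -> str:
    """Serialize to Newick with branch lengths; reserved characters in
    labels are single-quoted, never silently mangled."""

    def render(node: TreeNode) -> str:
        if node.is_leaf:
            body = _quote(node.label or "")
        else:
            body = "(" + ",".join(render(c) for c in node.children) + ")"
        return f"{body}:{node.length:.{precision}g}"

    return "(" + ",".join(render(c) for c in tree.root.children) + ");"


def parse_newick(text: str) -> Tree:
    """Minimal Newick reader for trees written by :func:`to_newick`."""
    text = text.strip()
    if not text.endswith(";"):
        raise ValidationError("Newick string must end with ';'")
    pos = 0

    def parse_node() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if text[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_node())
                if text[pos] == ",":
                    pos += 1
                    continue
                if text[pos] == ")":
                    pos += 1
                    break
        else:
            if text[pos] == "'":
                end = pos + 1
                label = []
                while True:
                    if text[end] == "'" and text[end + 1 : end + 2] == "'":
                        label.append("'")
                        end += 2
                    elif text[end] == "'":
                        end += 1
                        break
                    else:
                        label.append(text[end])
                        end += 1
                node.label = "".join(label)
                pos = end
            else:
                m = re.match(r"[^():,;]+", text[pos:])
                node.label = m.group(0)
                pos += m.end()
        if pos < len(text) and text[pos] == ":":
            m = re.match(r":([-+0-9.eE]+)", text[pos:])
            node.length = float(m.group(1))
            pos += m.end()
        return node

    root = TreeNode()
    if text[0] != "(":
        raise ValidationError("expected '(' at start of Newick string")
    pos = 1
    while True:
        root.children.append(parse_node())
        if text[pos] == ",":
            pos += 1
            continue
        break
    return Tree(root=root)


def neighbor_joining(d: DistanceMatrix) -> Tree:
    """Neighbor-joining tree from a symmetric, zero-diagonal distance matrix.

    Ties in the Q-criterion break to the lexicographically smallest index
    pair (row-major over the current node order), making the result
    deterministic.  Negative branch lengths are retained as computed.
    """
    k = len(d.labels)
    if k < 3:
        raise ValidationError("neighbor joining needs at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(label=lab) for lab in d.labels]
    dist = d.values.astype(float).copy()

    while len(nodes) > 3:
        m = len(nodes)
        totals = dist.sum(axis=1)
        q = (m - 2) * dist - totals[:, None] - totals[None, :]
        np.fill_diagonal(q, np.inf)
        # lexicographically smallest (i, j) among the minima
        i, j = np.unravel_index(np.argmin(np.round(q, 12)), q.shape)
        if i > j:
            i, j = j, i
        limb_i = 0.5 * dist[i, j] + (totals[i] - totals[j]) / (2.0 * (m - 2))
        limb_j = dist[i, j] - limb_i
        nodes[i].length = limb_i
        nodes[j].length = limb_j
        parent = TreeNode(children=[nodes[i], nodes[j]])
        new_row = 0.5 * (dist[i, :] + dist[j, :] - dist[i, j])
        keep = [x for x in range(m) if x not in (i, j)]
        nodes = [nodes[x] for x in keep] + [parent]
        dist = np.vstack(
            [
                np.hstack([dist[np.ix_(keep, keep)], new_row[keep, None]]),
                np.hstack([new_row[keep], [0.0]]),
            ]
        )

    # final three nodes join at the trifurcating top node; limb lengths
    # from the three-point formulas
    a, b, c = nodes
    d_ab, d_ac, d_bc = dist[0, 1], dist[0, 2], dist[1, 2]
    a.length = 0.5 * (d_ab + d_ac - d_bc)
    b.length = 0.5 * (d_ab + d_bc - d_ac)
    c.length = 0.5 * (d_ac + d_bc - d_ab)
    return Tree(root=TreeNode(children=[a, b, c]))
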