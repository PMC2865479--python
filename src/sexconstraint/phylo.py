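"""Rooted phylogenies: reading, validation, speciational form, traversal.

Trees are held as :class:`dendropy.Tree` objects wrapped in a thin
:class:`Phylogeny` that enforces the invariants the simulator relies on:
a single root, unique non-empty tip labels, and (after conversion) the
speciational form in which every non-root branch has length exactly 1 so
that evolutionary change is concentrated at speciation events.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np


class TreeError(ValueError):
    """Raised for malformed or invalid phylogenies."""


@dataclass
class BranchTable:
    """Flat, preorder-indexed view of a tree used by the simulator.

    ``parent[i]`` is the preorder index of node i's parent (-1 for the
    root, which carries no branch and receives no simulation step);
    ``tip_index[i]`` is the position of node i in ``tip_labels`` or -1
    for internal nodes.
    """

    parent: np.ndarray
    tip_index: np.ndarray
    tip_labels: list[str]

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)


class Phylogeny:
    """A validated rooted phylogeny."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._validate()

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        """Parse a single newick statement into a rooted Phylogeny.

        Missing branch lengths default to 1.  Unbalanced parentheses,
        duplicate or empty tip labels and empty input raise
        :class:`TreeError` naming the problem.
        """
        if not text or not text.strip():
            raise TreeError("empty newick input")
        stripped = text.strip()
        if not stripped.endswith(";"):
            raise TreeError("newick statement must end with ';'")
        depth = 0
        for pos, ch in enumerate(stripped):
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
                if depth < 0:
                    raise TreeError(
                        f"unbalanced parenthesis at position {pos}"
                    )
        if depth != 0:
            raise TreeError(
                f"unbalanced parentheses: {depth} unclosed '(' in input"
            )
        try:
            tree = dendropy.Tree.get(
                data=stripped,
                schema="newick",
                rooting="force-rooted",
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several error types
            raise TreeError(f"newick parse error: {exc}") from exc
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is None:
                edge.length = 1.0
        return cls(tree)

    @classmethod
    def from_file(cls, path) -> "Phylogeny":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def to_newick(self) -> str:
        s = self._tree.as_string(schema="newick", suppress_rooting=True)
        return s.strip()

    # -- validation ---------------------------------------------------

    def _validate(self) -> None:
        labels = []
        for leaf in self._tree.leaf_node_iter():
            label = leaf.taxon.label if leaf.taxon is not None else None
            if not label:
                raise TreeError("tip with empty label")
            labels.append(label)
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise TreeError(f"duplicate tip labels: {sorted(dupes)}")
        if not labels:
            raise TreeError("tree has no tips")
        for node in self._tree.preorder_node_iter():
            length = node.edge.length
            if node is not self._tree.seed_node and length is not None:
                if length < 0:
                    raise TreeError(f"negative branch length {length}")

    # -- properties ---------------------------------------------------

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def is_speciational(self) -> bool:
        """True iff every non-root branch length equals 1."""
        for node in self._tree.preorder_node_iter():
            if node is self._tree.seed_node:
                continue
            if node.edge.length != 1.0:
                return False
        return True

    # -- operations ---------------------------------------------------

    def as_speciational(self) -> "Phylogeny":
        """Return a copy with every non-root branch length set to 1.

        Topology and labels are unchanged; idempotent.  Original input
        lengths are discarded: one simulation step per branch.
        """
        clone = self._tree.clone(depth=1)
        for node in clone.preorder_node_iter():
            if node is clone.seed_node:
                node.edge.length = None
            else:
                node.edge.length = 1.0
        return Phylogeny(clone)

    def root_to_tip_order(self) -> list[dendropy.Node]:
        """Nodes in preorder: every node appears after its parent."""
        return list(self._tree.preorder_node_iter())

    def branch_table(self) -> BranchTable:
        """Preorder-indexed parent/tip arrays for vectorized simulation."""
        order = self.root_to_tip_order()
        index = {id(node): i for i, node in enumerate(order)}
        tip_labels = self.tip_labels
        tip_pos = {label: i for i, label in enumerate(tip_labels)}
        parent = np.full(len(order), -1, dtype=np.int64)
        tip_index = np.full(len(order), -1, dtype=np.int64)
        for i, node in enumerate(order):
            if node.parent_node is not None:
                parent[i] = index[id(node.parent_node)]
            if node.is_leaf():
                tip_index[i] = tip_pos[node.taxon.label]
        return BranchTable(parent=parent, tip_index=tip_index,
                           tip_labels=tip_labels)


def read_newick(text: str) -> Phylogeny:
    """Module-level convenience wrapper around Phylogeny.from_newick."""
    return Phylogeny.from_newick(text)


def as_speciational(tree: Phylogeny) -> Phylogeny:
    return tree.as_speciational()


def root_to_tip_order(tree: Phylogeny):
    return tree.root_to_tip_order()
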