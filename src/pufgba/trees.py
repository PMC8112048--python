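"""Rooted species trees and an indexed form for fast pruning.

Trees are stored as :class:`dendropy.Tree` objects; the likelihood code
works on a flat array representation (:class:`TreeIndex`) built once per
tree and cached, so repeated likelihood evaluations during optimisation
do not re-traverse the dendropy object graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = ["SpeciesTree", "TreeIndex", "NewickFormatError", "TreeValidationError"]


class NewickFormatError(ValueError):
    """Raised when Newick text cannot be parsed."""


class TreeValidationError(ValueError):
    """Raised when a parsed tree violates structural requirements."""


@dataclass
class TreeIndex:
    """Flat postorder arrays for one rooted tree.

    Nodes are numbered so that every child precedes its parent; the root
    is the last index.  ``children[i]`` lists child indices of node ``i``
    and ``edge_length[i]`` is the length of the branch above node ``i``
    (unused for the root).
    """

    n_nodes: int
    n_tips: int
    children: list[list[int]]
    edge_length: np.ndarray
    tip_index: dict[str, int]
    _levels: list | None = None

    @property
    def postorder(self) -> range:
        return range(self.n_nodes)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    def levels(self) -> list[tuple[np.ndarray, np.ndarray, int]]:
        """Internal nodes grouped by height above the tips.

        Each entry is ``(nodes, kids, n_pos)``: all ``nodes`` of one level
        can be processed together once lower levels are done.  Levels
        group nodes of equal child count ``n_pos``, and ``kids`` stacks
        the child indices position-major, i.e. ``kids.reshape(n_pos,
        len(nodes))[p]`` is the ``p``-th child of each node.
        """
        if self._levels is not None:
            return self._levels
        depth = np.zeros(self.n_nodes, dtype=int)
        groups: dict[tuple[int, int], list[int]] = {}
        for i in range(self.n_nodes):
            kids = self.children[i]
            if not kids:
                continue
            depth[i] = 1 + max(depth[c] for c in kids)
            groups.setdefault((depth[i], len(kids)), []).append(i)
        levels = []
        for (_, n_kids), nodes in sorted(groups.items()):
            kids = np.asarray([self.children[i][p] for p in range(n_kids)
                               for i in nodes])
            levels.append((np.asarray(nodes), kids, n_kids))
        self._levels = levels
        return levels


@dataclass
class SpeciesTree:
    """A rooted species tree with branch lengths and unique tip labels."""

    tree: dendropy.Tree
    defaulted_branch_lengths: int = 0
    _index: TreeIndex | None = field(default=None, repr=False, compare=False)

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree, default_length: float = 1.0) -> "SpeciesTree":
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(labels) < 2:
            raise TreeValidationError("tree must have at least 2 tips")
        dupes = {lab for lab in labels if labels.count(lab) > 1}
        if dupes:
            raise TreeValidationError(f"duplicate leaf labels: {sorted(dupes)}")
        defaulted = 0
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            if node.edge.length is None:
                node.edge.length = default_length
                defaulted += 1
            elif node.edge.length < 0:
                raise TreeValidationError(
                    f"negative branch length {node.edge.length} above node"
                )
        return cls(tree=tree, defaulted_branch_lengths=defaulted)

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def height(self) -> float:
        """Maximum root-to-tip path length."""
        return max(leaf.distance_from_root() for leaf in self.tree.leaf_node_iter())

    def scale_height(self, target: float = 1.0) -> "SpeciesTree":
        """Rescale all branch lengths so the tallest tip sits at ``target``."""
        h = self.height()
        if h <= 0:
            raise TreeValidationError("tree height is zero; cannot rescale")
        factor = target / h
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= factor
        self._index = None
        return self

    def to_newick(self) -> str:
        s = self.tree.as_string(schema="newick", suppress_rooting=True)
        return s.strip()

    def index(self) -> TreeIndex:
        """Build (or return cached) flat postorder arrays."""
        if self._index is not None:
            return self._index
        nodes = list(self.tree.postorder_node_iter())
        order = {id(node): i for i, node in enumerate(nodes)}
        children: list[list[int]] = []
        lengths = np.zeros(len(nodes))
        tip_index: dict[str, int] = {}
        n_tips = 0
        for i, node in enumerate(nodes):
            children.append([order[id(c)] for c in node.child_nodes()])
            if node.parent_node is not None:
                lengths[i] = float(node.edge.length)
            if node.is_leaf():
                tip_index[node.taxon.label] = i
                n_tips += 1
        self._index = TreeIndex(
            n_nodes=len(nodes),
            n_tips=n_tips,
            children=children,
            edge_length=lengths,
            tip_index=tip_index,
        )
        return self._index
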