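"""Rooted species trees with labelled internal nodes.

Thin wrapper around :mod:`dendropy` providing the operations the rest of
the package needs: label lookup, MRCA, leaf sets under a node, and
deterministic Newick round-trips.  Every node (leaf or internal) carries a
label; the branch subtending a node is referred to by that node's label
(e.g. the "Viridiplantae" stem is the edge above the node labelled
``Viridiplantae``).
"""

from __future__ import annotations

from typing import Iterable, Iterator

import dendropy

__all__ = ["SpeciesTree"]


def _node_label(node: dendropy.Node) -> str | None:
    if node.taxon is not None:
        return node.taxon.label
    return node.label


class SpeciesTree:
    """A rooted tree with unique node labels.

    Parameters
    ----------
    tree:
        A rooted :class:`dendropy.Tree`.  Leaf labels come from taxa;
        internal labels from ``node.label``.  Unlabelled internal nodes
        are assigned synthetic labels ``node_<i>`` in preorder.
    """

    def __init__(self, tree: dendropy.Tree):
        tree.is_rooted = True
        self._tree = tree
        self._by_label: dict[str, dendropy.Node] = {}
        counter = 0
        for node in tree.preorder_node_iter():
            label = _node_label(node)
            if label is None:
                label = f"node_{counter}"
                node.label = label
                counter += 1
            if label in self._by_label:
                raise ValueError(f"duplicate node label: {label!r}")
            self._by_label[label] = node

    # ------------------------------------------------------------------
    # construction / serialization
    # ------------------------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
        return cls(tree)

    @classmethod
    def read(cls, path) -> "SpeciesTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def to_newick(self) -> str:
        return (
            self._tree.as_string(
                schema="newick",
                suppress_rooting=True,
                unquoted_underscores=True,
                preserve_spaces=True,
            ).strip()
        )

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    # ------------------------------------------------------------------
    # queries
    # ------------------------------------------------------------------
    @property
    def root(self) -> dendropy.Node:
        return self._tree.seed_node

    def label_of(self, node: dendropy.Node) -> str:
        return _node_label(node)

    def node(self, label: str) -> dendropy.Node:
        try:
            return self._by_label[label]
        except KeyError:
            raise KeyError(f"no node labelled {label!r} in tree") from None

    def __contains__(self, label: str) -> bool:
        return label in self._by_label

    @property
    def leaf_labels(self) -> list[str]:
        return [_node_label(lf) for lf in self._tree.leaf_node_iter()]

    def leaves_under(self, label: str) -> set[str]:
        """Leaf labels of the clade rooted at ``label``."""
        node = self.node(label)
        return {_node_label(lf) for lf in node.leaf_iter()}

    def children(self, label: str) -> list[str]:
        return [_node_label(c) for c in self.node(label).child_nodes()]

    def parent(self, label: str) -> str | None:
        p = self.node(label).parent_node
        return None if p is None else _node_label(p)

    def is_leaf(self, label: str) -> bool:
        return self.node(label).is_leaf()

    def mrca(self, leaf_labels: Iterable[str]) -> str:
        """Label of the most recent common ancestor of the given leaves."""
        labels = list(leaf_labels)
        if not labels:
            raise ValueError("mrca of empty leaf set")
        if len(labels) == 1:
            return labels[0]
        taxa = [self.node(lbl).taxon for lbl in labels]
        if any(t is None for t in taxa):
            # fall back: intersect root-paths (handles internal labels)
            paths = [set(self.path_to_root(lbl)) for lbl in labels]
            shared = set.intersection(*paths)
            for lbl in self.path_to_root(labels[0]):
                if lbl in shared:
                    return lbl
            raise ValueError("disconnected labels")  # pragma: no cover
        node = self._tree.mrca(taxa=taxa)
        return _node_label(node)

    def path_to_root(self, label: str) -> list[str]:
        """Labels from ``label`` (inclusive) up to the root (inclusive)."""
        node = self.node(label)
        out = []
        while node is not None:
            out.append(_node_label(node))
            node = node.parent_node
        return out

    def preorder(self) -> Iterator[str]:
        for node in self._tree.preorder_node_iter():
            yield _node_label(node)

    def postorder(self) -> Iterator[str]:
        for node in self._tree.postorder_node_iter():
            yield _node_label(node)

    def internal_labels(self) -> list[str]:
        return [
            _node_label(n)
            for n in self._tree.preorder_node_iter()
            if not n.is_leaf()
        ]

    def __repr__(self) -> str:  # pragma: no cover
        return f"SpeciesTree({self.to_newick()!r})"
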