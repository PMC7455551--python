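"""Binary trait gain/loss mapping on a rooted species tree.

The default reconstruction is Dollo parsimony: each trait is gained at
most once — on the stem of the most recent common ancestor of all taxa
that have it — and may be lost independently on any number of branches
inside that clade.  Losses are placed on the stems of the *maximal*
all-absent subtrees, which is the unique minimal loss set for a fixed
single gain.  A Fitch mode (free gains and losses, unordered parsimony)
is available for sensitivity checks.

Branches are identified by the label of the node they subtend, e.g. a
gain on the branch above the node labelled ``Viridiplantae`` is reported
as a gain on the ``Viridiplantae`` stem.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from phycomp.trees import SpeciesTree

__all__ = [
    "TraitMatrix",
    "EventMap",
    "dollo_map",
    "fitch_map",
    "ancestral_toolbox",
    "event_table",
]


class TraitMatrix:
    """Traits × taxa boolean presence/absence matrix."""

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            dupes = data.index[data.index.duplicated()].tolist()
            raise ValueError(f"duplicate trait labels: {dupes}")
        if data.columns.has_duplicates:
            raise ValueError("duplicate taxon labels")
        self.data = data.astype(bool)

    @classmethod
    def from_dict(cls, presence: Mapping[str, Iterable[str]], taxa: Iterable[str]) -> "TraitMatrix":
        """Build from ``trait -> taxa-with-trait``, over an explicit taxon order."""
        taxa = list(taxa)
        rows = {
            trait: [t in set(present) for t in taxa]
            for trait, present in presence.items()
        }
        return cls(pd.DataFrame.from_dict(rows, orient="index", columns=taxa))

    @property
    def traits(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def taxa(self) -> list[str]:
        return self.data.columns.tolist()

    def presence(self, trait: str) -> set[str]:
        row = self.data.loc[trait]
        return set(row.index[row])

    def to_tsv(self, path) -> None:
        self.data.astype(int).to_csv(path, sep="\t", index_label="trait")

    @classmethod
    def read_tsv(cls, path) -> "TraitMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.astype(int).astype(bool))

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class EventMap:
    """Per-trait gain/loss placements plus per-node ancestral states.

    ``gains`` maps trait -> branch label (absent key under Fitch means the
    trait may have several gains, listed in ``multi_gains``).  ``losses``
    maps trait -> set of branch labels.  ``ancestral`` maps node label ->
    set of traits present at that node.
    """

    tree: SpeciesTree
    gains: dict[str, str] = field(default_factory=dict)
    losses: dict[str, set[str]] = field(default_factory=dict)
    ancestral: dict[str, set[str]] = field(default_factory=dict)
    multi_gains: dict[str, set[str]] = field(default_factory=dict)

    def gain_count(self, branch: str) -> int:
        n = sum(1 for b in self.gains.values() if b == branch)
        n += sum(1 for bs in self.multi_gains.values() if branch in bs)
        return n

    def loss_count(self, branch: str) -> int:
        return sum(1 for bs in self.losses.values() if branch in bs)

    def branch_summary(self) -> pd.DataFrame:
        branches = list(self.tree.preorder())
        return pd.DataFrame(
            {
                "gains": [self.gain_count(b) for b in branches],
                "losses": [self.loss_count(b) for b in branches],
            },
            index=pd.Index(branches, name="branch"),
        )


def dollo_map(matrix: TraitMatrix, tree: SpeciesTree) -> EventMap:
    """Map each trait onto the tree under Dollo (single-gain) parsimony.

    The gain goes on the stem of the MRCA of all presence taxa; losses go
    on the stems of maximal subtrees of that clade whose leaves all lack
    the trait.  Raises ``ValueError`` naming the trait if it is absent
    from every taxon (no gain can be placed).
    """
    leaf_set = set(tree.leaf_labels)
    unknown = set(matrix.taxa) - leaf_set
    if unknown:
        raise ValueError(f"matrix taxa not in tree: {sorted(unknown)}")

    event_map = EventMap(tree=tree)
    ancestral: dict[str, set[str]] = {lbl: set() for lbl in tree.preorder()}

    for trait in matrix.traits:
        present = matrix.presence(trait)
        if not present:
            raise ValueError(f"trait {trait!r} absent from all taxa")
        gain_node = tree.mrca(sorted(present))
        event_map.gains[trait] = gain_node

        losses = _minimal_losses(tree, gain_node, present)
        event_map.losses[trait] = losses

        # ancestral presence: nodes inside the gain clade not under a loss
        lost_under: set[str] = set()
        for loss in losses:
            lost_under |= _labels_under(tree, loss)
        for lbl in _labels_under(tree, gain_node):
            if lbl not in lost_under:
                ancestral[lbl].add(trait)

    event_map.ancestral = ancestral
    return event_map


def _labels_under(tree: SpeciesTree, label: str) -> set[str]:
    out = set()
    stack = [label]
    while stack:
        lbl = stack.pop()
        out.add(lbl)
        stack.extend(tree.children(lbl))
    return out


def _minimal_losses(tree: SpeciesTree, gain_node: str, present: set[str]) -> set[str]:
    """Stems of maximal all-absent subtrees inside the gain clade."""
    all_absent: dict[str, bool] = {}
    order = [lbl for lbl in tree.postorder() if lbl in _labels_under(tree, gain_node)]
    for lbl in order:
        kids = tree.children(lbl)
        if not kids:
            # taxa missing from the matrix are treated as absent
            all_absent[lbl] = lbl not in present
        else:
            all_absent[lbl] = all(all_absent[k] for k in kids)
    losses = set()
    for lbl in order:
        if not all_absent[lbl]:
            continue
        parent = tree.parent(lbl)
        if lbl == gain_node or (parent is not None and not all_absent.get(parent, False)):
            losses.add(lbl)
    return losses


def fitch_map(matrix: TraitMatrix, tree: SpeciesTree) -> EventMap:
    """Unordered (Fitch) parsimony mapping; gains are not restricted to one.

    Ancestral states follow the standard down-pass with ties resolved
    toward the parent state (absence at the root).  Event branches are
    edges whose endpoints disagree.
    """
    event_map = EventMap(tree=tree)
    ancestral: dict[str, set[str]] = {lbl: set() for lbl in tree.preorder()}

    parent_of = {lbl: tree.parent(lbl) for lbl in tree.preorder()}
    for trait in matrix.traits:
        present = matrix.presence(trait)
        # up-pass: state sets
        sets: dict[str, frozenset[bool]] = {}
        for lbl in tree.postorder():
            kids = tree.children(lbl)
            if not kids:
                sets[lbl] = frozenset({lbl in present})
            else:
                inter = frozenset.intersection(*(sets[k] for k in kids))
                sets[lbl] = inter if inter else frozenset.union(*(sets[k] for k in kids))
        # down-pass: resolve
        state: dict[str, bool] = {}
        for lbl in tree.preorder():
            options = sets[lbl]
            if len(options) == 1:
                state[lbl] = next(iter(options))
            else:
                parent = parent_of[lbl]
                state[lbl] = state[parent] if parent is not None else False
        gains, losses = set(), set()
        for lbl in tree.preorder():
            parent = parent_of[lbl]
            parent_state = state[parent] if parent is not None else False
            if state[lbl] and not parent_state:
                gains.add(lbl)
            elif parent_state and not state[lbl]:
                losses.add(lbl)
            if state[lbl]:
                ancestral[lbl].add(trait)
        event_map.multi_gains[trait] = gains
        event_map.losses[trait] = losses
    event_map.ancestral = ancestral
    return event_map


def ancestral_toolbox(event_map: EventMap, node: str) -> set[str]:
    """Traits inferred present at ``node``.

    A trait belongs to the toolbox iff its gain lies on or above the
    node's stem and no loss falls on the path from the root to the node.
    """
    tree = event_map.tree
    if node not in tree:
        raise KeyError(f"unknown node: {node!r}")
    return set(event_map.ancestral.get(node, set()))


def event_table(event_map: EventMap) -> pd.DataFrame:
    """Long-format table with one row per (branch, event, trait)."""
    rows = []
    for trait, branch in sorted(event_map.gains.items()):
        rows.append((branch, "gain", trait))
    for trait, branches in sorted(event_map.multi_gains.items()):
        for branch in sorted(branches):
            rows.append((branch, "gain", trait))
    for trait, branches in sorted(event_map.losses.items()):
        for branch in sorted(branches):
            rows.append((branch, "loss", trait))
    return pd.DataFrame(rows, columns=["branch", "event", "trait"])
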