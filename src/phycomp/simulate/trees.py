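"""Species-tree generation on the five-lineage backbone topology."""

from __future__ import annotations

from phycomp.simulate.config import SimConfig
from phycomp.trees import SpeciesTree

#: Default single-exemplar grouping: one leaf per major lineage.
DEFAULT_GROUPS: dict[str, list[str]] = {
    "Rhodoplantae": ["Rhodoplantae"],
    "Glaucoplantae": ["Glaucoplantae"],
    "Prasinodermophyta": ["Prasinodermophyta"],
    "Chlorophyta": ["Chlorophyta"],
    "Streptophyta": ["Streptophyta"],
}

#: Backbone ladder, outermost first.  Prasinodermophyta is sister to the
#: Chlorophyta+Streptophyta clade, which itself nests inside Viridiplantae.
_BACKBONE_ORDER = [
    "Rhodoplantae",
    "Glaucoplantae",
    "Prasinodermophyta",
]
_BACKBONE_NODE_LABELS = {
    1: "Archaeplastida",
    2: "Glauco+Viridiplantae",
    3: "Viridiplantae",
}
_CHERRY = ("Chlorophyta", "Streptophyta")
_CHERRY_LABEL = "Chlorophyta+Streptophyta"


def _clade_newick(name: str, taxa) -> str:
    taxa = list(taxa)
    if len(taxa) == 1 and taxa[0] == name:
        return _quote(name)
    if len(taxa) == 1:
        return f"({_quote(taxa[0])}){_quote(name)}"
    inner = ",".join(_quote(t) for t in taxa)
    return f"({inner}){_quote(name)}"


def _quote(label: str) -> str:
    if any(ch in label for ch in " ()[]:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def gen_species_tree(config: SimConfig | None = None) -> SpeciesTree:
    """Build the rooted backbone tree for the configured taxon groups.

    Default topology is the five-lineage ladder
    ``(Rhodoplantae,(Glaucoplantae,(Prasinodermophyta,(Chlorophyta,Streptophyta))))``
    with internal nodes labelled Archaeplastida, Glauco+Viridiplantae,
    Viridiplantae and Chlorophyta+Streptophyta.  Groups with more than one
    taxon become multi-leaf clades labelled by the group name.  The output
    is a deterministic function of the configuration (no randomness is
    involved; the seed is accepted for interface uniformity).

    Raises
    ------
    ValueError
        If fewer than 4 taxa are configured in total, or a taxon label is
        duplicated (rejected by :class:`SimConfig` itself).
    """
    if config is None:
        config = SimConfig(groups=DEFAULT_GROUPS)
    groups = dict(config.groups) or dict(DEFAULT_GROUPS)
    if len([t for v in groups.values() for t in v]) < 4:
        raise ValueError("need at least 4 taxa to build the backbone tree")
    missing = [g for g in (*_BACKBONE_ORDER, *_CHERRY) if g not in groups]
    if missing:
        raise ValueError(f"groups missing from config: {missing}")

    cherry = "({},{}){}".format(
        _clade_newick(_CHERRY[0], groups[_CHERRY[0]]),
        _clade_newick(_CHERRY[1], groups[_CHERRY[1]]),
        _quote(_CHERRY_LABEL),
    )
    newick = cherry
    for depth, group in zip((3, 2, 1), reversed(_BACKBONE_ORDER)):
        newick = "({},{}){}".format(
            _clade_newick(group, groups[group]),
            newick,
            _quote(_BACKBONE_NODE_LABELS[depth]),
        )
    return SpeciesTree.from_newick(newick + ";")


def two_taxon_tree(a: str, b: str) -> SpeciesTree:
    """Smallest rooted tree: a single cherry whose root is the MRCA."""
    if a == b:
        raise ValueError(f"duplicate taxon label: {a!r}")
    return SpeciesTree.from_newick(f"({_quote(a)},{_quote(b)})root;")
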