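"""Trait-history simulation on a tree, plus the TF/TR worked-example matrix."""

from __future__ import annotations

import numpy as np

from phycomp.simulate.config import GroundTruth
from phycomp.traits import TraitMatrix
from phycomp.trees import SpeciesTree

__all__ = ["gen_trait_history", "tf_fixture", "tf_fixture_tree", "TF_GROUP_TAXA"]


def gen_trait_history(
    tree: SpeciesTree,
    n_traits: int,
    gain_prob: float,
    loss_prob: float,
    seed: int,
    mode: str = "dollo",
) -> tuple[TraitMatrix, GroundTruth]:
    """Simulate binary trait histories and return the leaf matrix + truth.

    In the default ``dollo`` mode each trait receives exactly one gain on
    a uniformly chosen branch, followed by independent losses (probability
    ``loss_prob`` per branch strictly below the gain).  Loss placement is
    *canonical*: a loss is skipped if it would erase the trait entirely,
    confine the surviving presence to a single child of the gain node, or
    fall inside an already-lost subtree.  The planted events are therefore
    exactly the maximal-absent-subtree representation, so a correct Dollo
    mapper must recover them verbatim.

    In the opt-in ``free`` mode every branch may flip state (0→1 with
    ``gain_prob``, 1→0 with ``loss_prob``) and multiple gains per trait
    are possible; traits ending up absent from every leaf are dropped
    from the matrix and flagged under ``truth.data["all_absent"]``.
    """
    if mode not in ("dollo", "free"):
        raise ValueError(f"unknown mode: {mode!r}")
    if not (0.0 <= gain_prob <= 1.0 and 0.0 <= loss_prob <= 1.0):
        raise ValueError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    leaves = tree.leaf_labels
    labels = list(tree.preorder())

    traits: dict[str, set[str]] = {}
    truth_events: dict[str, dict] = {}
    all_absent: list[str] = []

    for i in range(n_traits):
        name = f"trait_{i:04d}"
        if mode == "dollo":
            gain = labels[int(rng.integers(len(labels)))]
            losses = _plant_dollo_losses(tree, gain, loss_prob, rng)
            present = _leaf_states(tree, gain, losses)
            truth_events[name] = {"gain": gain, "losses": sorted(losses)}
            traits[name] = present
        else:
            states = _free_history(tree, gain_prob, loss_prob, rng)
            present = {lf for lf in leaves if states[lf]}
            gains = []
            losses = []
            for lbl in labels:
                parent = tree.parent(lbl)
                pstate = states[parent] if parent is not None else False
                if states[lbl] and not pstate:
                    gains.append(lbl)
                elif pstate and not states[lbl]:
                    losses.append(lbl)
            truth_events[name] = {"gains": gains, "losses": losses}
            if not present:
                all_absent.append(name)
                continue
            traits[name] = present

    matrix = TraitMatrix.from_dict(traits, leaves)
    truth = GroundTruth(
        kind="trait_history",
        seed=seed,
        data={
            "mode": mode,
            "events": truth_events,
            "all_absent": all_absent,
        },
    )
    return matrix, truth


def _labels_under(tree: SpeciesTree, label: str) -> list[str]:
    out, stack = [], [label]
    while stack:
        lbl = stack.pop()
        out.append(lbl)
        stack.extend(tree.children(lbl))
    return out


def _leaf_states(tree: SpeciesTree, gain: str, losses: set[str]) -> set[str]:
    lost = set()
    for loss in losses:
        lost.update(_labels_under(tree, loss))
    return {
        lbl for lbl in _labels_under(tree, gain)
        if tree.is_leaf(lbl) and lbl not in lost
    }


def _plant_dollo_losses(tree: SpeciesTree, gain: str, loss_prob: float, rng) -> set[str]:
    """Sample losses below ``gain`` in canonical maximal-subtree form."""
    losses: set[str] = set()
    below = _labels_under(tree, gain)
    gain_children = tree.children(gain)
    for lbl in below:
        if lbl == gain:
            continue
        if any(lbl in _labels_under(tree, ls) for ls in losses):
            continue  # nested inside an existing loss
        if rng.random() >= loss_prob:
            continue
        candidate = losses | {lbl}
        present = _leaf_states(tree, gain, candidate)
        if not present:
            continue  # would erase the trait
        if gain_children:
            spanning = sum(
                1 for child in gain_children
                if present & set(_labels_under(tree, child))
            )
            if spanning < 2:
                continue  # survivors would no longer span the gain node
        # keep losses maximal: no ancestor strictly below the gain may end
        # up all-absent (that would merge sibling losses into its stem)
        anc = tree.parent(lbl)
        merged = False
        while anc is not None and anc != gain:
            anc_leaves = {
                l for l in _labels_under(tree, anc) if tree.is_leaf(l)
            }
            if not anc_leaves & present:
                merged = True
                break
            anc = tree.parent(anc)
        if merged:
            continue
        losses = candidate
    return losses


def _free_history(tree: SpeciesTree, gain_prob: float, loss_prob: float, rng) -> dict[str, bool]:
    states: dict[str, bool] = {}
    for lbl in tree.preorder():
        parent = tree.parent(lbl)
        pstate = states[parent] if parent is not None else False
        if pstate:
            states[lbl] = not (rng.random() < loss_prob)
        else:
            states[lbl] = rng.random() < gain_prob
    return states


# ----------------------------------------------------------------------
# TF/TR worked example (group-level presence/absence)
# ----------------------------------------------------------------------

TF_GROUP_TAXA = [
    "Rhodoplantae",
    "Glaucoplantae",
    "P. coloniale",
    "Chlorophyta",
    "Streptophyta",
]

# Named TF/TR types with group-level presence stated in the study narrative.
_VIRIDIPLANTAE_GAINS = ["C2C2-Dof", "WRKY", "SBP", "GARP_ARR-B", "TAZ"]
_LOST_IN_PRASINODERMA = ["C2H2", "C3H", "CCAAT_HAP2", "MADS_MIKC", "MBF1", "Zinc-finger-MIZ"]
_CHL_STR_GAINS = ["ABI3/VP1", "Dicer", "HD_DDT", "Pseudo ARR-B", "Whirly"]
_STREPTOPHYTA_GAINS = ["HD-ZIP_I_II", "HD-ZIP_III", "HD-PLINC", "GRF", "LUG", "SRS", "Trihelix"]
_N_ANCESTRAL = 50  # unnamed types in the ancestral Archaeplastida toolbox


def tf_fixture() -> TraitMatrix:
    """Canonical TF/TR type presence/absence matrix over the five lineages.

    Encodes group-level presence only: 55 types present in *P. coloniale*
    (50 ancestral + 5 gained on the Viridiplantae stem), 6 types lost on
    the *P. coloniale* branch, 5 gained on the Chlorophyta+Streptophyta
    stem and 7 on the Streptophyta stem.
    """
    R, G, P, C, S = TF_GROUP_TAXA
    presence: dict[str, set[str]] = {}
    for i in range(_N_ANCESTRAL):
        presence[f"ancestral_{i + 1:02d}"] = {R, G, P, C, S}
    for name in _VIRIDIPLANTAE_GAINS:
        presence[name] = {P, C, S}
    for name in _LOST_IN_PRASINODERMA:
        presence[name] = {R, G, C, S}
    for name in _CHL_STR_GAINS:
        presence[name] = {C, S}
    for name in _STREPTOPHYTA_GAINS:
        presence[name] = {S}
    return TraitMatrix.from_dict(presence, TF_GROUP_TAXA)


def tf_fixture_tree() -> SpeciesTree:
    """Collapsed five-lineage tree matching the tf_fixture taxon labels."""
    return SpeciesTree.from_newick(
        "(Rhodoplantae,(Glaucoplantae,('P. coloniale',"
        "(Chlorophyta,Streptophyta)'Chlorophyta+Streptophyta')Viridiplantae)"
        "'Glauco+Viridiplantae')Archaeplastida;"
    )
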