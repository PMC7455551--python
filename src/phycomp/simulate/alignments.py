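"""Alignments with planted clade-diagnostic columns and homoplasies.

The main alignment shows every planted column as a clean clade
diagnostic; the companion *control* alignment (same taxa plus extra
outside taxa) reveals which of them are parallelisms (clade state
re-appearing in an outside control taxon) or reversals (a clade member
reverting to the outside state) — mirroring an initial scan on a small
taxon set followed by checks against taxon-richer alignments.
"""

from __future__ import annotations

import numpy as np

from phycomp.simulate.config import GroundTruth
from phycomp.supermatrix import AlignmentBlock
from phycomp.trees import SpeciesTree

__all__ = ["gen_alignment_with_synapomorphies"]

_BASES = "ACGT"


def gen_alignment_with_synapomorphies(
    tree: SpeciesTree,
    clade_label: str,
    aln_length: int,
    n_diagnostic: int,
    n_parallel: int = 0,
    n_reversal: int = 0,
    background_rate: float = 0.0,
    seed: int = 0,
    n_control_taxa: int = 3,
) -> tuple[AlignmentBlock, AlignmentBlock, GroundTruth]:
    """Plant diagnostic/parallel/reversal columns for ``clade_label``.

    Returns ``(alignment, control_alignment, truth)``.  Truth records the
    1-based columns of each planted class.  Rejects clades of size 1
    (an autapomorphy, not a synapomorphy) and plans exceeding the
    alignment length.
    """
    clade_taxa = sorted(tree.leaves_under(clade_label))
    if len(clade_taxa) < 2:
        raise ValueError(f"clade {clade_label!r} has <2 members (autapomorphy)")
    n_planted = n_diagnostic + n_parallel + n_reversal
    if n_planted > aln_length:
        raise ValueError("planted columns exceed alignment length")
    if not 0.0 <= background_rate <= 1.0:
        raise ValueError("background_rate outside [0, 1]")

    rng = np.random.default_rng(seed)
    taxa = sorted(tree.leaf_labels)
    outside = [t for t in taxa if t not in clade_taxa]
    controls = [f"control_{i + 1}" for i in range(n_control_taxa)]

    positions = rng.permutation(aln_length)[:n_planted]
    diag_cols = sorted(int(p) for p in positions[:n_diagnostic])
    par_cols = sorted(int(p) for p in positions[n_diagnostic:n_diagnostic + n_parallel])
    rev_cols = sorted(int(p) for p in positions[n_diagnostic + n_parallel:])
    planted = set(diag_cols) | set(par_cols) | set(rev_cols)

    main = {t: [""] * aln_length for t in taxa}
    ctrl = {t: [""] * aln_length for t in taxa + controls}

    for j in range(aln_length):
        base, derived = rng.choice(4, size=2, replace=False)
        base_sym, derived_sym = _BASES[base], _BASES[derived]
        if j in planted:
            for t in taxa + controls:
                sym = derived_sym if t in clade_taxa else base_sym
                if t in taxa:
                    main[t][j] = sym
                ctrl[t][j] = sym
            if j in set(par_cols):
                # a control outsider shares the clade state
                lucky = controls[int(rng.integers(len(controls)))]
                ctrl[lucky][j] = derived_sym
            elif j in set(rev_cols):
                # a clade member reverts in the control alignment
                lucky = clade_taxa[int(rng.integers(len(clade_taxa)))]
                ctrl[lucky][j] = base_sym
        else:
            for t in taxa + controls:
                sym = base_sym
                if background_rate and rng.random() < background_rate:
                    alt = int(rng.integers(3))
                    sym = _BASES[(base + 1 + alt) % 4]
                if t in taxa:
                    main[t][j] = sym
                ctrl[t][j] = sym

    aln = AlignmentBlock(
        locus="synapomorphy_sim",
        sequences={t: "".join(main[t]) for t in taxa},
        alphabet="nt",
    )
    control = AlignmentBlock(
        locus="synapomorphy_sim_control",
        sequences={t: "".join(ctrl[t]) for t in taxa + controls},
        alphabet="nt",
    )
    truth = GroundTruth(
        kind="synapomorphy_alignment",
        seed=seed,
        data={
            "clade": clade_label,
            "clade_taxa": clade_taxa,
            "diagnostic_columns": [c + 1 for c in diag_cols],
            "parallel_columns": [c + 1 for c in par_cols],
            "reversal_columns": [c + 1 for c in rev_cols],
        },
    )
    return aln, control, truth
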