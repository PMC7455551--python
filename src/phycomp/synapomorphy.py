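"""Clade-diagnostic alignment positions and homoplasy classification.

A candidate synapomorphy is a column where every member of the focal
clade shares one unambiguous state that no outside taxon carries.
Candidates are then checked against taxon-richer control alignments: a
clade state reappearing outside the clade in any control marks a
parallelism; a clade member lacking it in a control marks a reversal;
columns clean in every covering control are non-homoplasious
synapomorphies (NHS).  Reported column coordinates are 1-based in the
original alignment frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from phycomp.supermatrix import AlignmentBlock
from phycomp.trees import SpeciesTree

__all__ = [
    "SynapomorphyRecord",
    "diagnostic_positions",
    "homoplasy_check",
    "report",
]

_NT_UNAMBIG = set("ACGT")
_AA_UNAMBIG = set("ACDEFGHIKLMNPQRSTVWY")
_GAPLIKE = set("-?.")


def _unambiguous(symbol: str, alphabet: str) -> bool:
    pool = _NT_UNAMBIG if alphabet == "nt" else _AA_UNAMBIG
    return symbol.upper() in pool


@dataclass
class SynapomorphyRecord:
    column: int  # 1-based, original alignment coordinates
    clade_state: str
    outside_states: str
    klass: str  # NHS | parallelism | reversal | ambiguous
    n_clade: int
    n_outside: int


def diagnostic_positions(
    aln: AlignmentBlock,
    tree: SpeciesTree,
    clade: str,
    strictness: float = 1.0,
) -> list[SynapomorphyRecord]:
    """Scan for columns where the clade carries a unique derived state.

    ``strictness`` is the fraction of clade rows that must carry an
    unambiguous (non-gap) symbol; at 1.0 any gap or ambiguity inside the
    clade disqualifies the column.  Outside rows with ambiguity codes are
    treated conservatively: an ambiguous outside symbol matching the
    clade state's code class blocks the candidate.  Returned records are
    candidates with class left as ``ambiguous`` pending homoplasy checks.
    """
    clade_taxa = tree.leaves_under(clade) & set(aln.taxa)
    if len(clade_taxa) < 2:
        raise ValueError(
            f"clade {clade!r} needs >=2 members in the alignment "
            f"(autapomorphies are not synapomorphies)"
        )
    outside_taxa = [t for t in aln.taxa if t not in clade_taxa]
    records: list[SynapomorphyRecord] = []
    for j in range(aln.length):
        col = aln.column(j)
        clade_syms = [col[t].upper() for t in clade_taxa]
        good = [s for s in clade_syms if _unambiguous(s, aln.alphabet)]
        if len(good) < len(clade_syms) * strictness or not good:
            continue
        states = set(good)
        if len(states) != 1:
            continue
        state = next(iter(states))
        outside_syms = {col[t].upper() for t in outside_taxa}
        # conservative: an ambiguous/gap outside symbol never certifies
        # difference unless it is an unambiguous different state
        if state in outside_syms:
            continue
        if any(not _unambiguous(s, aln.alphabet) and s not in _GAPLIKE for s in outside_syms):
            continue  # outside ambiguity code could mask the clade state
        records.append(
            SynapomorphyRecord(
                column=j + 1,
                clade_state=state,
                outside_states="".join(sorted(outside_syms - _GAPLIKE)),
                klass="ambiguous",
                n_clade=len(clade_taxa),
                n_outside=len(outside_taxa),
            )
        )
    return records


def homoplasy_check(
    candidates: list[SynapomorphyRecord],
    control_alns: list[AlignmentBlock],
    clade_taxa: set[str],
    column_maps: list[dict[int, int]] | None = None,
) -> list[SynapomorphyRecord]:
    """Classify candidate columns against control alignments.

    Controls share the candidate coordinate system unless ``column_maps``
    supplies, per control, a mapping from candidate column (1-based) to
    control column (1-based).  With no controls every candidate stays
    ``ambiguous`` (flagged, never silently dropped) and a warning is
    raised.
    """
    if not control_alns:
        import warnings

        warnings.warn("no control alignments supplied; all candidates left ambiguous")
        return [
            SynapomorphyRecord(
                r.column, r.clade_state, r.outside_states, "ambiguous", r.n_clade, r.n_outside
            )
            for r in candidates
        ]
    out: list[SynapomorphyRecord] = []
    for rec in candidates:
        klass = "NHS"
        covered = False
        for k, ctrl in enumerate(control_alns):
            if column_maps is not None:
                mapped = column_maps[k].get(rec.column)
                if mapped is None:
                    continue
                j = mapped - 1
            else:
                j = rec.column - 1
            if j >= ctrl.length:
                continue
            covered = True
            col = ctrl.column(j)
            members = [t for t in ctrl.taxa if t in clade_taxa]
            outsiders = [t for t in ctrl.taxa if t not in clade_taxa]
            state = rec.clade_state
            if any(col[t].upper() == state for t in outsiders):
                klass = "parallelism"
                break
            reverted = any(
                col[t].upper() != state and _unambiguous(col[t], ctrl.alphabet)
                for t in members
            )
            if reverted:
                klass = "reversal"
                break
        if not covered:
            klass = "ambiguous"
        out.append(
            SynapomorphyRecord(
                rec.column, rec.clade_state, rec.outside_states, klass, rec.n_clade, rec.n_outside
            )
        )
    return out


def report(records: list[SynapomorphyRecord], path=None) -> tuple[str, dict[str, int]]:
    """Render records as a TSV (sorted by column) plus per-class counts."""
    header = "column\tclade_state\toutside_states\tclass\tn_clade\tn_outside"
    lines = [header]
    summary: dict[str, int] = {}
    for rec in sorted(records, key=lambda r: r.column):
        summary[rec.klass] = summary.get(rec.klass, 0) + 1
        lines.append(
            f"{rec.column}\t{rec.clade_state}\t{rec.outside_states}\t"
            f"{rec.klass}\t{rec.n_clade}\t{rec.n_outside}"
        )
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text, summary
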