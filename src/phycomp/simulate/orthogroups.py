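"""Orthogroup-table generation with exact Venn partition control."""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from phycomp.orthogroups import OrthogroupTable
from phycomp.simulate.config import GroundTruth

__all__ = ["gen_orthogroup_table"]


def _draw_counts(law, rng: np.random.Generator, n: int) -> np.ndarray:
    """Positive per-species gene counts under a small law vocabulary."""
    if isinstance(law, int):
        return np.full(n, law, dtype=int)
    kind = law[0]
    if kind == "poisson1":  # 1 + Poisson(lam): guarantees membership
        return 1 + rng.poisson(law[1], size=n)
    if kind == "uniform":
        lo, hi = law[1], law[2]
        if lo < 1:
            raise ValueError("uniform law lower bound must be >=1")
        return rng.integers(lo, hi + 1, size=n)
    if kind == "geometric":
        return rng.geometric(law[1], size=n)
    raise ValueError(f"unknown gene count law: {law!r}")


def gen_orthogroup_table(
    partition_spec: Mapping[frozenset | tuple, int],
    groups: Mapping[str, Iterable[str]],
    gene_count_law=("poisson1", 2.0),
    seed: int = 0,
) -> tuple[OrthogroupTable, GroundTruth]:
    """Generate a gene-count table whose Venn partition equals ``partition_spec``.

    ``partition_spec`` maps a subset of group names (tuple/frozenset) to
    the number of orthogroups occupying exactly that subset.  Every
    species of every member group receives a positive count drawn from
    ``gene_count_law``; non-member species get zero, so the realized
    partition matches the spec exactly.  An empty spec yields an empty
    table.
    """
    groups = {g: list(sp) for g, sp in groups.items()}
    species = [sp for sps in groups.values() for sp in sps]
    rng = np.random.default_rng(seed)

    rows: dict[str, np.ndarray] = {}
    truth_cells: dict[str, list[str]] = {}
    og_index = 0
    for subset, count in sorted(
        partition_spec.items(), key=lambda kv: sorted(kv[0])
    ):
        subset = frozenset(subset)
        if count < 0:
            raise ValueError("partition counts must be >= 0")
        unknown = subset - set(groups)
        if unknown:
            raise KeyError(f"unknown group(s) in partition spec: {sorted(unknown)}")
        member_species = [sp for g in sorted(subset) for sp in groups[g]]
        member_idx = [species.index(sp) for sp in member_species]
        cell_key = "|".join(sorted(subset))
        truth_cells.setdefault(cell_key, [])
        for _ in range(count):
            og_id = f"OG{og_index:07d}"
            og_index += 1
            row = np.zeros(len(species), dtype=int)
            row[member_idx] = _draw_counts(gene_count_law, rng, len(member_idx))
            rows[og_id] = row
            truth_cells[cell_key].append(og_id)

    counts = pd.DataFrame.from_dict(rows, orient="index", columns=species).astype(int)
    if not rows:
        counts = pd.DataFrame(columns=species, dtype=int)
    table = OrthogroupTable(counts, groups)
    truth = GroundTruth(
        kind="orthogroup_table",
        seed=seed,
        data={
            "partition": {cell: len(ids) for cell, ids in truth_cells.items()},
            "cells": truth_cells,
        },
    )
    return table, truth
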