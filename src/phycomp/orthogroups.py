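"""Orthogroup presence/absence set algebra.

Operates on OrthoFinder-style gene-count tables (orthogroups × species).
Membership of a species in an orthogroup means a positive gene count;
all the set operations here depend only on membership, not magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from phycomp.trees import SpeciesTree

__all__ = [
    "OrthogroupTable",
    "TrichotomyResult",
    "venn_partition",
    "core_at_node",
    "taxon_span_percentages",
    "classify_lineage_families",
]


class OrthogroupTable:
    """Orthogroup × species gene-count matrix with a taxon grouping.

    ``groups`` maps group name -> list of species; every species column
    must belong to exactly one group.
    """

    def __init__(self, counts: pd.DataFrame, groups: Mapping[str, Iterable[str]]):
        counts = counts.astype(int)
        if (counts.values < 0).any():
            raise ValueError("gene counts must be non-negative")
        if counts.index.has_duplicates:
            raise ValueError("duplicate orthogroup ids")
        self.counts = counts
        self.groups = {g: list(sp) for g, sp in groups.items()}
        assigned: dict[str, str] = {}
        for g, species in self.groups.items():
            for sp in species:
                if sp in assigned:
                    raise ValueError(f"species {sp!r} in both {assigned[sp]!r} and {g!r}")
                assigned[sp] = g
        missing = set(counts.columns) - set(assigned)
        if missing:
            raise ValueError(f"species without a group: {sorted(missing)}")
        self.group_of = assigned

    @property
    def orthogroup_ids(self) -> list[str]:
        return self.counts.index.tolist()

    @property
    def species(self) -> list[str]:
        return self.counts.columns.tolist()

    def members(self, orthogroup: str) -> set[str]:
        row = self.counts.loc[orthogroup]
        return set(row.index[row > 0])

    def groups_present(self, orthogroup: str) -> frozenset[str]:
        return frozenset(self.group_of[sp] for sp in self.members(orthogroup))

    # -- OrthoFinder Orthogroups.GeneCount.tsv dialect -----------------
    @classmethod
    def read_genecount_tsv(cls, path, groups: Mapping[str, Iterable[str]]) -> "OrthogroupTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.columns[-1].lower() == "total":
            df = df.iloc[:, :-1]
        return cls(df, groups)

    def to_genecount_tsv(self, path, include_total: bool = True) -> None:
        out = self.counts.copy()
        if include_total:
            out["Total"] = out.sum(axis=1)
        out.to_csv(path, sep="\t", index_label="Orthogroup")

    @staticmethod
    def read_groups_yaml(path) -> dict[str, list[str]]:
        with open(path) as fh:
            return yaml.safe_load(fh)


def venn_partition(table: OrthogroupTable, groups: list[str]) -> dict[frozenset[str], int]:
    """Count orthogroups by the exact subset of ``groups`` they occupy.

    Each orthogroup lands in exactly one cell: the set of listed groups
    with at least one member species present.  Orthogroups present in
    none of the listed groups fall into the empty-set cell.  Counts over
    all cells sum to the number of orthogroups in the table.
    """
    unknown = set(groups) - set(table.groups)
    if unknown:
        raise KeyError(f"unknown group name(s): {sorted(unknown)}")
    focus = set(groups)
    out: dict[frozenset[str], int] = {}
    # vectorized: per-group presence indicator per orthogroup
    presence = {}
    for g in groups:
        cols = [sp for sp in table.groups[g] if sp in table.counts.columns]
        presence[g] = (table.counts[cols] > 0).any(axis=1) if cols else pd.Series(False, index=table.counts.index)
    presence_df = pd.DataFrame(presence)
    for _, row in presence_df.iterrows():
        cell = frozenset(g for g in focus if row[g])
        out[cell] = out.get(cell, 0) + 1
    return out


def core_at_node(table: OrthogroupTable, tree: SpeciesTree, node: str) -> set[str]:
    """Orthogroups spanning the basal split at ``node`` (ancestral core set).

    An orthogroup qualifies iff it is present in at least one taxon of
    each of two or more distinct child subtrees of ``node``.  Tree leaves
    may be species names or group names; a group-name leaf is considered
    present if any of its member species is.
    """
    if tree.is_leaf(node):
        raise ValueError(f"core_at_node requires an internal node, got leaf {node!r}")
    children = tree.children(node)
    # map each child subtree to the species it covers
    side_species: list[set[str]] = []
    for child in children:
        leaves = tree.leaves_under(child)
        species: set[str] = set()
        for leaf in leaves:
            if leaf in table.groups:
                species.update(table.groups[leaf])
            elif leaf in table.group_of:
                species.add(leaf)
        side_species.append(species)
    if sum(1 for s in side_species if s) < 2:
        raise ValueError(
            f"node {node!r} needs >=2 child subtrees with species present in the table"
        )
    mat = table.counts > 0
    side_presence = []
    for species in side_species:
        cols = [sp for sp in species if sp in mat.columns]
        side_presence.append(mat[cols].any(axis=1) if cols else pd.Series(False, index=mat.index))
    spanned = sum(s.astype(int) for s in side_presence) >= 2
    return set(mat.index[spanned])


def taxon_span_percentages(
    table: OrthogroupTable,
    viridiplantae_groups: list[str],
    chlorophyta_group: str = "Chlorophyta",
    streptophyta_group: str = "Streptophyta",
) -> pd.DataFrame:
    """Per-species fractions of proteins in shared / lineage-specific orthogroups.

    An orthogroup's span class is ``viridiplantae`` if it has members in
    both the Chlorophyta and Streptophyta groups (or any two distinct
    groups of ``viridiplantae_groups``), ``chlorophyta_specific`` or
    ``streptophyta_specific`` if confined to that single group, else
    ``other``.  Every protein inherits its orthogroup's class; fractions
    are of each species' total gene count and sum to <= 1 (the remainder
    being proteins in ``other``-span or no orthogroup).
    """
    classes = {}
    for og in table.orthogroup_ids:
        present = table.groups_present(og)
        focal = present & set(viridiplantae_groups)
        if len(focal) >= 2:
            classes[og] = "viridiplantae"
        elif focal == {chlorophyta_group}:
            classes[og] = "chlorophyta_specific"
        elif focal == {streptophyta_group}:
            classes[og] = "streptophyta_specific"
        else:
            classes[og] = "other"
    class_series = pd.Series(classes)
    rows = {}
    for sp in table.species:
        col = table.counts[sp]
        total = int(col.sum())
        if total == 0:
            rows[sp] = {"viridiplantae": 0.0, "chlorophyta_specific": 0.0, "streptophyta_specific": 0.0}
            continue
        sums = col.groupby(class_series).sum()
        rows[sp] = {
            key: float(sums.get(key, 0)) / total
            for key in ("viridiplantae", "chlorophyta_specific", "streptophyta_specific")
        }
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass
class TrichotomyResult:
    """Outcome of the early-lineage gene-family classification."""

    labels: pd.Series  # family -> label
    means: pd.DataFrame  # family -> mean count per group (kept families)
    reasons: pd.Series  # removed family -> reason

    LABELS = (
        "groupA-family",
        "groupB-family",
        "shared",
        "removed-outlier",
        "removed-singleton",
    )

    def count(self, label: str) -> int:
        return int((self.labels == label).sum())


def classify_lineage_families(
    table: OrthogroupTable, group_a: str, group_b: str
) -> TrichotomyResult:
    """Trichotomy of gene families between two early-diverging lineages.

    Applied in fixed order: (1) drop families where any single species'
    count exceeds ten times the mean count of all *other* species in that
    family (zeros included in the mean); (2) drop families present in
    only one species; (3) compare group means — a family belongs to a
    group iff its mean count there is *more than* twice the other group's
    mean, otherwise it is shared.  Families with all-zero counts indicate
    a malformed table and are rejected.
    """
    for g in (group_a, group_b):
        if g not in table.groups or not table.groups[g]:
            raise ValueError(f"group {g!r} is missing or empty")
    counts = table.counts
    if (counts.sum(axis=1) == 0).any():
        bad = counts.index[counts.sum(axis=1) == 0].tolist()
        raise ValueError(f"families with all-zero counts: {bad}")

    values = counts.values.astype(float)
    n_sp = values.shape[1]
    totals = values.sum(axis=1, keepdims=True)
    other_mean = (totals - values) / (n_sp - 1) if n_sp > 1 else np.zeros_like(values)
    with np.errstate(invalid="ignore"):
        outlier = ((values > 10.0 * other_mean) & (values > 0) & (other_mean > 0)).any(axis=1)
    singleton = (values > 0).sum(axis=1) == 1

    labels = pd.Series(index=counts.index, dtype=object)
    reasons = pd.Series(dtype=object)
    labels[outlier] = "removed-outlier"
    labels[~outlier & singleton] = "removed-singleton"
    for fam in counts.index[outlier]:
        reasons[fam] = "species count >10x mean of others"
    for fam in counts.index[~outlier & singleton]:
        reasons[fam] = "present in a single species"

    kept = ~outlier & ~singleton
    cols_a = [sp for sp in table.groups[group_a] if sp in counts.columns]
    cols_b = [sp for sp in table.groups[group_b] if sp in counts.columns]
    mean_a = counts.loc[kept, cols_a].mean(axis=1)
    mean_b = counts.loc[kept, cols_b].mean(axis=1)
    labels[kept & (mean_a > 2.0 * mean_b).reindex(counts.index, fill_value=False)] = "groupA-family"
    labels[kept & (mean_b > 2.0 * mean_a).reindex(counts.index, fill_value=False)] = "groupB-family"
    labels[kept & labels.isna()] = "shared"

    means = pd.DataFrame({group_a: mean_a, group_b: mean_b})
    return TrichotomyResult(labels=labels, means=means, reasons=reasons)
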