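import itertools

import numpy as np
import pandas as pd
import pytest

from phycomp.orthogroups import (
    OrthogroupTable,
    classify_lineage_families,
    core_at_node,
    taxon_span_percentages,
    venn_partition,
)
from phycomp.simulate import gen_orthogroup_table, gen_species_tree
from phycomp.trees import SpeciesTree

THREE_GROUPS = {
    "Prasinodermophyta": ["P. coloniale"],
    "Chlorophyta": ["M. commoda"],
    "Streptophyta": ["C. atmophyticus"],
}


def random_table(rng, groups, n_orthogroups):
    species = [sp for sps in groups.values() for sp in sps]
    counts = rng.integers(0, 4, size=(n_orthogroups, len(species)))
    # no all-zero rows (every orthogroup has at least one member)
    for i in np.nonzero(counts.sum(axis=1) == 0)[0]:
        counts[i, rng.integers(len(species))] = 1
    df = pd.DataFrame(
        counts, index=[f"OG{i:05d}" for i in range(n_orthogroups)], columns=species
    )
    return OrthogroupTable(df, groups)


def brute_force_venn(table, groups):
    out = {}
    for og in table.orthogroup_ids:
        members = table.members(og)
        cell = frozenset(
            g for g in groups if any(sp in members for sp in table.groups[g])
        )
        out[cell] = out.get(cell, 0) + 1
    return out


def brute_force_core(table, tree, node):
    children = tree.children(node)
    core = set()
    for og in table.orthogroup_ids:
        members = table.members(og)
        sides = 0
        for child in children:
            leaves = tree.leaves_under(child)
            species = set()
            for leaf in leaves:
                species |= set(table.groups.get(leaf, [leaf] if leaf in table.group_of else []))
            if members & species:
                sides += 1
        if sides >= 2:
            core.add(og)
    return core


class TestVennPartition:
    def test_all_groups_cell(self):
        df = pd.DataFrame(
            [[1, 2, 3]],
            index=["OG1"],
            columns=["P. coloniale", "M. commoda", "C. atmophyticus"],
        )
        table = OrthogroupTable(df, THREE_GROUPS)
        part = venn_partition(table, list(THREE_GROUPS))
        assert part == {frozenset(THREE_GROUPS): 1}

    def test_generator_round_trip(self, fig2a_partition_spec):
        table, truth = gen_orthogroup_table(fig2a_partition_spec, THREE_GROUPS, seed=0)
        part = venn_partition(table, list(THREE_GROUPS))
        assert part == fig2a_partition_spec

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(0)
        groups = {
            "A": ["a1", "a2"],
            "B": ["b1"],
            "C": ["c1", "c2", "c3"],
            "D": ["d1"],
        }
        table = random_table(rng, groups, 500)
        assert venn_partition(table, list(groups)) == brute_force_venn(table, groups)

    def test_counts_sum_to_table_size(self):
        rng = np.random.default_rng(1)
        table = random_table(rng, THREE_GROUPS, 200)
        part = venn_partition(table, list(THREE_GROUPS))
        assert sum(part.values()) == 200

    def test_magnitude_invariance(self):
        rng = np.random.default_rng(2)
        table = random_table(rng, THREE_GROUPS, 100)
        scaled = OrthogroupTable(table.counts * 7, table.groups)
        assert venn_partition(table, list(THREE_GROUPS)) == venn_partition(
            scaled, list(THREE_GROUPS)
        )

    def test_unknown_group_rejected(self):
        rng = np.random.default_rng(3)
        table = random_table(rng, THREE_GROUPS, 10)
        with pytest.raises(KeyError):
            venn_partition(table, ["Rhodoplantae"])

    def test_empty_spec_empty_table(self):
        table, _ = gen_orthogroup_table({}, THREE_GROUPS, seed=0)
        assert len(table.orthogroup_ids) == 0

    def test_generator_determinism(self, fig2a_partition_spec):
        t1, _ = gen_orthogroup_table(fig2a_partition_spec, THREE_GROUPS, seed=5)
        t2, _ = gen_orthogroup_table(fig2a_partition_spec, THREE_GROUPS, seed=5)
        assert t1.counts.equals(t2.counts)


class TestCoreAtNode:
    def test_fig2a_core_is_4092(self, fig2a_partition_spec, backbone_tree):
        table, _ = gen_orthogroup_table(fig2a_partition_spec, THREE_GROUPS, seed=1)
        core = core_at_node(table, backbone_tree, "Viridiplantae")
        assert len(core) == 4092

    def test_single_lineage_orthogroup_excluded(self, backbone_tree):
        table, _ = gen_orthogroup_table(
            {frozenset({"Prasinodermophyta"}): 1}, THREE_GROUPS, seed=0
        )
        # spans a single child subtree of the node -> not part of the core
        assert core_at_node(table, backbone_tree, "Viridiplantae") == set()

    def test_unique_orthogroups_excluded(self, fig2a_partition_spec, backbone_tree):
        table, truth = gen_orthogroup_table(fig2a_partition_spec, THREE_GROUPS, seed=1)
        core = core_at_node(table, backbone_tree, "Viridiplantae")
        for cell, ids in truth.data["cells"].items():
            if "|" not in cell:  # group-unique cells
                assert not (core & set(ids))

    def test_leaf_node_rejected(self, backbone_tree):
        table, _ = gen_orthogroup_table(
            {frozenset(THREE_GROUPS): 2}, THREE_GROUPS, seed=0
        )
        with pytest.raises(ValueError):
            core_at_node(table, backbone_tree, "Chlorophyta")

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        groups = {
            "Rhodoplantae": ["r1"],
            "Glaucoplantae": ["g1"],
            "Prasinodermophyta": ["p1", "p2"],
            "Chlorophyta": ["c1", "c2"],
            "Streptophyta": ["s1", "s2"],
        }
        from phycomp.simulate import SimConfig

        tree = gen_species_tree(SimConfig(groups=groups))
        table = random_table(rng, groups, 200)
        for node in ("Archaeplastida", "Viridiplantae", "Chlorophyta+Streptophyta"):
            assert core_at_node(table, tree, node) == brute_force_core(table, tree, node)

    def test_monotonicity_adding_presence(self, backbone_tree):
        rng = np.random.default_rng(8)
        table = random_table(rng, THREE_GROUPS, 100)
        base_core = core_at_node(table, backbone_tree, "Viridiplantae")
        bumped = table.counts.copy()
        zeros = np.argwhere(bumped.values == 0)
        for i, j in zeros[:50]:
            bumped.iat[i, j] = 1
        bigger = OrthogroupTable(bumped, table.groups)
        assert base_core <= core_at_node(bigger, backbone_tree, "Viridiplantae")


class TestTaxonSpan:
    def test_all_viridiplantae(self):
        df = pd.DataFrame(
            [[2, 1, 1], [1, 3, 0]],
            index=["OG1", "OG2"],
            columns=["P. coloniale", "M. commoda", "C. atmophyticus"],
        )
        table = OrthogroupTable(df, THREE_GROUPS)
        frac = taxon_span_percentages(table, list(THREE_GROUPS))
        assert frac.loc["P. coloniale", "viridiplantae"] == pytest.approx(1.0)

    def test_planted_span_fractions(self):
        # one species with 60/30/10 proteins in shared/Chl-only/Str-only groups
        df = pd.DataFrame(
            {
                "P. coloniale": [0, 0, 0],
                "M. commoda": [60, 30, 0],
                "C. atmophyticus": [60, 0, 10],
            },
            index=["OG_shared", "OG_chl", "OG_str"],
        )
        table = OrthogroupTable(df, THREE_GROUPS)
        frac = taxon_span_percentages(table, list(THREE_GROUPS))
        row = frac.loc["M. commoda"]
        assert row["viridiplantae"] == pytest.approx(60 / 90)
        assert row["chlorophyta_specific"] == pytest.approx(30 / 90)
        assert row["streptophyta_specific"] == pytest.approx(0.0)

    def test_empty_species_all_zero(self):
        df = pd.DataFrame(
            {"P. coloniale": [0], "M. commoda": [1], "C. atmophyticus": [1]},
            index=["OG1"],
        )
        table = OrthogroupTable(df, THREE_GROUPS)
        frac = taxon_span_percentages(table, list(THREE_GROUPS))
        assert frac.loc["P. coloniale"].sum() == 0.0

    def test_fractions_sum_at_most_one(self):
        rng = np.random.default_rng(9)
        table = random_table(rng, THREE_GROUPS, 300)
        frac = taxon_span_percentages(table, list(THREE_GROUPS))
        assert (frac.sum(axis=1) <= 1 + 1e-12).all()


TWO_LINEAGES = {
    "earlyChlorophyta": [f"chl{i}" for i in range(5)],
    "earlyStreptophyta": [f"str{i}" for i in range(5)],
}


def make_family(chl_counts, str_counts):
    df = pd.DataFrame(
        [list(chl_counts) + list(str_counts)],
        index=["fam"],
        columns=TWO_LINEAGES["earlyChlorophyta"] + TWO_LINEAGES["earlyStreptophyta"],
    )
    return OrthogroupTable(df, TWO_LINEAGES)


class TestTrichotomy:
    def test_group_a_family(self):
        table = make_family([4, 6, 8, 5, 7], [2, 3, 1, 2, 2])
        result = classify_lineage_families(table, "earlyChlorophyta", "earlyStreptophyta")
        assert result.labels["fam"] == "groupA-family"

    def test_outlier_removed(self):
        table = make_family([100, 5, 5, 5, 5], [5, 5, 5, 5, 5])
        result = classify_lineage_families(table, "earlyChlorophyta", "earlyStreptophyta")
        assert result.labels["fam"] == "removed-outlier"
        assert "10x" in result.reasons["fam"]

    def test_exact_double_is_shared(self):
        # meanA = 4, meanB = 2: not *more than* twice -> shared
        table = make_family([4, 4, 4, 4, 4], [2, 2, 2, 2, 2])
        result = classify_lineage_families(table, "earlyChlorophyta", "earlyStreptophyta")
        assert result.labels["fam"] == "shared"

    def test_singleton_removed(self):
        table = make_family([3, 0, 0, 0, 0], [0, 0, 0, 0, 0])
        result = classify_lineage_families(table, "earlyChlorophyta", "earlyStreptophyta")
        assert result.labels["fam"] == "removed-singleton"

    def test_group_b_family(self):
        table = make_family([1, 1, 1, 1, 1], [3, 3, 2, 3, 3])
        result = classify_lineage_families(table, "earlyChlorophyta", "earlyStreptophyta")
        assert result.labels["fam"] == "groupB-family"

    def test_all_zero_family_rejected(self):
        df = pd.DataFrame(
            [[0] * 10],
            index=["bad"],
            columns=TWO_LINEAGES["earlyChlorophyta"] + TWO_LINEAGES["earlyStreptophyta"],
        )
        table = OrthogroupTable(df, TWO_LINEAGES)
        with pytest.raises(ValueError, match="all-zero"):
            classify_lineage_families(table, "earlyChlorophyta", "earlyStreptophyta")

    def test_labels_exhaustive_and_exclusive(self):
        rng = np.random.default_rng(11)
        table = random_table(rng, TWO_LINEAGES, 500)
        result = classify_lineage_families(table, "earlyChlorophyta", "earlyStreptophyta")
        assert not result.labels.isna().any()
        assert set(result.labels.unique()) <= set(result.labels.index.__class__ and result.LABELS)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(12)
        table = random_table(rng, TWO_LINEAGES, 500)
        result = classify_lineage_families(table, "earlyChlorophyta", "earlyStreptophyta")
        for fam in table.orthogroup_ids:
            row = table.counts.loc[fam]
            vals = row.values.astype(float)
            outlier = False
            for i, v in enumerate(vals):
                others = np.delete(vals, i)
                if v > 0 and others.mean() > 0 and v > 10 * others.mean():
                    outlier = True
            if outlier:
                expect = "removed-outlier"
            elif (vals > 0).sum() == 1:
                expect = "removed-singleton"
            else:
                mean_a = row[TWO_LINEAGES["earlyChlorophyta"]].mean()
                mean_b = row[TWO_LINEAGES["earlyStreptophyta"]].mean()
                if mean_a > 2 * mean_b:
                    expect = "groupA-family"
                elif mean_b > 2 * mean_a:
                    expect = "groupB-family"
                else:
                    expect = "shared"
            assert result.labels[fam] == expect, fam

    def test_relabeling_and_scaling_invariance(self):
        rng = np.random.default_rng(13)
        table = random_table(rng, TWO_LINEAGES, 100)
        r1 = classify_lineage_families(table, "earlyChlorophyta", "earlyStreptophyta")
        # permute species within each group
        perm_cols = (
            list(np.array(TWO_LINEAGES["earlyChlorophyta"])[rng.permutation(5)])
            + list(np.array(TWO_LINEAGES["earlyStreptophyta"])[rng.permutation(5)])
        )
        permuted = OrthogroupTable(
            table.counts[perm_cols].set_axis(
                TWO_LINEAGES["earlyChlorophyta"] + TWO_LINEAGES["earlyStreptophyta"],
                axis=1,
            ),
            TWO_LINEAGES,
        )
        r2 = classify_lineage_families(permuted, "earlyChlorophyta", "earlyStreptophyta")
        assert (r1.labels == r2.labels).all()
        tripled = OrthogroupTable(table.counts * 3, TWO_LINEAGES)
        r3 = classify_lineage_families(tripled, "earlyChlorophyta", "earlyStreptophyta")
        assert (r1.labels == r3.labels).all()


class TestTableIO:
    def test_genecount_tsv_round_trip(self, tmp_path, fig2a_partition_spec):
        table, _ = gen_orthogroup_table(fig2a_partition_spec, THREE_GROUPS, seed=4)
        path = tmp_path / "Orthogroups.GeneCount.tsv"
        table.to_genecount_tsv(path)
        back = OrthogroupTable.read_genecount_tsv(path, THREE_GROUPS)
        assert back.counts.equals(table.counts)

    def test_species_in_two_groups_rejected(self):
        df = pd.DataFrame([[1, 1]], index=["OG1"], columns=["x", "y"])
        with pytest.raises(ValueError):
            OrthogroupTable(df, {"A": ["x", "y"], "B": ["y"]})

    def test_negative_counts_rejected(self):
        df = pd.DataFrame([[-1]], index=["OG1"], columns=["x"])
        with pytest.raises(ValueError):
            OrthogroupTable(df, {"A": ["x"]})
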