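import numpy as np
import pytest
from Bio.Align import PairwiseAligner, substitution_matrices

from phycomp.rbh import (
    EvalueModel,
    ProteinSet,
    candidate_gene_screen,
    flagellate_call,
    local_align_score,
    panel_inventory,
    reciprocal_best_hits,
    score_matrix,
)
from phycomp.simulate import gen_proteomes

AA = "ACDEFGHIKLMNPQRSTVWY"
BLOSUM62 = substitution_matrices.load("BLOSUM62")


def reference_aligner(gap_open=11, gap_extend=1):
    """Independent quadratic-space Smith–Waterman (Biopython's C engine)."""
    return PairwiseAligner(
        mode="local",
        substitution_matrix=BLOSUM62,
        open_gap_score=-(gap_open + gap_extend),
        extend_gap_score=-gap_extend,
    )


class TestLocalAlignScore:
    def test_self_alignment_is_diagonal_sum(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list(AA), size=100))
        expected = sum(BLOSUM62[c][c] for c in seq)
        assert local_align_score(seq, seq) == expected

    def test_single_residue_match(self):
        assert local_align_score("A", "A") == BLOSUM62["A"]["A"]

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = "".join(rng.choice(list(AA), size=rng.integers(5, 40)))
            b = "".join(rng.choice(list(AA), size=rng.integers(5, 40)))
            assert local_align_score(a, b) == local_align_score(b, a)

    def test_illegal_residue_rejected(self):
        with pytest.raises(ValueError):
            local_align_score("ABZ", "ACD")  # B, Z not in alphabet

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            local_align_score("", "ACD")

    @pytest.mark.parametrize("seed", range(5))
    def test_oracle_equivalence_short_pairs(self, seed):
        """Exact agreement with a reference implementation on pairs <=50 aa."""
        rng = np.random.default_rng(seed)
        aligner = reference_aligner()
        for _ in range(60):
            a = "".join(rng.choice(list(AA), size=rng.integers(1, 51)))
            b = "".join(rng.choice(list(AA), size=rng.integers(1, 51)))
            assert local_align_score(a, b) == int(aligner.score(a, b))

    def test_oracle_equivalence_alternative_gap_costs(self):
        rng = np.random.default_rng(77)
        aligner = reference_aligner(gap_open=7, gap_extend=2)
        for _ in range(30):
            a = "".join(rng.choice(list(AA), size=rng.integers(2, 50)))
            b = "".join(rng.choice(list(AA), size=rng.integers(2, 50)))
            mine = local_align_score(a, b, gap_open=7, gap_extend=2)
            assert mine == int(aligner.score(a, b))


class TestScoreMatrix:
    def test_matches_pairwise_scores(self):
        A, B, _ = gen_proteomes(5, divergence=0.2, n_decoys=3, protein_length=60, seed=3)
        sm = score_matrix(ProteinSet(A), ProteinSet(B))
        rng = np.random.default_rng(0)
        for a in list(A)[:4]:
            for b in list(B)[:4]:
                assert sm.loc[a, b] == local_align_score(A[a], B[b])

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            score_matrix(ProteinSet({}), ProteinSet({"x": "ACD"}))


class TestReciprocalBestHits:
    def test_identity_pairing_on_same_proteome(self):
        A, _, _ = gen_proteomes(10, divergence=0.0, n_decoys=0, seed=4)
        prot = ProteinSet(A)
        pairs = reciprocal_best_hits(prot, prot)
        assert pairs == {(i, i) for i in prot}

    def test_zero_divergence_full_recovery(self):
        A, B, truth = gen_proteomes(20, divergence=0.0, n_decoys=10, seed=5)
        pairs = reciprocal_best_hits(ProteinSet(A), ProteinSet(B))
        assert {tuple(p) for p in truth.data["pairs"]} <= pairs

    def test_divergence_03_precision_recall(self):
        A, B, truth = gen_proteomes(50, divergence=0.3, n_decoys=50, seed=2)
        pairs = reciprocal_best_hits(ProteinSet(A), ProteinSet(B))
        true_pairs = {tuple(p) for p in truth.data["pairs"]}
        tp = len(pairs & true_pairs)
        assert tp / len(pairs) >= 0.9  # precision
        assert tp / len(true_pairs) >= 0.9  # recall

    def test_symmetry(self):
        A, B, _ = gen_proteomes(10, divergence=0.3, n_decoys=5, seed=6)
        ab = reciprocal_best_hits(ProteinSet(A), ProteinSet(B))
        ba = reciprocal_best_hits(ProteinSet(B), ProteinSet(A))
        assert ab == {(a, b) for b, a in ba}

    def test_threshold_filters_everything(self):
        A, B, _ = gen_proteomes(5, divergence=0.3, n_decoys=0, seed=7)
        assert reciprocal_best_hits(ProteinSet(A), ProteinSet(B), min_score=1e9) == set()

    def test_no_families_empty(self):
        A, B, _ = gen_proteomes(0, divergence=0.3, n_decoys=5, seed=8)
        pairs = reciprocal_best_hits(ProteinSet(A), ProteinSet(B))
        assert pairs == set()

    def test_decoy_scores_below_ortholog_scores(self):
        A, B, truth = gen_proteomes(50, divergence=0.3, n_decoys=50, seed=2)
        sm = score_matrix(ProteinSet(A), ProteinSet(B))
        true_scores = [sm.loc[a, b] for a, b in truth.data["pairs"]]
        decoy_a = [i for i in A if "decoy" in i]
        decoy_b = [j for j in B if "decoy" in j]
        decoy_scores = sm.loc[decoy_a, decoy_b].values.ravel()
        frac_below = (decoy_scores < min(true_scores)).mean()
        assert frac_below >= 0.99


class TestEvalueModel:
    def test_calibrated_evalues_separate_signal(self):
        A, B, truth = gen_proteomes(20, divergence=0.3, n_decoys=30, seed=9)
        sm = score_matrix(ProteinSet(A), ProteinSet(B))
        decoy_a = [i for i in A if "decoy" in i]
        decoy_b = [j for j in B if "decoy" in j]
        decoy_scores = sm.loc[decoy_a, decoy_b].values.ravel()
        model = EvalueModel.calibrate(decoy_scores, 120, 120)
        a0, b0 = truth.data["pairs"][0]
        assert model.evalue(float(sm.loc[a0, b0]), 120, 120) < 1e-5
        assert model.evalue(float(np.median(decoy_scores)), 120, 120) > 1e-3

    def test_needs_enough_scores(self):
        with pytest.raises(ValueError):
            EvalueModel.calibrate([1, 2, 3], 10, 10)


class TestPanelInventory:
    def test_forced_counts(self):
        rng = np.random.default_rng(10)
        panel = {
            f"panel{i:02d}": "".join(rng.choice(list(AA), size=80)) for i in range(20)
        }
        # proteome holds exact copies of 10 panel members, 3 of them core
        member_ids = list(panel)[:10]
        proteome = {f"prot_{pid}": panel[pid] for pid in member_ids}
        core_ids = set(member_ids[:3])
        core, total = panel_inventory(
            ProteinSet(proteome), ProteinSet(panel), core_ids
        )
        assert (core, total) == (3, 10)

    def test_core_subset_enforced(self):
        panel = ProteinSet({"p1": "ACDEFGHIKL"})
        with pytest.raises(ValueError):
            panel_inventory(panel, panel, {"p1", "zz"})

    def test_core_never_exceeds_total(self):
        A, B, _ = gen_proteomes(15, divergence=0.2, n_decoys=5, seed=11)
        panel = ProteinSet(A)
        core, total = panel_inventory(ProteinSet(B), panel, set(list(A)[:7]))
        assert core <= total

    def test_worked_inventory_50_core_217_total(self):
        """Panel of 397 with 217 detectable members, 50 of them core."""
        rng = np.random.default_rng(12)
        panel = {
            f"fla{i:03d}": "".join(rng.choice(list(AA), size=80)) for i in range(397)
        }
        panel_ids = list(panel)
        detectable = panel_ids[:217]
        core_ids = set(panel_ids[:50])
        proteome = {}
        for pid in detectable:
            seq = np.frombuffer(panel[pid].encode(), dtype=np.uint8).copy()
            hit = rng.random(len(seq)) < 0.15  # mild divergence
            for idx in np.nonzero(hit)[0]:
                seq[idx] = ord(rng.choice(list(AA)))
            proteome[f"prot_{pid}"] = bytes(seq).decode()
        # plus decoys that should match nothing
        for i in range(50):
            proteome[f"junk{i:02d}"] = "".join(rng.choice(list(AA), size=80))
        core, total = panel_inventory(
            ProteinSet(proteome), ProteinSet(panel), core_ids
        )
        assert (core, total) == (50, 217)
        assert flagellate_call(core, total).call == "flagellate-capable"

    def test_invariant_to_panel_order_and_decoys(self):
        A, B, _ = gen_proteomes(10, divergence=0.2, n_decoys=0, seed=13)
        panel = ProteinSet(A)
        proteome = ProteinSet(B)
        core_ids = set(list(A)[:4])
        base = panel_inventory(proteome, panel, core_ids)
        reordered = ProteinSet({k: A[k] for k in reversed(list(A))})
        assert panel_inventory(proteome, reordered, core_ids) == base
        rng = np.random.default_rng(14)
        noisy = dict(B)
        for i in range(10):
            noisy[f"extra{i}"] = "".join(rng.choice(list(AA), size=90))
        assert panel_inventory(ProteinSet(noisy), panel, core_ids) == base


class TestFlagellateCall:
    def test_worked_point_is_flagellate(self):
        assert flagellate_call(50, 217).call == "flagellate-capable"

    def test_boundary_non_flagellate(self):
        assert flagellate_call(26, 140).call == "non-flagellate"

    def test_between_regimes_indeterminate(self):
        assert flagellate_call(30, 150).call == "indeterminate"

    def test_flagellate_boundary(self):
        assert flagellate_call(40, 192).call == "flagellate-capable"
        assert flagellate_call(39, 192).call == "indeterminate"
        assert flagellate_call(40, 191).call == "indeterminate"

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            flagellate_call(-1, 5)


class TestCandidateGeneScreen:
    def _fixture(self, seed=15):
        rng = np.random.default_rng(seed)
        queries = {
            f"q{i}": "".join(rng.choice(list(AA), size=90)) for i in range(5)
        }
        annotations = {qid: "dynein heavy chain" for qid in queries}
        proteome = {}
        expected = set()
        for i, qid in enumerate(queries):
            pid = f"true{i}"
            proteome[pid] = queries[qid]
            annotations[pid] = "putative dynein heavy chain protein"
            expected.add(pid)
        for i in range(5):
            pid = f"decoy{i}"
            proteome[pid] = "".join(rng.choice(list(AA), size=90))
            annotations[pid] = "hypothetical protein"
        return ProteinSet(proteome), ProteinSet(queries), annotations, expected

    def test_truth_recovery(self):
        proteome, queries, ann, expected = self._fixture()
        accepted, _ = candidate_gene_screen(proteome, queries, ann)
        assert accepted == expected

    def test_blank_annotation_rejected_with_reason(self):
        proteome, queries, ann, expected = self._fixture()
        victim = next(iter(expected))
        ann[victim] = ""
        accepted, reasons = candidate_gene_screen(proteome, queries, ann)
        assert victim not in accepted
        assert reasons[victim] == "annotation-inconsistent"

    def test_similar_but_misannotated_rejected(self):
        proteome, queries, ann, expected = self._fixture()
        victim = next(iter(expected))
        ann[victim] = "ribosomal subunit"
        accepted, reasons = candidate_gene_screen(proteome, queries, ann)
        assert victim not in accepted
        assert reasons[victim] == "annotation-inconsistent"
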