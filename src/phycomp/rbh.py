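"""Reciprocal-best-hit protein inventories and the flagellate classifier.

Similarity search is an in-repo affine-gap Smith–Waterman (BLOSUM62,
open 11 / extend 1 by default) with an extreme-value significance
estimate calibrated on shuffled decoys — a desk-scale stand-in for a
full BLAST pipeline.  The row recursion resolves the same-row gap
dependency with a running-maximum scan, which is exact whenever the gap
opening cost is at least the extension cost.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

__all__ = [
    "ProteinSet",
    "FlagellarCall",
    "local_align_score",
    "score_matrix",
    "reciprocal_best_hits",
    "panel_inventory",
    "flagellate_call",
    "candidate_gene_screen",
    "EvalueModel",
]

_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
_AA_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _aa in enumerate(_ALPHABET):
    _AA_INDEX[ord(_aa)] = _i
    _AA_INDEX[ord(_aa.lower())] = _i

#: 26/140 and 40/192 count thresholds for the flagellate capability call.
NON_FLAGELLATE_MAX = (26, 140)
FLAGELLATE_MIN = (40, 192)


def _blosum62() -> np.ndarray:
    """BLOSUM62 over the 20 residues + X, as a dense int matrix."""
    raw = substitution_matrices.load("BLOSUM62")
    n = len(_ALPHABET)
    out = np.zeros((n, n), dtype=np.int32)
    for i, a in enumerate(_ALPHABET):
        for j, b in enumerate(_ALPHABET):
            out[i, j] = int(raw[a][b])
    return out


_DEFAULT_SUB = _blosum62()


class ProteinSet(dict):
    """id -> amino-acid sequence over the 20-letter alphabet plus X."""

    def __init__(self, sequences: dict[str, str], source: str = ""):
        for sid, seq in sequences.items():
            bad = set(seq.upper()) - set(_ALPHABET)
            if bad:
                raise ValueError(f"illegal residue(s) {sorted(bad)} in {sid!r}")
        super().__init__(sequences)
        self.source = source

    @classmethod
    def read_fasta(cls, path, source: str = "") -> "ProteinSet":
        from Bio import SeqIO

        seqs = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in seqs:
                raise ValueError(f"duplicate sequence id {rec.id!r}")
            seqs[rec.id] = str(rec.seq)
        return cls(seqs, source=source or str(path))

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for sid, seq in self.items():
                fh.write(f">{sid}\n{seq}\n")


def _encode(seq: str) -> np.ndarray:
    arr = _AA_INDEX[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]
    if (arr < 0).any():
        bad = sorted({seq[i] for i in np.nonzero(arr < 0)[0]})
        raise ValueError(f"illegal residue(s): {bad}")
    return arr.astype(np.int64)


def local_align_score(
    a: str,
    b: str,
    substitution: np.ndarray | None = None,
    gap_open: int = 11,
    gap_extend: int = 1,
) -> int:
    """Optimal affine-gap Smith–Waterman score of two protein sequences.

    A gap of length g costs ``gap_open + g * gap_extend`` (BLAST
    convention).  Symmetric in its arguments; rejects empty sequences and
    residues outside the 20-letter alphabet plus X.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if gap_open < 0 or gap_extend < 0 or gap_extend > gap_open + gap_extend:
        raise ValueError("gap costs must be non-negative")
    sub = _DEFAULT_SUB if substitution is None else substitution
    return int(
        _batch_scores(
            [_encode(a)], np.asarray([_encode(b)]), np.asarray([len(b)]), sub,
            gap_open + gap_extend, gap_extend,
        )[0, 0]
    )


def _batch_scores(
    queries: list[np.ndarray],
    subjects_mat: np.ndarray,
    subject_lens: np.ndarray,
    sub: np.ndarray,
    first_gap: int,
    ext: int,
) -> np.ndarray:
    """Score every query against every (padded) subject row.

    ``subjects_mat`` is (n_subjects x max_len) with arbitrary codes in
    pad positions; pads are masked to a large negative substitution
    score, so local alignments cannot extend into them.  ``first_gap``
    is the cost of the first gap position (open + extend).
    """
    n_sub, max_len = subjects_mat.shape
    pad_mask = np.arange(max_len)[None, :] >= subject_lens[:, None]
    neg = np.int64(-(10**9))
    col_offsets = np.arange(max_len, dtype=np.int64) * ext
    out = np.zeros((len(queries), n_sub), dtype=np.int64)

    for qi, q in enumerate(queries):
        H = np.zeros((n_sub, max_len + 1), dtype=np.int64)
        F = np.full((n_sub, max_len + 1), neg, dtype=np.int64)
        best = np.zeros(n_sub, dtype=np.int64)
        for code in q:
            srow = sub[code][subjects_mat]
            srow = np.where(pad_mask, neg, srow)
            diag = H[:, :-1] + srow
            F = np.maximum(H - first_gap, F - ext)
            H0 = np.maximum(np.maximum(diag, F[:, 1:]), 0)
            # same-row gaps via running max of H0 + j*ext
            base = np.concatenate(
                [np.zeros((n_sub, 1), dtype=np.int64), H0[:, :-1]], axis=1
            )
            runmax = np.maximum.accumulate(base + col_offsets[None, :], axis=1)
            E = runmax - col_offsets[None, :] - first_gap
            Hrow = np.maximum(H0, np.maximum(E, 0))
            Hrow = np.where(pad_mask, 0, Hrow)
            H = np.concatenate(
                [np.zeros((n_sub, 1), dtype=np.int64), Hrow], axis=1
            )
            best = np.maximum(best, Hrow.max(axis=1))
        out[qi] = best
    return out


def score_matrix(
    set_a: ProteinSet,
    set_b: ProteinSet,
    substitution: np.ndarray | None = None,
    gap_open: int = 11,
    gap_extend: int = 1,
) -> pd.DataFrame:
    """All-vs-all Smith–Waterman scores (rows: set_a ids, cols: set_b ids)."""
    if not set_a or not set_b:
        raise ValueError("both protein sets must be non-empty")
    sub = _DEFAULT_SUB if substitution is None else substitution
    a_ids = list(set_a)
    b_ids = list(set_b)
    queries = [_encode(set_a[i]) for i in a_ids]
    b_enc = [_encode(set_b[i]) for i in b_ids]
    lens = np.array([len(e) for e in b_enc])
    mat = np.zeros((len(b_ids), lens.max()), dtype=np.int64)
    for r, e in enumerate(b_enc):
        mat[r, : len(e)] = e
    scores = _batch_scores(queries, mat, lens, sub, gap_open + gap_extend, gap_extend)
    return pd.DataFrame(scores, index=a_ids, columns=b_ids)


@dataclass
class EvalueModel:
    """Gumbel tail fit of random-pair scores: E = K * m * n * exp(-lam * S)."""

    lam: float
    K: float

    @classmethod
    def calibrate(cls, decoy_scores, m: float, n: float) -> "EvalueModel":
        """Method-of-moments Gumbel fit on shuffled-decoy pair scores."""
        arr = np.asarray(list(decoy_scores), dtype=float)
        if len(arr) < 10:
            raise ValueError("need >=10 decoy scores to calibrate")
        lam = math.pi / (math.sqrt(6) * arr.std())
        mu = arr.mean() - 0.5772156649 / lam
        K = math.exp(lam * mu) / (m * n)
        return cls(lam=lam, K=K)

    def evalue(self, score: float, m: float, n: float) -> float:
        return self.K * m * n * math.exp(-self.lam * score)


def _best_hits(
    scores: pd.DataFrame, min_score: float, subject_lens: dict[str, int]
) -> dict[str, str]:
    """Best subject per query; equal scores break toward the shorter
    subject (higher alignment coverage for the same score), then
    lexicographic id."""
    out = {}
    for qid, row in scores.iterrows():
        top = row.max()
        if top < min_score:
            continue
        tied = list(row.index[row == top])
        out[qid] = min(tied, key=lambda sid: (subject_lens[sid], sid))
    return out


def reciprocal_best_hits(
    set_a: ProteinSet,
    set_b: ProteinSet,
    min_score: float = 75.0,
    scores: pd.DataFrame | None = None,
    evalue_model: EvalueModel | None = None,
    max_evalue: float = 1e-5,
) -> set[tuple[str, str]]:
    """Ortholog pairs (a, b) that are mutual unique best hits.

    Both directions use the same symmetric score matrix, so
    ``reciprocal_best_hits(A, B)`` is the transpose of
    ``reciprocal_best_hits(B, A)`` by construction.  Pairs must pass
    ``min_score``; when an ``evalue_model`` is supplied the pair must
    additionally satisfy ``E < max_evalue``.
    """
    if scores is None:
        scores = score_matrix(set_a, set_b)
    lens = {sid: len(seq) for sid, seq in {**set_a, **set_b}.items()}
    a_best = _best_hits(scores, min_score, lens)
    b_best = _best_hits(scores.T, min_score, lens)
    pairs = {
        (a, b)
        for a, b in a_best.items()
        if b_best.get(b) == a
    }
    if evalue_model is not None:
        pairs = {
            (a, b)
            for a, b in pairs
            if evalue_model.evalue(
                float(scores.loc[a, b]), len(set_a[a]), len(set_b[b])
            )
            < max_evalue
        }
    return pairs


def panel_inventory(
    proteome: ProteinSet,
    panel: ProteinSet,
    core_ids: set[str],
    min_score: float = 75.0,
) -> tuple[int, int]:
    """(core_count, total_count) of panel members with an RBH partner.

    ``core_ids`` must be a subset of the panel ids.  The counts are
    invariant to panel ordering and to decoy proteins in the proteome
    that match nothing.
    """
    extra = set(core_ids) - set(panel)
    if extra:
        raise ValueError(f"core ids not in panel: {sorted(extra)}")
    pairs = reciprocal_best_hits(panel, proteome, min_score=min_score)
    found = {a for a, _ in pairs}
    return len(found & set(core_ids)), len(found)


@dataclass
class FlagellarCall:
    core_count: int
    total_count: int
    call: str  # flagellate-capable | non-flagellate | indeterminate


def flagellate_call(core_count: int, total_count: int) -> FlagellarCall:
    """Classify flagellate capability from flagellar-protein counts.

    Flagellate-capable requires core >= 40 and total >= 192;
    non-flagellate requires core <= 26 and total <= 140; anything in
    between is indeterminate.
    """
    if core_count < 0 or total_count < 0:
        raise ValueError("counts must be non-negative")
    if core_count >= FLAGELLATE_MIN[0] and total_count >= FLAGELLATE_MIN[1]:
        call = "flagellate-capable"
    elif core_count <= NON_FLAGELLATE_MAX[0] and total_count <= NON_FLAGELLATE_MAX[1]:
        call = "non-flagellate"
    else:
        call = "indeterminate"
    return FlagellarCall(core_count=core_count, total_count=total_count, call=call)


def _tokens(text: str) -> set[str]:
    return {t for t in "".join(c.lower() if c.isalnum() else " " for c in text).split() if t}


def candidate_gene_screen(
    proteome: ProteinSet,
    queries: ProteinSet,
    annotations: dict[str, str],
    min_score: float = 75.0,
    match: str = "all",
) -> tuple[set[str], dict[str, str]]:
    """Two-rule candidate screen: sequence similarity + annotation consistency.

    A proteome member is accepted iff (1) it has a hit at or above
    ``min_score`` to some query and (2) its annotation shares the best
    query's keyword set (case-insensitive token match; ``match='all'``
    requires every query token, ``'any'`` at least one).  Members whose
    annotation is missing or blank are rejected with reason
    ``annotation-inconsistent``.  Returns (accepted ids, rejection
    reasons for candidates that passed rule 1 only).
    """
    if not proteome or not queries:
        return set(), {}
    scores = score_matrix(queries, proteome)
    accepted: set[str] = set()
    reasons: dict[str, str] = {}
    for pid in proteome:
        col = scores[pid]
        top = col.max()
        if top < min_score:
            continue
        qid = sorted(col.index[col == top])[0]
        required = _tokens(annotations.get(qid, ""))
        have = _tokens(annotations.get(pid, ""))
        if not have:
            reasons[pid] = "annotation-inconsistent"
            continue
        ok = required <= have if match == "all" else bool(required & have)
        if ok and required:
            accepted.add(pid)
        else:
            reasons[pid] = "annotation-inconsistent"
    return accepted, reasons
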