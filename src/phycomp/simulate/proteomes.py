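"""Proteome pairs with planted ortholog families and shuffled decoys."""

from __future__ import annotations

import numpy as np

from phycomp.simulate.config import GroundTruth

__all__ = ["gen_proteomes"]

_AA = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype=np.uint8)
#: rough background amino-acid weights (uniform is fine for decoy scoring)
_AA_P = np.full(20, 1 / 20)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    codes = rng.choice(20, size=length, p=_AA_P)
    return bytes(_AA[codes]).decode("ascii")


def _diverge(seq: str, divergence: float, rng: np.random.Generator) -> str:
    """Substitute each site with probability ``divergence`` (new residue)."""
    if divergence == 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(len(arr)) < divergence
    # replace with a uniformly random *different* residue
    for i in np.nonzero(hit)[0]:
        choices = _AA[_AA != arr[i]]
        arr[i] = choices[rng.integers(len(choices))]
    return bytes(arr).decode("ascii")


def _shuffle(seq: str, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    rng.shuffle(arr)
    return bytes(arr).decode("ascii")


def gen_proteomes(
    n_families: int,
    divergence: float = 0.3,
    n_decoys: int = 0,
    protein_length: int = 120,
    seed: int = 0,
) -> tuple[dict[str, str], dict[str, str], GroundTruth]:
    """Two protein sets with one true ortholog pair per planted family.

    Proteome A holds the ancestral sequence of each family; proteome B a
    copy with i.i.d. substitutions at rate ``divergence`` per site.
    Each proteome additionally receives ``n_decoys`` composition-
    preserving shuffles of randomly chosen family members (or fresh
    random sequences when there are no families), so decoy hits share
    the real amino-acid background.
    """
    if divergence < 0:
        raise ValueError("divergence must be >= 0")
    rng = np.random.default_rng(seed)
    set_a: dict[str, str] = {}
    set_b: dict[str, str] = {}
    pairs: list[tuple[str, str]] = []
    ancestors: list[str] = []
    for i in range(n_families):
        anc = _random_protein(rng, protein_length)
        ancestors.append(anc)
        a_id, b_id = f"A_fam{i:03d}", f"B_fam{i:03d}"
        set_a[a_id] = anc
        set_b[b_id] = _diverge(anc, divergence, rng)
        pairs.append((a_id, b_id))
    for prefix, target in (("A", set_a), ("B", set_b)):
        for i in range(n_decoys):
            if ancestors:
                src = ancestors[int(rng.integers(len(ancestors)))]
                target[f"{prefix}_decoy{i:03d}"] = _shuffle(src, rng)
            else:
                target[f"{prefix}_decoy{i:03d}"] = _random_protein(rng, protein_length)
    truth = GroundTruth(
        kind="proteomes",
        seed=seed,
        data={
            "pairs": pairs,
            "divergence": divergence,
            "n_families": n_families,
            "n_decoys": n_decoys,
        },
    )
    return set_a, set_b, truth
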