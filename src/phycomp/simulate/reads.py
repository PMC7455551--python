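"""Read-set simulation from a genome of known size at known depth."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from phycomp.simulate.config import GroundTruth

__all__ = ["ReadSet", "gen_reads", "gen_genome"]

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class ReadSet:
    """Simulated reads kept as a compact (n_reads x read_length) code array."""

    codes: np.ndarray  # uint8, values 0..3
    read_length: int

    @property
    def n_reads(self) -> int:
        return self.codes.shape[0]

    @property
    def total_bases(self) -> int:
        return self.codes.size

    def sequences(self) -> list[str]:
        byte_mat = _BASE_BYTES[self.codes]
        return [bytes(row).decode("ascii") for row in byte_mat]

    def write_fastq(self, path) -> None:
        with open(path, "w") as fh:
            for i, seq in enumerate(self.sequences()):
                fh.write(f"@read_{i}\n{seq}\n+\n{'I' * len(seq)}\n")


def gen_genome(length: int, gc: float = 0.5, seed: int = 0) -> str:
    """Random genome sequence with the requested expected GC fraction."""
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    codes = rng.choice(4, size=length, p=probs).astype(np.uint8)
    return bytes(_BASE_BYTES[codes]).decode("ascii")


def gen_reads(
    genome_length: int,
    depth: float,
    read_length: int,
    error_rate: float = 0.0,
    seed: int = 0,
) -> tuple[str, ReadSet, GroundTruth]:
    """Simulate uniform shotgun reads from a fresh random genome.

    Returns ``(reference, reads, truth)``.  The number of reads is
    ``round(genome_length * depth / read_length)`` so total read bases
    match ``genome_length x depth`` to within one read.  Substitution
    errors are i.i.d. per base at ``error_rate``; reads come off either
    strand with equal probability.  No indels are simulated.
    """
    if read_length >= genome_length:
        raise ValueError("read_length must be smaller than genome_length")
    if depth <= 0:
        raise ValueError("depth must be positive")
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must lie in [0, 1)")

    rng = np.random.default_rng(seed)
    genome_codes = rng.integers(0, 4, size=genome_length, dtype=np.uint8)
    reference = bytes(_BASE_BYTES[genome_codes]).decode("ascii")

    n_reads = int(round(genome_length * depth / read_length))
    starts = rng.integers(0, genome_length - read_length + 1, size=n_reads)
    offsets = np.arange(read_length)
    reads = np.empty((n_reads, read_length), dtype=np.uint8)
    n_errors = 0
    # batch the window gather: keeps the int64 index array small
    batch = 200_000
    for lo in range(0, n_reads, batch):
        hi = min(lo + batch, n_reads)
        block = genome_codes[starts[lo:hi, None] + offsets[None, :]]
        rc_mask = rng.random(hi - lo) < 0.5
        block[rc_mask] = (3 - block[rc_mask])[:, ::-1]
        if error_rate > 0:
            # substitution errors shift by 1..3 mod 4 (never the original)
            err = rng.random(block.shape) < error_rate
            shift = rng.integers(1, 4, size=block.shape, dtype=np.uint8)
            block = np.where(err, (block + shift) % 4, block).astype(np.uint8)
            n_errors += int(err.sum())
        reads[lo:hi] = block

    truth = GroundTruth(
        kind="reads",
        seed=seed,
        data={
            "genome_length": genome_length,
            "depth": depth,
            "read_length": read_length,
            "error_rate": error_rate,
            "n_reads": n_reads,
            "n_errors": n_errors,
        },
    )
    return reference, ReadSet(codes=reads, read_length=read_length), truth
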