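"""K-mer spectrum genome-size estimation.

Depth and the k-mer peak are linked by M = N * (L - K + 1) / L, where M
is the k-mer coverage at the spectrum peak, N the base sequencing depth,
L the read length and K the k-mer length.  Genome size follows as the
total above-valley k-mer mass divided by M.  K-mers are canonicalized
(lexicographic minimum of a k-mer and its reverse complement) and any
window containing a non-ACGT symbol is skipped.

Only the haploid/homozygous model is implemented; there is no
heterozygous-peak mixture fitting.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "KmerSpectrum",
    "DepthModel",
    "count_kmers",
    "find_peak",
    "depth_from_peak",
    "estimate_genome_size",
]

_CODE = np.full(256, 4, dtype=np.uint8)  # 4 marks non-ACGT
for i, base in enumerate(b"ACGT"):
    _CODE[base] = i
    _CODE[base + 32] = i  # lowercase


@dataclass
class KmerSpectrum:
    """Multiplicity histogram of canonical k-mers plus read metadata."""

    K: int
    L: int  # representative (modal) read length
    counts: dict[int, int]  # multiplicity m -> number of distinct k-mers
    total_read_bases: int

    def __post_init__(self):
        if self.K > self.L:
            raise ValueError("K must not exceed the read length")
        if any(m < 1 for m in self.counts):
            raise ValueError("multiplicities must be >= 1")

    @property
    def total_kmer_instances(self) -> int:
        return sum(m * c for m, c in self.counts.items())

    @property
    def n_distinct(self) -> int:
        return sum(self.counts.values())

    def scaled(self, factor: float) -> "KmerSpectrum":
        return KmerSpectrum(
            K=self.K,
            L=self.L,
            counts={m: int(round(c * factor)) for m, c in self.counts.items()},
            total_read_bases=int(round(self.total_read_bases * factor)),
        )

    # two-column TSV, jellyfish-histo layout --------------------------
    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# K={self.K} L={self.L} total_read_bases={self.total_read_bases}\n")
            for m in sorted(self.counts):
                fh.write(f"{m}\t{self.counts[m]}\n")

    @classmethod
    def read_tsv(cls, path, K: int | None = None, L: int | None = None,
                 total_read_bases: int | None = None) -> "KmerSpectrum":
        counts: dict[int, int] = {}
        meta: dict[str, int] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    for token in line[1:].split():
                        if "=" in token:
                            key, val = token.split("=")
                            meta[key] = int(val)
                    continue
                m, c = line.split("\t")[:2]
                counts[int(m)] = int(c)
        return cls(
            K=K if K is not None else meta.get("K", 17),
            L=L if L is not None else meta.get("L", 100),
            counts=counts,
            total_read_bases=(
                total_read_bases
                if total_read_bases is not None
                else meta.get("total_read_bases", sum(m * c for m, c in counts.items()))
            ),
        )


@dataclass
class DepthModel:
    """Fitted peak/depth/genome-size model for one spectrum."""

    M: float  # k-mer coverage at the spectrum peak
    N: float  # base sequencing depth
    G: float  # genome size from k-mer mass / M
    G_bases: float  # genome size from total read bases / N
    valley: int  # multiplicity separating error peak from main peak

    def __post_init__(self):
        if self.G <= 0:
            raise ValueError("estimated genome size must be positive")


def _encode_reads(reads) -> tuple[np.ndarray, int, int]:
    """Concatenate reads into a code array with 4-valued separators."""
    chunks = []
    total_bases = 0
    lengths = Counter()
    sep = np.array([4], dtype=np.uint8)
    for read in reads:
        if hasattr(read, "codes"):  # simulate.reads.ReadSet
            n, L = read.codes.shape
            body = np.column_stack(
                [read.codes, np.full((n, 1), 4, dtype=np.uint8)]
            ).ravel()
            chunks.append(body)
            total_bases += read.total_bases
            lengths[L] += n
            continue
        seq = str(read)
        codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        chunks.append(codes)
        chunks.append(sep)
        total_bases += len(seq)
        lengths[len(seq)] += 1
    if total_bases == 0:
        raise ValueError("empty read set")
    modal_length = lengths.most_common(1)[0][0]
    return np.concatenate(chunks), total_bases, modal_length


def _canonical_codes(codes: np.ndarray, K: int, chunk: int = 8_000_000) -> np.ndarray:
    """Canonical k-mer integer codes of all valid windows, preallocated.

    Filled chunk-by-chunk into a single output array to keep the peak
    memory at one int64 array of the window count (plus small chunk
    temporaries).
    """
    n = len(codes) - K + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    bad_cum = np.zeros(len(codes) + 1, dtype=np.int32)
    np.cumsum(codes >= 4, dtype=np.int32, out=bad_cum[1:])
    safe = np.where(codes >= 4, 0, codes)  # uint8; cast per chunk below
    out = np.empty(n, dtype=np.int64)
    filled = 0
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        m = hi - lo
        fwd = np.zeros(m, dtype=np.int64)
        rev = np.zeros(m, dtype=np.int64)
        for j in range(K):
            window = safe[lo + j : lo + j + m].astype(np.int64)
            fwd = (fwd << 2) | window
            rev |= (3 - window) << (2 * j)
        np.minimum(fwd, rev, out=fwd)
        valid = (bad_cum[lo + K : hi + K] - bad_cum[lo:hi]) == 0
        kept = fwd[valid]
        out[filled : filled + len(kept)] = kept
        filled += len(kept)
    return out[:filled]


def count_kmers(reads, K: int) -> KmerSpectrum:
    """Build the canonical k-mer multiplicity spectrum of a read set.

    ``reads`` is an iterable of sequence strings (or a
    :class:`~phycomp.simulate.reads.ReadSet`).  Windows containing
    non-ACGT symbols are skipped.  Raises on an empty read set or K
    longer than the reads.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > 31:
        raise ValueError("K > 31 exceeds the 2-bit int64 packing")
    codes, total_bases, modal_length = _encode_reads(
        reads if not hasattr(reads, "codes") else [reads]
    )
    if K > modal_length:
        raise ValueError(f"K={K} exceeds read length {modal_length}")
    allcodes = _canonical_codes(codes, K)
    del codes
    if len(allcodes) == 0:
        raise ValueError("no valid k-mer windows")
    allcodes.sort()  # in-place introsort: no extra full-size copy
    boundary = np.flatnonzero(allcodes[1:] != allcodes[:-1])
    edges = np.concatenate([[-1], boundary, [len(allcodes) - 1]])
    multiplicities = np.diff(edges)
    ms, cs = np.unique(multiplicities, return_counts=True)
    counts = {int(m): int(c) for m, c in zip(ms, cs)}
    return KmerSpectrum(K=K, L=modal_length, counts=counts, total_read_bases=total_bases)


def find_peak(spectrum: KmerSpectrum) -> tuple[int, int]:
    """Locate the main peak M and the error valley of a spectrum.

    The valley is the smallest multiplicity m >= 2 that is a local
    minimum of the histogram left of the global mode (0 when the
    spectrum is unimodal); M is the argmax of counts over m > valley.
    """
    if not spectrum.counts:
        raise ValueError("empty spectrum")
    max_m = max(spectrum.counts)
    dense = np.zeros(max_m + 2, dtype=np.int64)
    for m, c in spectrum.counts.items():
        dense[m] = c
    valley = 0
    for m in range(2, max_m):
        if dense[m] < dense[m - 1] and dense[m] <= dense[m + 1]:
            valley = m
            break
    above = dense[valley + 1 :]
    if above.sum() == 0:
        raise ValueError("spectrum too shallow: no mode above the valley")
    M = valley + 1 + int(np.argmax(above))
    return M, valley


def depth_from_peak(M: float, L: int, K: int) -> float:
    """Invert M = N * (L - K + 1) / L for the base depth N."""
    if K > L:
        raise ValueError("K must not exceed L")
    if K < 1 or M <= 0:
        raise ValueError("require K >= 1 and M > 0")
    return M * L / (L - K + 1)


def estimate_genome_size(spectrum: KmerSpectrum) -> DepthModel:
    """Fit the haploid depth model and estimate genome size.

    G = (sum of m * counts[m] over m > valley) / M, excluding the error
    mass below the valley; G_bases = total_read_bases / N is reported as
    a cross-check (the two agree closely on error-free data).
    """
    M, valley = find_peak(spectrum)
    if valley >= M:
        raise ValueError("valley at or above the peak; cannot fit model")
    mass = sum(m * c for m, c in spectrum.counts.items() if m > valley)
    N = depth_from_peak(M, spectrum.L, spectrum.K)
    return DepthModel(
        M=float(M),
        N=N,
        G=mass / M,
        G_bases=spectrum.total_read_bases / N,
        valley=valley,
    )


# ----------------------------------------------------------------------
# file input
# ----------------------------------------------------------------------

def read_sequences(path):
    """Iterate sequences from FASTA/FASTQ, plain or gzipped."""
    from Bio import SeqIO

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    stem = path.name[:-3] if path.suffix == ".gz" else path.name
    fmt = "fastq" if stem.endswith((".fastq", ".fq")) else "fasta"
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, fmt):
            yield str(rec.seq)
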