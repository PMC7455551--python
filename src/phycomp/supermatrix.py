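"""Supermatrix construction: gap masking, concatenation, partition files.

Coordinates in partition records are 1-based inclusive, matching the
RAxML/NEXUS conventions.  Kept-column maps record, per input block, which
original columns survived masking and where they sit in the concatenated
frame.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AlignmentBlock",
    "Supermatrix",
    "mask_gappy_columns",
    "concatenate",
    "write_partitioned",
    "read_alignment_fasta",
]

#: Symbols counted as gap-or-missing during column masking, per alphabet.
GAPLIKE = {
    "nt": set("-?Nn"),
    "aa": set("-?Xx"),
}


@dataclass
class AlignmentBlock:
    """One locus: taxa mapped to equal-length aligned sequences."""

    locus: str
    sequences: dict[str, str]
    alphabet: str = "nt"  # "nt" | "aa"

    def __post_init__(self):
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(f"unequal row lengths in block {self.locus!r}: {lengths}")
        if self.alphabet not in GAPLIKE:
            raise ValueError(f"unknown alphabet: {self.alphabet!r}")

    @property
    def taxa(self) -> list[str]:
        return list(self.sequences)

    @property
    def length(self) -> int:
        if not self.sequences:
            return 0
        return len(next(iter(self.sequences.values())))

    def column(self, i: int) -> dict[str, str]:
        """0-based column as taxon -> symbol."""
        return {t: s[i] for t, s in self.sequences.items()}


@dataclass
class Supermatrix:
    """Concatenated alignment with partition bookkeeping."""

    sequences: dict[str, str]
    partitions: list[tuple[str, int, int]]  # (label, start, end), 1-based inclusive
    alphabet: str = "nt"
    column_maps: dict[str, list[int]] = field(default_factory=dict)

    @property
    def length(self) -> int:
        if not self.sequences:
            return 0
        return len(next(iter(self.sequences.values())))

    @property
    def taxa(self) -> list[str]:
        return list(self.sequences)

    def validate(self) -> None:
        expect = 1
        for label, start, end in self.partitions:
            if start != expect or end < start:
                raise ValueError(f"partition {label!r} not contiguous at {start}-{end}")
            expect = end + 1
        if self.partitions and expect - 1 != self.length:
            raise ValueError("partitions do not cover the matrix")


def mask_gappy_columns(
    block: AlignmentBlock, threshold: float = 0.5, count_missing: bool = True
) -> tuple[AlignmentBlock, list[int]]:
    """Drop columns whose gap fraction is >= ``threshold``.

    Returns the masked block and the 0-based indices of kept columns (in
    original coordinates, strictly increasing).  ``count_missing``
    includes missing-data symbols (?, N/X) in the gap tally; when False
    only "-" counts.  If every column is removed a warning is issued and
    an empty block returned.
    """
    if not block.sequences:
        raise ValueError("empty alignment block")
    gapset = GAPLIKE[block.alphabet] if count_missing else {"-"}
    n_taxa = len(block.sequences)
    rows = list(block.sequences.values())
    kept: list[int] = []
    for j in range(block.length):
        gaps = sum(1 for row in rows if row[j] in gapset)
        if gaps / n_taxa < threshold:
            kept.append(j)
    if not kept and block.length > 0:
        warnings.warn(f"all {block.length} columns masked in block {block.locus!r}")
    masked = AlignmentBlock(
        locus=block.locus,
        sequences={t: "".join(s[j] for j in kept) for t, s in block.sequences.items()},
        alphabet=block.alphabet,
    )
    return masked, kept


def concatenate(blocks: list[AlignmentBlock]) -> Supermatrix:
    """Join blocks in order into a partitioned supermatrix.

    Taxa are the union over blocks; a taxon absent from a block is filled
    with "-" across that block's span.  Duplicate locus labels are
    rejected.
    """
    labels = [b.locus for b in blocks]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate locus labels: {dupes}")
    taxa: list[str] = []
    for b in blocks:
        for t in b.taxa:
            if t not in taxa:
                taxa.append(t)
    parts: list[tuple[str, int, int]] = []
    chunks: dict[str, list[str]] = {t: [] for t in taxa}
    column_maps: dict[str, list[int]] = {}
    offset = 0
    for b in blocks:
        parts.append((b.locus, offset + 1, offset + b.length))
        for t in taxa:
            chunks[t].append(b.sequences.get(t, "-" * b.length))
        column_maps[b.locus] = list(range(offset, offset + b.length))
        offset += b.length
    matrix = Supermatrix(
        sequences={t: "".join(chunks[t]) for t in taxa},
        partitions=parts,
        alphabet=blocks[0].alphabet if blocks else "nt",
        column_maps=column_maps,
    )
    matrix.validate()
    return matrix


_ILLEGAL = re.compile(r"[^\w.\-]")


def _sanitize(name: str) -> str:
    return _ILLEGAL.sub("_", name)


def write_partitioned(
    matrix: Supermatrix,
    prefix,
    fmt: str = "phylip",
    partition_dialect: str = "raxml",
) -> dict[str, Path]:
    """Write the matrix plus a partition file; returns written paths.

    ``fmt`` is ``phylip`` (relaxed) or ``fasta``; ``partition_dialect``
    is ``raxml`` or ``nexus``.  Taxon names illegal for the dialect are
    sanitized (whitespace etc. -> "_") and the mapping is recorded in
    ``<prefix>.names.tsv`` when any renaming happened.
    """
    if not matrix.sequences:
        raise ValueError("empty supermatrix")
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    renames = {t: _sanitize(t) for t in matrix.taxa}
    records = [
        SeqRecord(Seq(seq), id=renames[t], description="")
        for t, seq in matrix.sequences.items()
    ]
    written: dict[str, Path] = {}

    if fmt == "phylip":
        aln_path = prefix.with_suffix(".phy")
        AlignIO.write(MultipleSeqAlignment(records), str(aln_path), "phylip-relaxed")
    elif fmt == "fasta":
        aln_path = prefix.with_suffix(".fasta")
        SeqIO.write(records, str(aln_path), "fasta")
    else:
        raise ValueError(f"unknown format: {fmt!r}")
    written["alignment"] = aln_path

    part_path = prefix.parent / (prefix.name + ".partitions")
    datatype = "DNA" if matrix.alphabet == "nt" else "PROT"
    with open(part_path, "w") as fh:
        if partition_dialect == "raxml":
            for label, start, end in matrix.partitions:
                fh.write(f"{datatype}, {_sanitize(label)} = {start}-{end}\n")
        elif partition_dialect == "nexus":
            fh.write("#nexus\nbegin sets;\n")
            for label, start, end in matrix.partitions:
                fh.write(f"    charset {_sanitize(label)} = {start}-{end};\n")
            fh.write("end;\n")
        else:
            raise ValueError(f"unknown partition dialect: {partition_dialect!r}")
    written["partitions"] = part_path

    if any(t != s for t, s in renames.items()):
        map_path = prefix.parent / (prefix.name + ".names.tsv")
        with open(map_path, "w") as fh:
            fh.write("original\tsanitized\n")
            for t, s in renames.items():
                if t != s:
                    fh.write(f"{t}\t{s}\n")
        written["names"] = map_path
    return written


def read_supermatrix(aln_path, partition_path, alphabet: str = "nt") -> Supermatrix:
    """Read back an alignment + raxml-style partition file pair."""
    aln_path = Path(aln_path)
    fmt = "fasta" if aln_path.suffix in (".fasta", ".fa", ".fna", ".faa") else "phylip-relaxed"
    aln = AlignIO.read(str(aln_path), fmt)
    sequences = {rec.id: str(rec.seq) for rec in aln}
    partitions = []
    with open(partition_path) as fh:
        for line in fh:
            m = re.match(r"\s*\w+,\s*(\S+)\s*=\s*(\d+)-(\d+)", line)
            if m:
                partitions.append((m.group(1), int(m.group(2)), int(m.group(3))))
    matrix = Supermatrix(sequences=sequences, partitions=partitions, alphabet=alphabet)
    matrix.validate()
    return matrix


def read_alignment_fasta(path, locus: str | None = None, alphabet: str = "nt") -> AlignmentBlock:
    """Read one aligned FASTA file as an AlignmentBlock."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    return AlignmentBlock(
        locus=locus or path.stem,
        sequences={rec.id: str(rec.seq) for rec in records},
        alphabet=alphabet,
    )
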