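"""Structural genome descriptors: GC, interval fractions, exon/intron lengths.

GFF3 coordinates are 1-based inclusive throughout; BED input (0-based
half-open) is converted at the I/O boundary only.  Introns are derived
as the gaps between consecutive exons of a transcript rather than read
from intron features, since annotations routinely omit them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Transcript",
    "GeneModelSet",
    "StructureSummary",
    "gc_content",
    "interval_fraction",
    "exon_intron_lengths",
    "compare_species",
    "read_bed_intervals",
]


@dataclass
class Transcript:
    gene_id: str
    transcript_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]  # 1-based inclusive, ascending
    cds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        prev_end = 0
        for start, end in self.exons:
            if start <= prev_end:
                raise ValueError(
                    f"overlapping exons in transcript {self.transcript_id!r}"
                )
            if end < start:
                raise ValueError(f"negative-length exon in {self.transcript_id!r}")
            prev_end = end

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def exon_lengths(self) -> list[int]:
        return [end - start + 1 for start, end in self.exons]

    def intron_lengths(self) -> list[int]:
        """Gaps between consecutive exons; count is n_exons - 1."""
        out = []
        for (_, end_a), (start_b, _) in zip(self.exons, self.exons[1:]):
            out.append(start_b - end_a - 1)
        return out


@dataclass
class GeneModelSet:
    """Genome sequences plus nested gene models."""

    genome: dict[str, str]
    transcripts: list[Transcript]

    @classmethod
    def from_files(cls, fasta_path, gff3_path) -> "GeneModelSet":
        from Bio import SeqIO
        import gffutils

        genome = {
            rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")
        }
        db = gffutils.create_db(
            str(gff3_path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
        transcripts = []
        for mrna in db.features_of_type("mRNA"):
            exons = [
                (f.start, f.end) for f in db.children(mrna, featuretype="exon")
            ]
            cds = [(f.start, f.end) for f in db.children(mrna, featuretype="CDS")]
            parents = list(db.parents(mrna, featuretype="gene"))
            gene_id = parents[0].id if parents else mrna.id
            transcripts.append(
                Transcript(
                    gene_id=gene_id,
                    transcript_id=mrna.id,
                    contig=mrna.seqid,
                    strand=mrna.strand,
                    exons=exons,
                    cds=cds,
                )
            )
        return cls(genome=genome, transcripts=transcripts)

    def to_gff3(self) -> str:
        lines = ["##gff-version 3"]
        for tr in self.transcripts:
            start, end = tr.span
            common = f"{tr.contig}\tphycomp\t"
            tail = f"\t.\t{tr.strand}\t"
            lines.append(
                f"{common}gene\t{start}\t{end}{tail}.\tID={tr.gene_id}"
            )
            lines.append(
                f"{common}mRNA\t{start}\t{end}{tail}.\t"
                f"ID={tr.transcript_id};Parent={tr.gene_id}"
            )
            for k, (s, e) in enumerate(tr.exons, 1):
                lines.append(
                    f"{common}exon\t{s}\t{e}{tail}.\t"
                    f"ID={tr.transcript_id}.exon{k};Parent={tr.transcript_id}"
                )
            for k, (s, e) in enumerate(tr.cds, 1):
                lines.append(
                    f"{common}CDS\t{s}\t{e}{tail}0\t"
                    f"ID={tr.transcript_id}.cds{k};Parent={tr.transcript_id}"
                )
        return "\n".join(lines) + "\n"

    def write(self, fasta_path, gff3_path) -> None:
        with open(fasta_path, "w") as fh:
            for contig, seq in self.genome.items():
                fh.write(f">{contig}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        Path(gff3_path).write_text(self.to_gff3())

    @property
    def genome_length(self) -> int:
        return sum(len(s) for s in self.genome.values())

    def cds_intervals(self) -> list[tuple[str, int, int]]:
        return [
            (tr.contig, s, e) for tr in self.transcripts for s, e in tr.cds
        ]

    def exon_intervals(self) -> list[tuple[str, int, int]]:
        return [
            (tr.contig, s, e) for tr in self.transcripts for s, e in tr.exons
        ]


@dataclass
class StructureSummary:
    """Per-species structural descriptors (fractions in [0, 1])."""

    species: str
    gc: float | None = None
    repeat_fraction: float | None = None
    coding_fraction: float | None = None
    exon_lengths: list[int] = field(default_factory=list)
    intron_lengths: list[int] = field(default_factory=list)
    mean_gene_length: float | None = None
    mean_gene_spacing: float | None = None

    def _stats(self, values: list[int]) -> dict[str, float | None]:
        if not values:
            return {"mean": None, "median": None, "q1": None, "q3": None, "n": 0}
        arr = np.asarray(values, dtype=float)
        return {
            "mean": float(arr.mean()),
            "median": float(np.median(arr)),
            "q1": float(np.percentile(arr, 25)),
            "q3": float(np.percentile(arr, 75)),
            "n": len(values),
        }

    @property
    def exon_stats(self) -> dict[str, float | None]:
        return self._stats(self.exon_lengths)

    @property
    def intron_stats(self) -> dict[str, float | None]:
        return self._stats(self.intron_lengths)


def gc_content(genome: dict[str, str] | str) -> float:
    """(G+C)/(A+C+G+T); ambiguity symbols excluded from the denominator."""
    if isinstance(genome, str):
        genome = {"_": genome}
    if not genome or all(len(s) == 0 for s in genome.values()):
        raise ValueError("empty sequence set")
    gc = acgt = 0
    for seq in genome.values():
        arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
        for byte in b"GC":
            gc += int((arr == byte).sum())
        for byte in b"AT":
            acgt += int((arr == byte).sum())
    acgt += gc
    if acgt == 0:
        raise ValueError("no unambiguous A/C/G/T bases in input")
    return gc / acgt


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def interval_fraction(
    genome: dict[str, str], intervals: list[tuple[str, int, int]], role: str = "CDS"
) -> float:
    """Fraction of the genome covered by the merged union of intervals.

    Intervals are (contig, start, end), 1-based inclusive.  Overlapping
    and duplicate intervals are merged before summing, so the result is
    idempotent under duplication and invariant to splitting.
    """
    genome_length = sum(len(s) for s in genome.values())
    if genome_length == 0:
        raise ValueError("empty genome")
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for contig, start, end in intervals:
        if contig not in genome:
            raise ValueError(f"{role} interval on unknown contig {contig!r}")
        if start < 1 or end > len(genome[contig]):
            raise ValueError(
                f"{role} interval {contig}:{start}-{end} outside contig bounds"
            )
        by_contig.setdefault(contig, []).append((start, end))
    covered = 0
    for contig, ivs in by_contig.items():
        covered += sum(e - s + 1 for s, e in _merge(ivs))
    return covered / genome_length


def read_bed_intervals(path) -> list[tuple[str, int, int]]:
    """BED (0-based half-open) -> internal 1-based inclusive intervals."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            out.append((fields[0], int(fields[1]) + 1, int(fields[2])))
    return out


def exon_intron_lengths(
    models: GeneModelSet,
    species: str = "sample",
    repeats: list[tuple[str, int, int]] | None = None,
    coding: str = "cds",
) -> StructureSummary:
    """Full structural summary of one annotated genome.

    ``coding`` selects whether the coding fraction counts CDS intervals
    (default) or all exonic sequence.  Gene spacing is the gap between
    consecutive gene spans along each contig.
    """
    exon_lengths: list[int] = []
    intron_lengths: list[int] = []
    spans_by_contig: dict[str, list[tuple[int, int]]] = {}
    for tr in models.transcripts:
        if not tr.exons:
            raise ValueError(f"transcript {tr.transcript_id!r} has no exons")
        exon_lengths.extend(tr.exon_lengths())
        intron_lengths.extend(tr.intron_lengths())
        spans_by_contig.setdefault(tr.contig, []).append(tr.span)

    gene_lengths = [
        e - s + 1 for spans in spans_by_contig.values() for s, e in spans
    ]
    spacings: list[int] = []
    for spans in spans_by_contig.values():
        spans = sorted(spans)
        for (_, end_a), (start_b, _) in zip(spans, spans[1:]):
            spacings.append(max(0, start_b - end_a - 1))

    intervals = models.cds_intervals() if coding == "cds" else models.exon_intervals()
    coding_fraction = (
        interval_fraction(models.genome, intervals, role="CDS") if intervals else 0.0
    )
    repeat_fraction = (
        interval_fraction(models.genome, repeats, role="repeat")
        if repeats
        else None
    )
    return StructureSummary(
        species=species,
        gc=gc_content(models.genome) if models.genome else None,
        repeat_fraction=repeat_fraction,
        coding_fraction=coding_fraction,
        exon_lengths=exon_lengths,
        intron_lengths=intron_lengths,
        mean_gene_length=float(np.mean(gene_lengths)) if gene_lengths else None,
        mean_gene_spacing=float(np.mean(spacings)) if spacings else None,
    )


def compare_species(summaries: list[StructureSummary]) -> pd.DataFrame:
    """Tidy (species, metric, value) table; input order preserved.

    Missing metrics appear as explicit NA rows rather than being dropped.
    """
    if len(summaries) < 2:
        raise ValueError("need summaries for at least 2 species")
    rows = []
    for s in summaries:
        rows.append((s.species, "gc", s.gc))
        rows.append((s.species, "repeat_fraction", s.repeat_fraction))
        rows.append((s.species, "coding_fraction", s.coding_fraction))
        rows.append((s.species, "mean_exon_length", s.exon_stats["mean"]))
        rows.append((s.species, "mean_intron_length", s.intron_stats["mean"]))
        rows.append((s.species, "mean_gene_length", s.mean_gene_length))
        rows.append((s.species, "mean_gene_spacing", s.mean_gene_spacing))
    return pd.DataFrame(rows, columns=["species", "metric", "value"])
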