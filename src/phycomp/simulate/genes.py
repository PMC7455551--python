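"""Gene-model generation: genome + GFF3 with fully known structure."""

from __future__ import annotations

import numpy as np

from phycomp.genomestats import GeneModelSet, Transcript
from phycomp.simulate.config import GroundTruth

__all__ = ["gen_gene_models"]

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _draw(law, rng: np.random.Generator) -> int:
    """One positive length from a law: int | ("uniform", lo, hi) | ("lognormal", mu, sigma)."""
    if isinstance(law, (int, np.integer)):
        value = int(law)
    elif law[0] == "uniform":
        value = int(rng.integers(law[1], law[2] + 1))
    elif law[0] == "lognormal":
        value = int(round(rng.lognormal(law[1], law[2])))
    else:
        raise ValueError(f"unknown length law: {law!r}")
    if value <= 0:
        raise ValueError(f"law {law!r} produced non-positive length {value}")
    return max(1, value)


def gen_gene_models(
    n_genes: int,
    exon_length_law,
    intron_length_law,
    intergenic_law=200,
    exons_per_gene=2,
    seed: int = 0,
    contig: str = "chr1",
) -> tuple[GeneModelSet, GroundTruth]:
    """Lay out ``n_genes`` non-overlapping genes on one contig.

    ``exon_length_law`` may be a list of explicit exon lengths (used
    verbatim for every gene, overriding ``exons_per_gene``) or a length
    law; likewise ``intron_length_law`` (list cycled per junction).
    Coordinates are 1-based inclusive; every exon doubles as CDS, so the
    true coding fraction equals total exon bases over genome length.
    Strands alternate +/- to exercise strand handling; all reported
    lengths are strand-invariant.
    """
    rng = np.random.default_rng(seed)
    transcripts: list[Transcript] = []
    truth_genes = []
    all_exon_lengths: list[int] = []
    all_intron_lengths: list[int] = []
    pos = 0  # 0-based cursor; features emitted 1-based

    for i in range(n_genes):
        pos += _draw(intergenic_law, rng)
        if isinstance(exon_length_law, (list, tuple)) and not (
            isinstance(exon_length_law, tuple) and isinstance(exon_length_law[0], str)
        ):
            exon_lengths = [int(x) for x in exon_length_law]
        else:
            n_ex = _draw(exons_per_gene, rng) if not isinstance(exons_per_gene, int) else exons_per_gene
            exon_lengths = [_draw(exon_length_law, rng) for _ in range(n_ex)]
        n_introns = len(exon_lengths) - 1
        if isinstance(intron_length_law, (list, tuple)) and not (
            isinstance(intron_length_law, tuple) and isinstance(intron_length_law[0], str)
        ):
            pool = [int(x) for x in intron_length_law]
            intron_lengths = [pool[k % len(pool)] for k in range(n_introns)]
        else:
            intron_lengths = [_draw(intron_length_law, rng) for _ in range(n_introns)]

        exons = []
        cursor = pos
        for k, ex_len in enumerate(exon_lengths):
            exons.append((cursor + 1, cursor + ex_len))  # 1-based inclusive
            cursor += ex_len
            if k < n_introns:
                cursor += intron_lengths[k]
        pos = cursor
        strand = "+" if i % 2 == 0 else "-"
        gene_id = f"gene_{i:04d}"
        transcripts.append(
            Transcript(
                gene_id=gene_id,
                transcript_id=f"{gene_id}.t1",
                contig=contig,
                strand=strand,
                exons=exons,
                cds=list(exons),
            )
        )
        all_exon_lengths.extend(exon_lengths)
        all_intron_lengths.extend(intron_lengths)
        truth_genes.append(
            {
                "gene_id": gene_id,
                "strand": strand,
                "exon_lengths": exon_lengths,
                "intron_lengths": intron_lengths,
                "span": [exons[0][0], exons[-1][1]],
            }
        )

    genome_length = pos + _draw(intergenic_law, rng)
    codes = rng.integers(0, 4, size=genome_length, dtype=np.uint8)
    genome = {contig: bytes(_BASE_BYTES[codes]).decode("ascii")}
    models = GeneModelSet(genome=genome, transcripts=transcripts)

    coding_bases = sum(all_exon_lengths)
    truth = GroundTruth(
        kind="gene_models",
        seed=seed,
        data={
            "genes": truth_genes,
            "exon_lengths": all_exon_lengths,
            "intron_lengths": all_intron_lengths,
            "genome_length": genome_length,
            "cds_fraction": coding_bases / genome_length if genome_length else 0.0,
        },
    )
    return models, truth
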