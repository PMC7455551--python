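# phycomp

Comparative phylogenomics toolkit for the analyses that surround an
early-diverging green-algal genome project: k-mer genome-size
estimation, orthogroup set algebra and ancestral core-genome
reconstruction, Dollo gain/loss trait mapping, reciprocal-best-hit
protein inventories with a flagellate-capability classifier,
supermatrix construction with gap masking, and tree-aware synapomorphy
scanning.  A first-class synthetic-data module generates every input
class with recorded ground truth, so the whole pipeline is testable
offline.

## Modules

| module | what it does |
|---|---|
| `phycomp.simulate` | generators for trees, trait histories, orthogroup tables, alignments with planted diagnostic columns, shotgun reads, proteome pairs, and gene models — each with a JSON ground-truth sidecar |
| `phycomp.kmer` | canonical k-mer spectra, peak/valley detection, depth via `M = N(L-K+1)/L`, genome-size estimation |
| `phycomp.orthogroups` | Venn partitioning, span-rule core genome at a tree node, per-species taxon-span fractions, early-lineage family trichotomy |
| `phycomp.traits` | Dollo (single-gain) and Fitch parsimony mapping, ancestral toolboxes, per-branch event tables |
| `phycomp.rbh` | affine-gap Smith–Waterman (BLOSUM62), reciprocal best hits, panel inventories, flagellate call (≥40/≥192 vs ≤26/≤140), annotation-consistency screens |
| `phycomp.supermatrix` | ≥50%-gap column masking, ordered concatenation with partition bookkeeping, relaxed PHYLIP/FASTA + RAxML/NEXUS partition files |
| `phycomp.synapomorphy` | clade-diagnostic column scan, homoplasy classification against control alignments (NHS / parallelism / reversal / ambiguous) |
| `phycomp.genomestats` | GC content, merged-interval coverage fractions, exon/intron length summaries, cross-species comparison tables |

## Command-line tools

Each stage has its own entry point (see `--help` for options):

```bash
simgen tree|traits|orthogroups|alignment|reads|proteomes|genes --seed 1 --out DIR
kmersize --k 17 --reads reads.fastq --report report.json
orthalg venn|core|span|trichotomy --table Orthogroups.GeneCount.tsv --groups groups.yaml
traitevo map --matrix traits.tsv --tree tree.nwk --mode dollo --out DIR
rbhscan inventory --proteome prot.fasta --panel panel.fasta --core-ids core.txt
rbhscan screen --proteome prot.fasta --queries q.fasta --annotations ann.tsv
supermat --aln-dir alignments/ --mask 0.5 --out prefix
synscan --aln aln.fasta --tree tree.nwk --clade CLADE --control big_aln.fasta
gstats --genome genome.fasta --gff genes.gff3 [--repeats repeats.bed]
```

Example end-to-end: simulate reads and re-estimate the genome size,

```bash
simgen reads --seed 1 --out sim --genome-length 1000000 --depth 30
kmersize --k 17 --reads sim/reads.fastq --report sim/report.json
```

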