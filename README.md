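# ecotypekit

Comparative genomics of closely related bacterial genomes, built around the
analyses used to delineate ecotypes within a bacterial family:

- **AAI** — reciprocal-best-hit average amino-acid identity between
  proteomes, via exact affine-gap Smith–Waterman (BLOSUM62, open 11 /
  extend 1) with an optional k-mer prescreen for large proteome pairs.
- **Phylogenomics** — RBH-graph ortholog groups, single-copy-per-genome
  ortholog (SCGO) selection, progressive multiple alignment, concatenation
  with partitions (relaxed PHYLIP + RAxML-style partition export), neighbor
  joining on Poisson-corrected distances with column bootstrap supports.
- **16S × AAI rank zoning** — pairwise 16S identity (end-gap-free global
  alignment) and taxonomic-rank calls from empirical AAI zones.
- **Genomic islands & hot spots** — runs of genes unique to one genome of a
  pair, corroborated by GC-window z-scores, flanking tRNAs, or
  recombinase-like annotations; islands from both genomes mapped onto
  shared syntenic gaps to find recombination hot spots.
- **Metabolic-module inventory** — copy numbers of multi-gene modules
  (methylotrophy and nitrogen metabolism defaults included) from product
  keywords plus optional homology to reference proteins.
- **Simulator** — genome pairs/sets with exact amino-acid divergence truth,
  planted GC-shifted islands at tRNA integration sites, gene loss and
  duplication noise, emitted as standard FASTA + GFF3 + JSON truth.

## CLI

```sh
ecotypekit simulate-pair --seed 1 --n-genes 300 --divergence 0.05 \
    --islands 4 --hotspots 2 --out simdir/
ecotypekit aai simdir/sim1_a.fasta:simdir/sim1_a.gff3 \
    simdir/sim1_b.fasta:simdir/sim1_b.gff3 --out aai.tsv
ecotypekit islands A.fasta:A.gff3 B.fasta:B.gff3
ecotypekit hotspots A.fasta:A.gff3 B.fasta:B.gff3
ecotypekit tree A.fasta:A.gff3 B.fasta:B.gff3 C.fasta:C.gff3 --bootstrap 100
ecotypekit inventory A.fasta:A.gff3
ecotypekit classify --aai 90.6 --rrna-id 99.5
ecotypekit run-all pipeline.yaml
```

Genome inputs are given as `FASTA:FEATURES[:dialect]` with dialect `gff3`
(default) or `genbank_table` (a TSV with 1-based inclusive coordinates; see
`genome_io.TABLE_COLUMNS`). A pipeline YAML lists genomes, thresholds,
seed, stages and an output directory; `run-all` writes the AAI/16S
matrices, SCGO tree, per-pair island and hot-spot tables, module inventory,
rank calls, a run log and a MANIFEST, all byte-reproducible for a fixed
config and seed.

## Conventions

Internal coordinates are 0-based half-open (GFF3 converts at the boundary);
GC fractions exclude ambiguous bases; translation uses the bacterial code
(table 11) with the terminal stop trimmed; identity uses the BLAST
convention (matches / aligned columns including internal gaps); coverage
thresholds apply to both partners (`min(qcov, scov)`).
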