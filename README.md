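# bcrtrace

Longitudinal single-cell B-cell receptor (BCR) repertoire analysis:
chain filtering, clonotyping, class-switch detection, clonal lineage
trees, somatic-hypermutation profiling, usage statistics over visits, and
antigen-specific CDR3 queries — with a built-in simulator so the whole
pipeline is testable without any data download.

## Who this is for

Studies that profile the same donor's B cells at several time points
around a vaccination or infection (e.g. single-cell 5' V(D)J sequencing of
plasmablasts at days 0, 5, 7, 10, 14) need to answer a recurring set of
questions from the contig annotation tables: which cells descend from the
same ancestral rearrangement, which clones class-switched, how mutated
each lineage is and in which V-region segments, how V/J usage shifts
between visits, and whether any clones resemble antibodies of known
specificity. `bcrtrace` implements that workflow as a library plus a thin
`bcrtrace` command-line tool, consuming AIRR Rearrangement TSVs or 10x
`filtered_contig_annotations.csv` files.

## The core definitions

**Clonotype.** Heavy chains belong to one clone when they share the V
*family* (e.g. IGHV3) and J gene, and their CDR3 nucleotide sequences
reach 80% Levenshtein identity,

    identity(a, b) = 1 − d_Lev(a, b) / max(|a|, |b|),

linked transitively (single-linkage connected components). V-*gene*-level
grouping is available for comparison, and the unadjusted Rand index
quantifies how much the two partitions differ.

**Class switching.** A clonotype whose members use ≥ 2 distinct IGH
constant genes has undergone class-switch recombination; isotype pairs
are tabulated in a clone co-occurrence matrix, and the genomic constant
gene order (IGHM → IGHD → IGHG3 → IGHG1 → IGHA1 → IGHG2 → IGHG4 → IGHE →
IGHA2) acts as an irreversibility constraint.

**Lineages.** Per clone, unique V-region sequences (IMGT-gapped) form a
minimum-spanning tree rooted at the germline, with edge weights equal to
substitution counts. Inferred nodes are added where sibling branches
share identical mutations (evidence of an unsampled ancestor) and where
isotypes would otherwise switch backwards along a path.

**Antigen queries.** Literature CDR3 amino-acid sequences of antibodies
with known specificity (tetanus/diphtheria/pertussis toxoid, …) are
searched against repertoire junctions at a relaxed identity (default
0.65) within a length-flexibility window (default ±3 residues).

See `docs/methods.md` for the full model description, parameter defaults
and limitations.

## Worked example

Simulate a default repertoire (300 clones, power-law sizes, six visits),
filter it, assign clonotypes and compare grouping levels:

```sh
$ bcrtrace simulate --seed 7 --out sim/
INFO simulated 1156 chains into sim
$ bcrtrace filter --in sim/chains.tsv --out filtered.tsv
INFO retained 1108 chains
$ bcrtrace clonotype --in filtered.tsv --out clones.tsv \
      --summary summary.csv --compare-grouping
INFO 554 heavy chains -> 300 clonotypes
rand_index(family, gene) = 1.0000
```

The 1108 surviving chains are the productive heavy+light pairs of 554
cells — the 48 dropped contigs are the simulator's planted unproductive
and low-read decoys. The 554 heavy chains recover exactly the 300
simulated clones, and on this repertoire the gene- and family-level
partitions happen to coincide (Rand index 1.0 — no two genes of one
family carry near-identical CDR3s here). Downstream:

```sh
$ bcrtrace csr --in clones.tsv --out-dir csr/
INFO 240 single- and 60 multi-isotype clonotypes
$ bcrtrace lineage --in clones.tsv --clone-id 1 --out tree.json --format json
INFO clone 1: 39 nodes, total weight 239
$ bcrtrace shm --in clones.tsv --out-dir shm/
INFO heavy-light mutation correlation r=0.779 (p=4e-114, n=554)
```

The positive heavy–light correlation reflects the simulator's shared
per-cell mutation-rate factor: cells that mutated their heavy chain more
also mutated their light chain more. A single `bcrtrace run --config
run.yaml --seed 5 --out out/` executes all stages in order and writes a
manifest with input digests and parameters; rerunning with the same seed
reproduces every stage output byte-for-byte.

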