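# Methods

This note documents the models and procedures implemented in `bcrtrace`,
the assumptions behind them, the tunable parameters that matter, and what
the synthetic-data generator does and does not emulate.

## Input model and filtering

The unit of analysis is a *chain record*: one assembled V(D)J contig of one
cell, carrying gene calls (`v_call`, `d_call`, `j_call`, `c_call`), the
junction/CDR3 at nucleotide and amino-acid level, read/UMI support, a visit
label, and optionally an IMGT-gapped V-region alignment with its germline
and region boundaries. Tables arrive either in AIRR Rearrangement TSV or in
the 10x `filtered_contig_annotations.csv` layout; 10x columns are renamed
onto the AIRR schema on read and everything downstream consumes one
dialect. Region boundary columns (`fwr1_start` … `fwr3_end`) are 0-based,
half-open, in alignment coordinates.

Two filters precede all analysis:

1. **Productivity** — only contigs flagged productive are retained.
2. **Read support** (`read_ratio`, default 0.1) — within each
   (cell, locus) group, a chain is dropped when its read count is below
   `read_ratio` × the group maximum. Chains with similar support are all
   kept deliberately: genuine multi-chain B cells exist and their chains
   should enter the analysis, whereas ambient/doublet contigs are
   typically supported by an order of magnitude fewer reads. The 10%
   default is a conservative choice for that separation and is exposed as
   a flag; missing read counts are treated as zero support, so an
   unsupported contig never survives next to a supported sibling.

## Clonotype model

Two heavy chains belong to one clonotype when they use the same V group,
the same J gene, and their CDR3 nucleotide sequences are sufficiently
similar. Concretely:

* V grouping is at the **family** level by default (`IGHV3-23*04` →
  `IGHV3`), because V *gene* assignment is the least reliable part of
  upstream annotation and near-identical genes of one family otherwise
  split real clones. Gene-level grouping is available for comparison, and
  `rand_index` quantifies the agreement of the two partitions (unadjusted
  Rand index: the fraction of chain pairs on which the partitions agree;
  the adjusted variant sits behind a flag).
* Similarity is Levenshtein identity
  `1 − d(a,b) / max(|a|,|b|)` with threshold 0.8. The max-length
  denominator means a sequence compared with its own prefix is penalized
  for the missing suffix; indels are allowed rather than length-stratifying
  the comparison, since the edit distance absorbs length differences
  naturally.
* Within a (V group, J gene) block, chains with identity ≥ threshold are
  linked and clones are the **connected components** (single linkage).
  Membership is therefore transitive, matching the usual clonotype notion
  in repertoire tools; the brute-force transitive-closure oracle in the
  test suite pins this semantics exactly.
* Clone ids are 1..K by decreasing size, ties broken by the
  lexicographically smallest member CDR3, so partitions are reproducible.

Lowering the identity threshold can only merge clones (never split), and
the gene-level partition always refines the family-level one; both
properties are tested.

## Class switching

Constant-gene usage is tallied per visit (fractions over chains with an
assigned `c_call`). A clonotype whose members use ≥ 2 distinct constant
genes is a class-switch (CSR) clonotype; the isotype co-occurrence matrix
counts, for every gene pair, the clonotypes containing both (a clone with
k isotypes contributes to all C(k,2) pairs — the per-pair convention is a
declared choice). The constant-gene order

`IGHM, IGHD, IGHG3, IGHG1, IGHA1, IGHG2, IGHG4, IGHE, IGHA2`

is the human IGH locus order, shipped as an editable constant. Because
naive B cells co-express IgM and IgD by alternative splicing rather than
recombination, a flag can collapse the IGHM/IGHD pair before counting; the
default counts distinct genes literally.

## Lineage trees

A clone's lineage is reconstructed from somatic hypermutation in the
V-region alignment:

* **Distance** is the substitution (Hamming) count over the gapped
  alignment, skipping positions where either sequence has a gap or N —
  SHM is modeled as substitutions in IMGT-gapped space.
* Identical member sequences collapse into one observed node (size =
  member count, visit composition tallied; a node's isotype is its
  members' majority `c_call`, ties resolved toward the earlier switch
  order).
* The tree is the **minimum spanning tree** over {germline} ∪ unique
  sequences, rooted at the germline and directed away from it. MST rather
  than maximum parsimony keeps the construction exact, deterministic and
  testable (for ≤ 6 unique sequences the tests enumerate every spanning
  tree via Prüfer sequences and confirm optimality). Kruskal ties are
  broken by (weight, germline distance of the downstream node,
  lexicographic sequence), so trees are reproducible.
* **Inferred intermediates**: when ≥ 2 children of a node share an
  identical mutation (same position, same derived base) relative to that
  node, a single unsampled ancestor explains it better than independent
  hits. An inferred node carrying exactly the shared mutations is inserted
  and the children re-attached beneath it. When different child subsets
  share different mutations, the group with the largest shared set is
  resolved first (ties toward the lexicographically smallest mutation
  set), then the parent is re-examined; total tree weight never increases.
* **Switch-order repair**: CSR only moves downstream on the locus, so an
  observed node whose isotype precedes an ancestor's implies an unsampled
  pre-switch intermediate. An inferred node with the descendant's sequence
  and its earlier isotype is inserted above the first offending ancestor,
  and the descendant re-attached beneath it with a zero-weight edge. This
  is iterated to a fixpoint, after which every root-to-leaf isotype
  sequence is non-decreasing; observed node sizes never change.

Trees serialize losslessly to GraphML, DOT and JSON.

## SHM profiling

A substitution is a position where observed and germline alignments both
carry an unambiguous base and differ; counts are tallied per region from
the FWR1/CDR1/FWR2/CDR2/FWR3 bounds (substitutions outside annotated
regions are reported separately). Replacement/silent classification
translates each substituted codon as a whole (one call per codon, so a
double-hit codon yields a single R or S), excluding codons containing gaps
or ambiguity. Heavy–light coupling across cells is summarized by the
Pearson correlation of per-cell mutation loads (Spearman behind a flag)
with the usual t-distribution p value; group comparisons use Welch's
two-sample t-test with the conventional star labels (* for p ∈
(0.01, 0.05], ** for (0.001, 0.01], *** for ≤ 0.001). No multiple-testing
correction is applied by default (a Benjamini–Hochberg option exists);
zero-variance-in-both-groups input returns a flagged NaN result rather
than raising.

## Longitudinal usage statistics

* **VJ usage** counts (V key, J gene) pairs per visit with within-visit
  frequencies; link classification against a baseline visit labels a pair
  *new* (absent at baseline), *expanded* (frequency ≥ `expansion_factor` ×
  baseline, default 2.0 — the factor is a flag since "expanded" has no
  canonical numeric rule), else *unchanged*. The three classes partition
  each visit's pairs.
* **CDR3 lengths** are measured on the amino-acid CDR3; when only the
  junction is present the conserved flanking Cys and Trp/Phe are trimmed
  (junction length − 2). Summaries can be per cell or per clonotype (one
  representative length per clone).
* **Light-chain ratio** is the per-visit κ:λ chain count ratio, reported
  reduced (e.g. 3:2) and as a decimal; a visit without λ chains is flagged
  infinite instead of raising.
* **Junction composition** aligns junctions from both ends toward the
  middle (IMGT-style anchoring), so the conserved Cys-104 and Trp/Phe-118
  line up across lengths; per-position residue frequencies sum to 1.

## Antigen-specific CDR3 search

Literature-derived CDR3/junction amino-acid sequences with known
specificity are matched against repertoire junctions. Because SHM makes
exact cross-individual matches unlikely, the search (i) restricts to
subjects whose length differs from the query by at most `length_flex`
residues (default 3) *before* any distance is computed, and (ii) accepts
Levenshtein identity ≥ `min_identity` (default 0.65 — the midpoint of the
60–70% relaxation customary in this setting). Identity is computed on the
full junction by default (a trim flag and a nucleotide mode exist). Hits
carry clone id, visit and isotype when available, and raising the
threshold can only shrink the hit set. No antibody database ships with
the package; query files are plain CSV (`query_id, antigen, junction_aa,
source`).

## Synthetic repertoires

The generator emulates a single-donor longitudinal vaccination time
course so every module is testable offline. Defaults are the study
conditions the toolkit targets:

| parameter | default | meaning |
|---|---|---|
| `n_clones` | 300 | independent clonal families |
| `clone_size_exponent` / `clone_size_max` | 2.5 / 129 | power-law clone sizes, capped |
| `cdr3_length_mean` / `sd` | 15.8 / 3.8 | amino-acid CDR3 length distribution |
| `shm_rate` | 0.02 /base | Poisson substitution rate over a 300-nt V region |
| `shared_cell_rate_shape` | 2.0 | gamma shape coupling a cell's heavy and light loads |
| `kappa_fraction` | 0.6 | the normal human 3:2 κ:λ ratio |
| `visits` | d0_B … d14 | ordered visit labels with sampling weights |
| `isotype_transition` | per-visit vectors | IgM/IgD-dominated at baseline B cells, IgG1/IgA1-dominated post-boost |

Each clone draws one germline V (synthetic random 300-nt sequences with
fixed codon-aligned region bounds, so no reference download is needed),
one ancestral CDR3, and a paired light chain. Members sample a visit and
an isotype i.i.d. from the per-visit vectors — so configured fractions are
recovered in expectation — and the clone's generative lineage order is
then arranged by switch rank, keeping class switches forward-only along
ancestry. Mutations are drawn per chain as Poisson(rate × length × g) with
the per-cell gamma factor g shared between heavy and light chain (mean 1;
set the shape to `None` for uncoupled, purely Poisson loads). A fraction
of cells receives a planted unproductive contig or a low-read secondary
heavy chain to exercise the filters, and query-tool fixtures are created
by planting junction variants whose identity to a query is confined to a
requested band (substitution-only, so the band maps exactly onto an edit
count). Ground truth (clone labels, per-region mutation maps, planted-hit
and decoy lists) is emitted alongside the table, and all randomness flows
through one seeded generator: a fixed seed reproduces the output
byte-for-byte.

What the generator does **not** emulate: SHM hot-spot motifs (WRC/GYW
targeting), junctional indels within a clone (members share their
ancestor's CDR3 exactly, so clonotype recovery on simulated data is
cleaner than on real data), allelic variation in germlines, sequencing
error, and cell-type-dependent BCR expression. Passing tests therefore
demonstrate algorithmic correctness against the stated model, not
robustness to every artifact of real single-cell data.

## Numerical and testing choices

* Levenshtein distances come from `edlib`; the test suite validates them
  against an independent full-matrix dynamic-programming oracle, and the
  clonotype partition against an all-pairs transitive-closure oracle
  (instances up to 200 chains).
* Statistical recovery tests compare empirical fractions with configured
  probabilities at a 3-standard-error bound. Where many proportions are
  checked simultaneously (per-visit isotype vectors, V-gene pools), the
  bound is Bonferroni-adjusted so the familywise false-alarm rate equals
  that of a single 3-SE check; scalar recoveries (mean mutation count,
  mean CDR3 length) use the plain 3-SE bound.
* Problem sizes in the test and acceptance runs (25–100 random clonotype
  instances, 500–2000 simulated chains, 30–50 lineage clones with ≤ 6
  unique sequences) are chosen so each exhaustive oracle stays exact;
  Prüfer enumeration grows as n^(n-2) and is the binding constraint on
  lineage oracle size.
* Degenerate inputs favor flagged results over exceptions where a
  downstream table is expected (infinite κ:λ ratio, zero-variance Welch
  test); hard contract violations (duplicate ids, inconsistent locus,
  alignment length mismatch, infeasible identity band) raise typed errors.

## Known limitations

* MST lineages are a parsimony surrogate: with high per-clone mutation
  loads the true genealogy can differ from the minimum-weight tree even
  though total weight is optimal.
* The shared-mutation rule for inferred intermediates resolves groups
  greedily; pathological clones with overlapping shared-mutation subsets
  may admit lighter inferred placements than the greedy order finds
  (weight still never increases).
* Clonotyping is heavy-chain only by design; light-chain-aware definitions
  and probabilistic assignment models are out of scope.
* Selection-pressure estimation is not implemented; the SHM module emits
  the per-region replacement/silent tables such analyses consume.
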