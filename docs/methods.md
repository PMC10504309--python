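# Methods

`dsrpipe` re-implements, as a reusable and fully testable pipeline, the
comparative-genomics procedure used to reconstruct the evolution of the
dissimilatory sulfite/sulfate reduction (Dsr) pathway: detect Dsr-protein
families in annotated genomes with decoy disambiguation, reduce redundancy
by identity clustering, build and root per-family phylogenies, extract
gene-neighborhood (synteny) clusters, and genotype each genome's pathway
repertoire.  At field scale this kind of analysis runs over hundreds of
thousands of assemblies and profile-HMM databases that cannot ship with a
package, so every stage is exercised against a bundled genome simulator
with known evolutionary ground truth.

## Family assignment

Each protein is locally aligned (Smith-Waterman, affine gaps, BLOSUM62,
open 10 / extend 0.5) against one or more reference sequences per family.
The reference set deliberately includes *decoy* families — homologous
complexes with similar domain architecture (NarGHI-like, HdrA-like) — and a
protein whose best hit is a decoy is rejected rather than assigned, which is
what keeps e.g. HdrA paralogs out of the QmoA family.  The best hit
(highest bitscore; ties to lower E-value, then family name) must reach 25%
local identity and an E-value of 1e-10 or better.

Because no database search engine is embedded, E-values are a
Karlin-Altschul surrogate `E = K·m·n·exp(-λS)` with (K = 0.041, λ = 0.267),
the published constants for gapped BLOSUM62 scoring, and m, n the sequence
lengths.  Ingested hit tables (HMM/BLAST-style TSV) carry their own
E-values, which take precedence.

Global alignments use classic Needleman-Wunsch-Gotoh with end gaps
penalised; percent identity counts identical columns over the full
alignment length, gap columns included in the denominator.  (EMBOSS
`needleall` leaves end gaps free by default; with the near-full-length
homologs these matrices are built from, the two conventions rarely differ,
and the end-gap-penalised form is the one the exhaustive test oracle
verifies exactly.)  Traceback tie-breaks are fixed (diagonal, then up, then
left) so runs are deterministic.

## Redundancy reduction

Within each family, an all-vs-all global identity matrix is thresholded
strictly above 90% and clustered with the Markov cluster algorithm
(inflation 2.0).  The MCL implementation is dense: column-stochastic matrix
with unit self-loops, alternating expansion (matrix squaring) and inflation
(elementwise power + column renormalisation), entries below 1e-5 pruned,
stopping when the largest elementwise change falls below 1e-6 or after 100
iterations (non-convergence warns and returns the current partition).
Clusters are the connected components of the converged nonzero pattern;
component labelling is deterministic (ordered by smallest member id).
Pruning and convergence settings are this package's choices; the strict 90%
threshold and inflation 2.0 are the established conventions for redundancy
reduction on protein identity graphs.  From each cluster the longest
sequence per genus is kept (ties to the smallest id);
optionally only representatives from complete assemblies are retained,
applied after representative selection.

## Alignment, trimming, tree inference

The self-contained multiple aligner is progressive: 3-mer count cosine
distances feed a UPGMA guide tree, profiles are merged up the tree with
affine-gap profile-profile alignment (sum-of-pairs column scores under
BLOSUM62; the inner DP is numba-compiled).  It replaces an external
iterative aligner for the package's purposes; since the simulator evolves
sequences without indels, simulated families align gap-free and every
column is homologous by construction, which is exactly what the downstream
recovery tests need.  Columns with fewer than 95% non-gap residues are then
removed (the gap-threshold convention of trimal), with the retained-column
provenance map returned.

Distances between rows are p-distances over shared non-gap columns,
corrected by inverting the uniform 20-state substitution model,
`d = -(19/20)·ln(1 - 20p/19)`, capped at d = 10 when p ≥ 0.95.  Trees come
from canonical neighbor joining with deterministic tie-breaks
(lexicographic label pairs) and negative branch lengths clamped to zero
with a warning.  Branch support is a Felsenstein column bootstrap (an
ultrafast bootstrap from an ML engine plays the same role but its values
are not numerically comparable); supports are the percentage of replicate
trees containing each bipartition of the point-estimate tree.  Maximum
likelihood inference is not re-implemented: `external_tree_adapter` runs
any engine via a `{in}`/`{out}` command template, validates the returned
leaf set, and feeds rooting identically.

## Rooting

MAD (minimal ancestor deviation) scans every branch: for each leaf pair the
relative deviation from a strict clock is `r_bc = |2·d(ρ,b)/d(b,c) - 1|`,
where the putative ancestor is the root position ρ for pairs spanning the
branch and the pair's fixed induced ancestor otherwise.  The branch score
is the RMS of r over all pairs, minimised over ρ in closed form (the
objective is quadratic; the minimiser is clamped to [0, 1]).  Zero-length
branches are replaced by ε = 1e-9 rather than collapsed so the candidate
set stays complete.  All candidates are returned sorted by deviation with
the ambiguity ratio (second-best/best ≥ 1) as the near-tie diagnostic.  On
an ultrametric tree the minimum deviation is exactly 0 at the true root,
which the tests exploit.

Outgroup rooting (the AsrC-style paralog design) places the root at the
midpoint of the branch separating a monophyletic outgroup; a scattered
outgroup is flagged and the root goes to the branch minimising misplaced
leaves, ties resolved by MAD among the tied branches.  `compare_roots`
reports whether the two strategies agree; when they conflict the pipeline
reports both rather than arbitrating.

## Synteny and genotyping

Gene positions are 0-based ranks along a contig; all distances are counted
in genes.  Family hits on one contig join a synteny cluster while at most
`max_gap = 4` non-hit genes separate consecutive hits ("maximum distance of
four genes" read as intervening genes; the index-offset reading is
selectable via `gap_rule="offset"`).  Clusters never span contigs,
singletons are allowed, intervening cargo genes are kept in the output, and
strand is recorded but ignored for clustering since real Dsr arrangements
span operons on both strands.

The presence/absence matrix counts assignments per genome and family.
Genotype calls use the DsrABCMK minimal set: *chimeric* (minimal set plus
both reductive-type and oxidative-type markers), *oxidative* (minimal set
plus DsrEFH or DsrL, without DsrD), *sulfate_capable* (minimal set plus
Sat, AprAB and QmoA or QmoB), *sulfite_minimal* (minimal set only),
*partial* (an incomplete minimal set), *none*.  The precedence order
chimeric > oxidative > sulfate_capable > sulfite_minimal is a design choice
of this package; the genotype classes themselves follow the biology (the
Qmo/Apr/Sat arm is what turns a sulfite reducer into a sulfate reducer).
A separate screen lists genomes with Apr/Qmo assignments and no Dsr
assignment at all.

## The synthetic-genome simulator

The simulator provides the ground truth every recovery test scores against.
Its parts:

* **Species tree** — a seeded forward birth-death process (defaults λ = 1,
  μ = 0) conditioned on the number of extant genomes, observed one waiting
  time after the target count is reached so the youngest split has nonzero
  subtending branches; full extinction retries with derived sub-seeds.  The
  tree is rescaled to a root-to-tip depth of 0.5 expected
  substitutions/site.
* **Minimum internal branch** — after rescaling, internal branches are
  raised to at least 0.04 while preserving ultrametricity (node heights are
  pushed apart, tip branches absorb the remainder).  Raw birth-death trees
  routinely contain internal branches carrying less than one expected
  substitution at 500 sites; no inference method can recover those edges,
  so leaving them in would make end-to-end topology tests measure tree-shape
  luck rather than pipeline correctness.  The floor (≈ 20 expected
  substitutions per internal branch at 500 sites) puts every divergence in
  the informative regime, emulating the deep, well-separated clades real
  Dsr proteins show.  Set `min_internal_branch=0` for unmodified
  birth-death trees (the Yule-expectation tests do).
* **Sequences** — evolved along the tree under a uniform 20-state model:
  per site, Poisson(rate × branch length × site rate) replacement events,
  each drawing one of the 19 alternatives uniformly; optional gamma site
  rates.  This model was chosen over an empirical matrix because it has a
  closed-form distance inverse, giving the tests an exact oracle; pipeline
  logic does not depend on substitution-model realism.
* **Genome classes** — leaves are assigned in tree order to five classes
  (defaults 25/40/20/10/5%): archaeal-style minimal sulfite reducers
  (DsrABCMKN in one block), bacterial reductive genomes (the consecutive
  DsrABDNCTMKJOP cluster, with dsrT adjacent to dsrM, plus QmoABC and
  AprAB-Sat blocks), oxidative genomes (DsrEFH/DsrL, no DsrD/T), chimeric
  genomes (both), and Apr/Qmo-only genomes without Dsr.  Planted blocks are
  inserted as contiguous units between cargo genes (random unrelated
  sequences), so block contiguity is part of the ground truth.
* **Decoys** — NarG-like and HdrA-like families evolve from independent
  random roots that share a 30-residue motif with DsrA and QmoA
  respectively, making decoy disambiguation non-trivial.
* **LGT** — xenologous replacement: the recipient's copy is re-evolved from
  the donor's terminal sequence over a short branch (0.02), and the true
  gene tree regrafts the recipient as the donor's sister.  An additive mode
  flag exists but replacement is the default, matching the
  DsrAB-in-Archaeoglobus scenario the pipeline must detect.
* **Incompleteness** — i.i.d. gene deletion at a configurable probability,
  emulating incomplete assemblies; deletions are ledgered and a genome that
  lost genes is marked incomplete.

Every draw flows from named substreams of one mandatory seed; exports are
byte-identical across runs.  Each genome gets a unique genus by default, so
redundancy reduction is exercised with dedicated fixtures rather than the
simulator.  What the simulator does **not** emulate: indel evolution (the
aligner's gap handling is exercised with constructed alignments, not
simulated homology), rate variation across lineages, genome rearrangement
within blocks, annotation errors, and empirical amino-acid exchangeabilities.
Passing recovery tests therefore demonstrate the pipeline's logic is
correct under its stated model, not field performance on real assemblies.

## Evaluation against ground truth

`simulate_and_run` scores: assignment accuracy over planted non-cargo genes
(and the decoy rejection rate); genotype concordance with the planted
classes; an adjusted-Rand comparison of MCL clusters against the partition
predicted by true-tree patristic distances (pairs closer than the distance
at which expected identity crosses 90% should co-cluster — approximate near
the boundary, so this is a diagnostic); Robinson-Foulds distances between
each inferred family tree and the true gene tree restricted to the retained
genomes; MAD root-branch recovery; and per-event LGT discordance, flagged
when the recipient's nearest leaf by patristic distance in a family tree is
the donor.  Genome-level tree comparisons are only defined for single-copy
representation, so genomes contributing more than one leaf to a family tree
(paralogs, or a borderline false positive that slipped past the hit
filters) are dropped from that family's tree scores; the pipeline outputs
themselves are untouched.

## Problem sizes and numerical choices

Simulation-based checks use 20 genomes at 500 residues per family gene
(10 replicates for end-to-end recovery), 12-leaf/500-site clock trees for
noisy rooting (100 replicates), 8-taxon matrices for NJ additivity (50),
and 3×8 planted-partition graphs for MCL (100).  Pipeline runs in these
checks disable the bootstrap (`n_bootstrap=0`); the default configuration
keeps 1000 replicates.  Tolerances: exact score equality for alignments
(integer-valued scoring), 1e-9 for NJ branch lengths on additive input,
1e-3 for the MAD ρ grid comparison at 1e-4 resolution, 1e-6 for "zero"
deviation on clock trees.  Ties are broken deterministically everywhere
(documented per operation); warnings never change results.

## Known limitations

* The NJ/distance stand-in is consistent under the simulator's model but is
  not a substitute for ML inference on real proteins; use the engine
  adapter for production trees.
* The E-value surrogate ignores composition and edge effects; it exists so
  the standard hit filters are exercisable offline, not to reproduce
  BLAST/DIAMOND E-values numerically.
* MCL here is dense (O(n³) per iteration); it is meant for per-family sets
  up to a few thousand sequences, not genome-database scale.
* Genotype precedence between co-satisfied classes is a convention; real
  chimeric systems may warrant manual review.
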