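# Methods

This note documents the models, conventions and numerical choices behind each
analysis stage, what the synthetic-data generator does and does not emulate,
and the known limitations.

## Gene catalog construction

Redundancy removal is greedy incremental clustering, the semantics of the
standard nucleotide clustering tools: sequences are processed longest-first
(ties broken by lexicographic gene id, for determinism), and each sequence
joins the **first** existing cluster representative it matches — no best-hit
search — else founds a new cluster. A match requires simultaneously
`identity ≥ id_thresh` and `coverage ≥ cov_thresh` (defaults 0.95 / 0.90).

Identity and coverage use the short-sequence convention: both are divided by
the length of the shorter sequence; coverage counts the shorter sequence's
positions inside the mutually aligned span (terminal overhangs of the longer
sequence do not count against it). The underlying global alignment is
Needleman–Wunsch (via Biopython's pairwise aligner) with fixed scores
match +1, mismatch −1, gap open −2, gap extend −1; the thresholds, not the
scores, are the scientific contract, and the scores are deliberately not
exposed as analysis parameters. Sequences are compared in the given
orientation only: inputs are assumed to be coding-strand gene predictions, so
no reverse-complement pass is made. `align_identity` canonicalizes argument
order before aligning so that tie-breaks among co-optimal alignments cannot
make the function asymmetric.

Merging two internally nonredundant sets scans each B representative against
A's representatives (first match wins, same thresholds). Matched B genes are
recorded as members of the matching A cluster; unmatched B genes enter as new
clusters. Because both inputs are nonredundant, no additional
B-against-B deduplication is needed. The overlap statistics (shared count,
shared fraction of each input) are what one inspects before deciding to merge.

Greedy clustering is quadratic in the worst case and intended for desk-scale
inputs (thousands of genes); it deliberately omits k-mer prefilters and other
throughput engineering.

## Abundance profiling

Gene relative abundance from unique-mapped read counts: divide each count by
gene length, then renormalize each sample to sum to one. An all-zero sample
yields an all-zero profile with a logged warning rather than an error, since
dropped samples should be a visible upstream decision.

KO profiles sum member-gene relative abundances per KO. A gene annotated to
k KOs contributes its **full** abundance to each of the k, so the KO table's
column totals may exceed one; this keeps per-KO presence meaningful for the
route analysis, which is what KO profiles feed here. Taxon profiles aggregate
at a named rank (domain → genus) and pool genes unclassified at that rank
under `unassigned`, so taxon profiles conserve mass and conservation is
testable.

The core-feature fraction uses strict presence (> 0) with no minimum-abundance
cutoff, and the denominator is the union of features observed in at least one
sample (not a fixed reference catalog) — with deep, complete catalogs the two
conventions coincide.

## Strain detection

Presence: strictly more than `presence_frac` (default 0.5) of the strain's
pangenome genes have a count ≥ 1 in the sample. "Mapped" is operationalized
as count ≥ 1; no minimum-read threshold is imposed. Abundance of a present
strain is the mean of count/length over its **detected** genes only; it is not
renormalized across strains, so values are comparable across samples only at
equal sequencing depth. Two limitations are inherent and are asserted as
expected behavior in the tests rather than patched: a truly absent strain
sharing more than `presence_frac` of its genes with present strains is called
present (read recruitment cannot separate shared gene content), and shared
core genes inflate the abundance of rare strains relative to their private
genes.

## Pathway logic

The route database is declarative JSON with enzyme gene symbols as primary
ids and an editable, logic-free KO alias column (the field names enzymes
*gdhA*, *NirA*, *nifH* more often than KO numbers).

* **Routes** are ordered steps, each an OR-set; a route is usable iff every
  step has a present member. Six nitrogen-assimilation routes are encoded:
  urea→ammonia (urease), nitrile→ammonia (nitrilase), glutamine/glutamate
  deamination (*gdhA*), direct ammonium import (*amt*), nitrite assimilation
  (entry by nitrite/nitrate transport **or** nitroalkane oxidation by
  nitronate monooxygenase, then reduction by *NirA*), and cyanate→ammonia
  (cyanate lyase). Folding the nitroalkane entry into the nitrite route as an
  OR-variant, rather than a seventh route, is the only reading consistent
  with a six-route repertoire in which nitrate reduction (*NarB*) is absent
  but nitrite can still be used.
* **Modules** (dissimilatory/assimilatory nitrate reduction, denitrification,
  nitrification, nitrogen fixation, anammox) are marker OR-sets; a module is
  detected iff any marker is present. This is a presence screen, not a
  completeness claim.
* **Amino-acid pathways** are AND-of-OR step lists. For the six amino acids
  with curated enzyme patterns the steps follow the biochemistry: Met needs
  *metC* and *metH*; Ser needs *serC* and *serB*; Tyr needs *tyrC* then
  *tyrB*; Phe needs *pheA2* then *tyrB*; Ala has one OR-step {*asdA*, *ALT*}
  (two alternative routes). Gly has two alternative routes — from threonine
  via *ltaE*, or from de novo serine via *glyA* — expressed in conjunctive
  normal form as (ltaE|serC) ∧ (ltaE|serB) ∧ (ltaE|glyA), which keeps the
  flat step-list contract while making glycine depend on the serine
  precursors. The remaining 14 amino acids are encoded as single-step
  presence checks over one representative terminal enzyme each; users with
  richer annotations can replace these definitions in the JSON.
* **Uptake compensation**: an incomplete pathway is downgraded to
  `incomplete_with_uptake` when a transporter for the amino acid itself is
  present, or when a present bidirectional conversion enzyme links it to an
  importable partner (one edge, no multi-hop chaining). The `uptake` field
  records which mechanism applied, so direct-import counts and
  conversion-rescue counts stay distinguishable.
* **Marker-KO pathway abundance** is the mean over the full marker set,
  counting absent markers as zero — "total abundance divided by the number of
  KOs" is read as all markers, not detected ones — making the statistic
  comparable across samples with different detected subsets.

All of the pathway logic is monotone by construction: adding enzymes can never
remove a route, a module, or a complete amino acid (property-tested).

The database also carries the observed enzyme sets of an oligotrophic
surface-water study system (a *Prochlorococcus* population's nitrogen
repertoire, the community nitrogen repertoire, and the six-amino-acid gap
pattern with its transporters) as curated data, so the worked examples are
reproducible from the package alone.

## Phylogenetics

Marker selection drops family members with length ≤ `min_len` (default
800 bp, strict) and returns the family with the most survivors (ties to the
lexicographically smallest id). Distances are p-distances over columns where
neither sequence has a gap; a pair with no comparable column is an error, not
a zero. Sequences must be pre-aligned or equal-length; `align_to_anchor`
provides a logged pairwise-projection fallback (insertions relative to the
anchor are dropped), which is a convenience, not a substitute for a proper
multiple alignment.

Neighbor joining is implemented in-package (Saitou–Nei agglomeration with the
standard Q-criterion; ties resolved to the smallest index pair; final
three-taxon star solved in closed form). Negative branch-length estimates are
clamped to zero and the total deficit logged. On additive matrices the
reconstruction is exact (tested to 1e−9 on random 8-leaf trees) and the
topology matches scikit-bio's implementation, which serves as an independent
oracle in the tests, never as the implementation. Distance-based trees were
chosen over likelihood methods deliberately: the preserved contract is clade
membership (ecotype assignment), not likelihood scores, and nucleotide space
is used for the marker gene.

Ecotype assignment gives each query the label of its nearest labeled
reference leaf by patristic distance (ties to the lexicographically smallest
reference id). Simulations show exact recovery when between-clade divergence
is ≥ 3× within-clade divergence; closer clades degrade gracefully but are not
guaranteed.

ANI is the mean identity of reciprocal best-hit gene pairs above an identity
floor (default 0.3, configurable), × 100. The floor exists to keep spurious
alignments between unrelated genes out of the mean; if no pair passes, the
function raises with a diagnostic rather than reporting a meaningless number.

## Statistics

Spearman's rho is computed on mid-ranks (average ranks for ties). The
p-value is a two-sided permutation test of one vector: exhaustive enumeration
when `n! ≤ n_perm` (exact, e.g. n ≤ 7 at the default 10,000), otherwise
`n_perm` seeded random permutations with the add-one estimator
`(1 + hits) / (1 + n_perm)`. Permutation rather than the large-sample
approximation because oceanographic transects have small station counts.
A tolerance of 1e−12 guards the `|rho_perm| ≥ |rho_obs|` comparison against
floating-point ties.

The group comparison is Welch's unequal-variance t-test (two-sided,
Welch–Satterthwaite degrees of freedom, delegated to scipy), chosen over the
pooled-variance test because oceanic station groups have unequal variances by
construction. Two identical constant groups return t = 0, p = 1 rather than
an error. Calibration: empirical type-I error at α = 0.05 over 10,000 null
replicates with 3:1 variance ratio stays within Monte-Carlo error of nominal
(tested).

## Synthetic data: what it does and does not emulate

The generator reproduces the statistical structure the downstream math
assumes — and only that:

* **Pangenomes**: all strains share the core genes; accessory genes are
  private to one strain. Gene lengths are uniform on a configurable range
  with a hard 150 bp minimum (the minimum predicted-gene length the catalog
  accepts); sequences are uniform-random ACGT.
* **Counts**: per sample, a single multinomial draw with gene probability
  ∝ gene length × summed abundance of carrier strains, i.e. uniform read
  starts over shared genes. The depth distribution of unique-mapping reads
  across shared versus private genes in real data is unknown; the
  length-proportional model is an explicit assumption of this package, not a
  property imported from any dataset. Column sums are exactly the requested
  depth.
* **Mutants**: substitution-only (no indels), each hit position moved to a
  uniformly chosen different base, so expected identity is exactly
  1 − divergence and binomial error bars are analytic. Indel robustness of
  the clustering is a separate concern exercised through the
  coverage threshold, not through the mutator.
* **Environment**: temperature is a strictly increasing affine transform of
  the linked taxon's abundance (rank correlation exactly +1 for distinct
  inputs); the other covariates are independent uniforms on plausible
  oligotrophic surface ranges (salinity 33–37.5 PSU, pH 7.8–8.3, nutrients at
  sub-μM to few-μM levels, chlorophyll-a ≤ 0.5 μg/L).

Consequently, passing tests demonstrate internal correctness of the math
(normalization, aggregation, thresholds, tree reconstruction, calibration),
not robustness to real-data pathologies: no sequencing error, chimeras,
mapping ambiguity, compositional coupling between taxa, GC or length biases,
or overdispersion beyond multinomial sampling.

All generators take an integer seed and reproduce byte-identical output for
the same seed.

## Problem sizes and determinism of the shipped checks

The test suite and acceptance script regenerate every input at run time from
seeds; no data files ship beyond the route database. The quantitative checks
use: 100-gene communities at 10⁶ reads (gene-profile recovery, L1 < 0.01),
2 × 30-gene strain pairs at 2 × 10⁵ reads (abundance ratio within 3 SD of
3:1), ≤ 26-sequence families for clustering-oracle equivalence, 8–10-leaf
trees for NJ checks, 800 bp markers for ecotype recovery, 10⁴ replicates for
t-test calibration, and exhaustive n = 5 permutation enumeration for the
Spearman p-value. The pathway-logic results are fully deterministic: they
depend only on the shipped route database and set algebra.

## Known limitations

* Greedy first-match clustering is order-dependent by specification; the
  order (longest first, lexicographic ties) is fixed and documented, but a
  different order convention would yield different (equally defensible)
  representatives.
* `enumerate_routes`/`module_presence` are annotation-presence screens; they
  say nothing about expression, flux, or gene completeness.
* The single-enzyme encodings of the 14 uncurated amino-acid pathways make
  their "complete" calls only as strong as the chosen representative enzyme.
* ANI by reciprocal best hit over genes approximates whole-genome ANI; it is
  not a fragment-based estimator and will differ on rearranged or
  partially assembled genomes.
* Strain abundances are not depth-normalized across samples, by design; users
  comparing across samples must normalize depth upstream.
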