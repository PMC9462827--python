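# Methods

## Problem and model

Clonally related BCR heavy-chain sequences descend from one V(D)J
rearrangement and differ only through somatic hypermutation.  They therefore
share their germline IGHV and IGHJ genes and (absent junction indels) their
CDR3 length, and their CDR3 amino-acid sequences stay similar.  `bcrclust`
turns these facts into a three-stage partitioning of an annotated repertoire.

### Pre-clustering

Sequences are keyed by (IGHV gene, IGHJ gene, CDR3 length); gene calls are
compared after stripping the `*NN` allele suffix by default, because allele
miscalls are common in practice (`allele_level=True` restores allele-exact
grouping).  Inside a key group, pairs with CDR3 amino-acid identity ≥ *s*
(Hamming identity on the equal-length strings; default *s* = 0.70) are
linked and the connected components become the initial clusters.  Components
("single linkage") are the weakest splitting consistent with separating
pairs below the threshold; since the later stages can only merge, a stronger
splitting here would be unrecoverable.  The comparison is inclusive at *s*:
identity exactly at threshold links, strictly below separates.

An optional CDR3-length tolerance (default 0) pools key groups whose lengths
chain within the tolerance and switches identity to 1 − normalized
Levenshtein, accommodating the rare SHM indel inside the junction.

### Composed distance

All refinement decisions use a per-pair distance

    d(i, j) = (α·dV + β·dCDR3 + λ·dJ) / (α + β + λ),

a weighted mean of segment distances, so short CDR3s are not swamped by the
much longer V region and each segment can use the metric that suits it:

- `binary` — 0 if the two labels/strings are equal, else 1;
- `levenshtein` — edit distance divided by the longer length (in [0, 1]);
- `kmer` — 1 − |shared distinct k-mers| / max(|k-mer set a|, |k-mer set b|).
  The containment denominator (rather than Jaccard) makes identity give
  exactly 0 and k-mer-disjointness exactly 1.  Default k = 3, a standard
  choice for short peptides;
- `giana` — Euclidean distance between fixed-length numeric encodings of the
  amino-acid strings: each residue maps to a rank-6 spectral factor of
  BLOSUM62, the shorter string is center-padded with zero vectors, and the
  result is divided by the largest achievable embedding distance at that
  length so it stays in [0, 1].  This is a deliberately simple encoding
  distance; it is not part of the default configuration.

Defaults: binary for V, Levenshtein for CDR3 and J, α = β = λ = 1 (the
arithmetic mean).  V/J distances operate on the gene-call labels, the only
germline information an annotated table carries.  Distances are computed
once per unique (segment-value) pair and cached in a full matrix, so exact
duplicates cost nothing and repeated queries are bit-identical.

### Refinement (cohesion vs. separation)

For each sequence *i* in a multi-member cluster *k*:

    a_i = mean distance from i to the other members of k       (cohesion)
    b_i = min over clusters l≠k of mean distance from i to l   (separation)

`b_i` is the smallest *average* — the silhouette-consistent definition — not
a minimum over single distances; ties on the average break toward the
smallest cluster label.  If a_i > b_i, cluster *k* is merged with the
cluster attaining b_i and the scan restarts.  Clusters and members are
visited in deterministic sorted order and the first violation triggers the
merge, so the result is independent of hash ordering.  Iteration stops when
a full pass performs no merge, or after `max_iter` (default 1000) passes,
in which case the best-so-far partition is returned with a warning.  At
convergence, no sequence of any multi-member cluster violates a_i ≤ b_i
(asserted in the test suite).

### Singleton merging

Refinement can never move a singleton (its a_i is 0), so a second pass
considers each singleton *k* in ascending label order, finds the cluster *l*
with the smallest mean distance to *k*'s sequence, and merges them iff

    |unif(l ∪ k) − unif(l)| < δ,       default δ = 0.05

with cluster uniformity defined from nearest-neighbour ("local density")
distances:

    local_den(i) = min_{j≠i in k} d(i, j)
    avg_den(k)   = mean_i local_den(i)
    unif(k)      = Σ_i |local_den(i) − avg_den(k)| / avg_den(k),  n > 1
    unif(k)      = 0,                                             n = 1

Two conventions are worth stating.  First, the uniformity sum uses
*absolute* deviations: the signed sum is identically zero for every cluster
(deviations from a mean cancel), which cannot measure variability; a
`literal_uniformity` flag restores the signed form for auditing, and a test
demonstrates its degeneracy.  Second, a cluster of exact duplicates has
avg_den = 0; its uniformity is defined as 0 (perfectly uniform) rather than
dividing by zero.  Merged clusters are visible to later singletons, which
maximizes absorption.  With δ = 0 the strict inequality never fires and no
singleton merges.  Singleton merging runs once, after refinement has
converged.

## Benchmark simulator

The simulator emulates the generative process the clustering method assumes:
independent lineages, each a naive recombined ancestor diversified by SHM.

- **Germline pool.**  The bundled pool is *synthetic*: 20 V, 8 D and 6 J
  segments of random stop-free codons generated deterministically in code.
  V segments end with the conserved cysteine codon 9 nt before their 3' end;
  J segments are a 9-nt head, the TGG tryptophan codon, and an in-frame
  18-nt tail.  The CDR3 anchors are therefore known by construction and the
  junction reading frame is guaranteed whenever the total length is a
  multiple of three.  User V/D/J FASTA files following the same anchor
  conventions can replace the pool.
- **Recombination.**  Uniform picks of V, D, J; 0–5 nt exonuclease trimming
  per junction side; 0–10 random N nucleotides per junction (uniform
  lengths — the real insertion-length distributions are not modelled);
  draws are rejected until the ancestor is in frame and stop-free.
- **Lineage growth.**  A Galton–Watson tree: each node draws
  Poisson(λ) offspring (default λ = 2), capped at `tree_cap` = 500 nodes
  per lineage; extinct trees are redrawn within a retry budget.  Each
  offspring acquires m ~ Poisson(μ₀λ₀) substitutions (default λ₀ = 0.26;
  the benchmark grid uses {0.16, 0.26, 0.36, 0.46}), at positions drawn
  proportionally to per-site mutability, each to a uniform alternative
  base.  μ₀ is the mean site mutability of the parent sequence, so more
  mutable sequences accumulate more mutations.
- **Mutability.**  The default model raises the centre position of WRC and
  GYW hotspot motifs (W = A/T, R = A/G, Y = C/T) to weight 5.0 over a
  baseline of 1.0; truncated edge contexts stay at baseline.  A 5-mer
  context table in CSV form (5-mer, rate) can be loaded instead.
- **Assembly.**  Only productive nodes (no stop codon in the V frame) are
  candidates.  Lineages are subsampled without replacement to clonality
  profiles: monoclonal — one lineage at ~72 % of the target (≥ 70 % after
  realization); oligoclonal — two dominant lineages at ~14 % and ~9 %;
  polyclonal — even sizes, each ≤ 5 %.  Default lineage counts are 34 / 43 /
  44 and the default target is 1000 sequences.  A dominant lineage whose
  capped tree yields fewer productive nodes than its target keeps them all
  and the minor lineages scale down to preserve dominance, so realized
  monoclonal repertoires are smaller (~650) than nominal — the expected
  behaviour of productive-only filtering under a tree cap.

What the simulator does **not** model: selection/affinity (plain branching,
no fitness), junction indels during SHM, sequencing error, isotypes, light
chains, allele-level annotation noise, and the empirical 5-mer substitution
spectrum (the hotspot approximation biases *where* mutations land, not their
full context-specific rates).  Perfect recovery on these benchmarks
therefore shows that the pipeline resolves lineage structure created by
junctional diversity plus hotspot-biased point mutation; it does not bound
performance on repertoires dominated by annotation errors or indels.

## Evaluation

- **Pairwise**: TP/FP/FN over unordered sequence pairs, computed from the
  truth-by-inferred contingency table (equivalent to pair enumeration, which
  the tests check explicitly).  Precision = TP/(TP+FP), recall = TP/(TP+FN),
  F-score their harmonic mean; empty denominators yield 0 by convention and
  are logged.
- **Closeness**: clusters are first matched one-to-one by shared membership
  (greedy descending overlap; ties prefer the larger truth cluster, then
  lexicographic labels; a Hungarian exact option exists for small
  instances); TP/FP/FN are the unions of per-pair intersections and
  differences over matched pairs only.
- **Events**: every cluster of distribution d₂ gets exactly one label
  relative to d₁, with precedence not-found → identical → join → split →
  mix, which makes the five labels a total, mutually exclusive
  classification; reports include raw counts and both normalizations (by d₂
  and by d₁ cluster counts), since either denominator can be of interest.
- **Clonality**: mean-absolute-difference Gini coefficient and the Lorenz
  curve of cluster sizes, related by Gini = 1 − 2·AUC (exact for the
  piecewise-linear curve; asserted to 1e−9).

## Parameter sweep

`bcrclust grid` enumerates pre-clustering thresholds × per-segment metric
choices × coefficient schemes × singleton on/off.  The canonical axes
(5 thresholds 50–90 %, 4 metrics per segment, 7 coefficient schemes, 2
singleton settings) give 5·4³·7·2 = 4480 configurations.  The seven default
schemes are the arithmetic mean plus the six ways of double-weighting one or
two segments ((2,1,1), (1,2,1), (1,1,2), (2,2,1), (2,1,2), (1,2,2)) — a
package choice, as only the scheme *count* is canonical; arbitrary
(α, β, λ) triples are accepted.  `--max-runs` and `--plan-only` support
desk-scale subsets.

## Problem sizes and determinism

Benchmarks in the test suite and the acceptance script use ~1000-sequence
repertoires with 34–44 lineages — large enough that lineage collisions (two
lineages sharing V, J, CDR3 length *and* ≥ 70 % identity) are rare but the
full pipeline, including the distance matrix and all refinement passes, runs
in seconds.  All randomness flows through a single seeded generator per run;
identical seed and configuration reproduce byte-identical repertoires and
clusterings, and cluster labels are derived from sequence ids, never from
iteration order.

## Known limitations

- V and J distances are label distances; two annotations differing only by a
  miscalled gene land in different pre-clusters, as in any annotation-first
  method.
- The refinement merge loop recomputes cluster means each pass; worst-case
  cost is O(passes · n²) on the cached matrix.  Repertoires with one huge
  cluster dominate the n² term.
- The uniformity statistic is scale-dependent on the local-density
  distribution; δ was taken at its published default (0.05) and is exposed,
  not re-tuned.
- Greedy closeness matching can in principle differ from the exact
  assignment on adversarial overlap structures; the exact option is provided
  and the two agree on all tested realistic split/merge perturbations.
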