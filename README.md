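# bcrclust

Clonal lineage inference for B-cell receptor (BCR) repertoires.

After V(D)J recombination and antigen-driven somatic hypermutation (SHM), a
B-cell clonal lineage is the set of sequences descending from one
rearrangement event: one unmutated ancestor plus all of its mutated variants.
Grouping the IGH sequences of a high-throughput repertoire into such lineages
is the starting point of most repertoire analyses — diversity estimation,
clonal tracking, and the detection of clonal expansions in leukemia,
lymphoma, infection, and vaccination studies.  `bcrclust` performs this
grouping from annotated AIRR rearrangement tables, and ships a
branching-process benchmark simulator and partition-comparison metrics so
that inference quality can be measured against known truth.

## Method

Input sequences must carry IGHV and IGHJ gene calls and a CDR3 (or junction)
amino-acid string.  Clustering proceeds in three stages:

1. **Pre-clustering.**  Sequences with the same IGHV gene, IGHJ gene and CDR3
   length are grouped; within each group, single-linkage connected components
   at CDR3 amino-acid identity ≥ *s* (default 70 %) form the initial
   clusters.

2. **Refinement.**  Distances between sequences are a weighted mean of
   per-segment distances,

       d(i, j) = (α·dV + β·dCDR3 + λ·dJ) / (α + β + λ),

   with binary, normalized-Levenshtein, k-mer, or substitution-matrix
   embedding metrics per segment (default: binary V, Levenshtein CDR3 and J,
   α = β = λ).  For every sequence *i* of every multi-member cluster the
   silhouette terms are computed: aᵢ, the mean distance to its own cluster,
   and bᵢ, the smallest mean distance to any other cluster.  aᵢ > bᵢ flags an
   inconsistency; the two clusters involved are merged and the scan restarts,
   until cohesion and separation admit no further improvement.

3. **Singleton merging.**  A singleton cluster joins its nearest cluster *l*
   when |unif(l ∪ k) − unif(l)| < δ (default 0.05), where unif is the
   dispersion of nearest-neighbour distances within the cluster — so
   singletons are absorbed only where they fit the local density.

Optimising cohesion and separation simultaneously means no global distance
threshold has to be tuned: over-split initial clusters are repaired by the
refinement stage.

## Worked example

```python
from bcrclust import ClonalLineageClusterer, SimConfig, assemble_repertoire
from bcrclust.evaluate import closeness_metrics, gini, pairwise_metrics

sim = assemble_repertoire(SimConfig(repertoire_type="oligoclonal", seed=42))
print(f"{len(sim.repertoire)} sequences in {sim.truth.n_clusters} true lineages")

model = ClonalLineageClusterer(s=0.70).fit(sim.repertoire)
print(f"inferred {model.n_clusters_} clonal lineages")

pw = pairwise_metrics(sim.truth, model.clustering_)
cl = closeness_metrics(sim.truth, model.clustering_)
print(f"pairwise  F-score: {pw.fscore:.3f}")
print(f"closeness F-score: {cl.fscore:.3f}")
print(f"Gini of cluster sizes: {gini(list(model.clustering_.sizes().values())):.3f}")
```

prints

```
1000 sequences in 43 true lineages
inferred 43 clonal lineages
pairwise  F-score: 1.000
closeness F-score: 1.000
Gini of cluster sizes: 0.191
```

The simulated oligoclonal repertoire has two expanded lineages (~14 % and
~9 % of sequences) over a diverse background; the estimator recovers the true
partition exactly, in both the pair-counting and the structure-sensitive
(closeness) scoring mode.  The Gini coefficient of 0.19 reflects the mild
clonal inequality of an oligoclonal repertoire (0 = perfectly even,
→ 1 = one dominant clone).

The same pipeline is available from the shell:

```sh
bcrclust simulate -o bench --repertoire-type polyclonal --seed 1
bcrclust run bench/repertoire.tsv -o out
bcrclust evaluate bench/truth.tsv out/clustered.tsv
```

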