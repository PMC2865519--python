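# phylodiff

Differentiation-based phylogenies of cancer subtypes from gene-expression data.

Histopathological tumor classification relies in part on the degree of
differentiation of the sample, but there is no objective, systematic way to
order tumor subtypes by maturation.  `phylodiff` ranks tumor subtypes by the
dissimilarity of their gene expression from stem cells and from fully
differentiated tissue, by building a bootstrapped, rooted, distance-based
phylogeny of the subtypes.  It is aimed at computational biologists working
with normalized (log2 / RMA-scale) expression matrices of pathologically
classified tumor cohorts, plus reference profiles of a stem-cell outgroup and
a mature-tissue endpoint.

## Method

Given a genes × samples matrix and a sample→group annotation:

1. **Filter** — genes differentially expressed in at least one tumor subtype
   are selected with a one-way ANOVA (alternatives: Welch's heteroscedastic
   one-way test, Kruskal–Wallis), corrected with Benjamini–Hochberg
   (default FDR < 0.01) or Holm.
2. **Distances** — per-subtype mean profiles over the selected genes give a
   distance matrix δ, with the Pearson correlation distance *d* = 1 − *r*
   (default) or the Euclidean distance.
3. **Tree** — a phylogeny is reconstructed from δ.  The default criterion is
   weighted least squares (Fitch–Margoliash):

       E = Σ_{i<j} (δ_ij − d^T_ij)² / δ_ij²

   where d^T are path lengths on the candidate tree; branch lengths are fit
   by non-negative least squares, and topologies are searched exhaustively
   (≤ 8 leaves) or by stepwise addition + NNI.  Minimum evolution (smallest
   total branch length), neighbor-joining and UPGMA are also available.
   Fit quality is reported as E and the average percent standard deviation
   (apsd), 100·√(mean of squared relative deviations).
4. **Bootstrap** — the construction is repeated (default 10,000×) with gene
   subsets of random size *n* ~ DiscreteUniform{1..N} drawn with replacement
   from the N selected genes, and with each group's samples resampled with
   replacement; an extended majority-rule consensus summarizes the replicate
   trees with per-branch support percentages.
5. **Rank** — the consensus is rooted at the stem-cell outgroup; subtypes are
   ranked by where they attach along the path from the root to the
   differentiated reference leaf (the differentiation path).
6. **Profile clusters** — standardized mean profiles over the ranked order
   are clustered with fuzzy c-means (default c = 20, fuzzifier m = 1.25);
   genes in clusters whose centroid rises or falls monotonically along the
   ranking are reported, ordered by the fold change 2^Δ between the outgroup
   and the reference.

Greedy ordering by distance-to-outgroup and minimum spanning trees are
included as baselines, and a parameter sweep enumerates all combinations of
test × correction × cutoff × tree method × metric, keyed by consensus
topology.

## Worked example

Real cohorts are not bundled; the built-in generator plants a known
differentiation trajectory (root at t = 0, K subtypes at interior positions,
reference at t = 1) so the whole pipeline can be exercised end to end:

```python
from phylodiff import (
    SimulationSpec, simulate_dataset, PipelineConfig, run_pipeline,
    compute_group_means, standardize_profiles, fuzzy_cmeans,
    monotone_clusters, fold_change_ranking,
)

spec = SimulationSpec(n_genes=2000, n_subtypes=5, samples_per_group=10,
                      noise_sd=0.5, seed=7)
x, ann, truth = simulate_dataset(spec)

result = run_pipeline(x, ann, PipelineConfig(replicates=200, seed=7))
print("selected genes:", result.n_selected)
print("ranking:       ", result.ranking)
print("tree fit:       E = %.3f, apsd = %.2f%%" % (result.fit.objective, result.fit.apsd))
print("consensus:     ", result.rooted.to_newick(lengths=False, supports=True))
```

prints

```
selected genes: 804
ranking:        S1 < S2 < S3 < S4 < S5
tree fit:       E = 0.229, apsd = 10.45%
consensus:      (ROOT,(S1,(S2,(S3,(S4,(S5,REF)98.5)99)99)99));
```

804 of 2000 genes pass the ANOVA/BH filter; the consensus tree attaches the
subtypes to the ROOT→REF path exactly in the planted order S1…S5, every
branch on that path has ≥ 98.5% bootstrap support, and the tree reproduces
the observed distances to within a 10.45% average relative deviation.
Continuing to the differentiation-associated genes:

```python
means = compute_group_means(x, ann, result.selected_genes)
order = ["ROOT"] + result.ranking.flat() + ["REF"]
model = fuzzy_cmeans(standardize_profiles(means, order), c=20, seed=7)
table = fold_change_ranking(monotone_clusters(model), means, "ROOT", "REF")
print(table.head(3)[["gene_id", "direction", "fold_change", "log2_ratio"]])
```

```
gene_id  direction  fold_change  log2_ratio
 G00378 increasing    21.099701    4.399151
 G00385 increasing    20.481224    4.356230
 G00051 increasing    20.093789    4.328678
```

i.e. the genes whose expression rises most steeply from the stem-cell
outgroup to the mature reference (a 21-fold change is 4.40 on the log2
scale).  Negative folds use the signed convention −2^(−Δ), so a halving
displays as −2.

The same steps are available from the shell via the `phylodiff` console
script (`simulate`, `filter`, `dist`, `tree`, `bootstrap`, `rank`,
`profiles`, `baseline`, `pipeline`, `sweep`); see `phylodiff --help`.
Expression input is a TSV with gene rows and a sample-id header row; the
annotation is a headerless TSV of `sample<TAB>group[<TAB>role]` with roles
`subtype` (default), `root_outgroup`, `differentiated_reference`,
`auxiliary`.  Input must already be normalized on the log2 scale; missing
values are rejected, not imputed.

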