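# Methods

This note documents the models, conventions and numerical choices behind
`phylodiff`, in the order the pipeline applies them.

## Data model and assumptions

The unit of analysis is a group of samples: tumor subtypes, a single
stem-cell *root outgroup*, a single fully differentiated *reference*, and
optional auxiliary groups (e.g. progenitor populations of known maturity)
that ride along as tree leaves.  Expression values are assumed to be
normalized, summarized log2 intensities (RMA scale).  The package performs
no normalization and rejects missing values rather than imputing them —
imputation would silently change every downstream distance.  Row
identifiers are opaque features: probe sets and collapsed genes are treated
identically, and probe-to-gene mapping is the user's concern.

## Differential-expression filter

Testing runs across subtype groups only; outgroup/reference/auxiliary
samples never enter the statistic, because they are added to the analysis
for rooting and ranking, not for defining subtype differences.  The one-way
ANOVA and Welch's heteroscedastic one-way test are computed vectorized over
genes; Kruskal–Wallis uses the tie-corrected H with the chi-square
approximation (expression values carry ties after rounding).  Corrections
are Benjamini–Hochberg step-up (FDR) and Holm step-down (FWER), both via
statsmodels; selection is strict (`adjusted p < alpha`, default 0.01).

Constant genes (within- and between-group variance both zero, detected with
a rounding-floor tolerance of ~1e-12 relative to the grand mean) are
flagged degenerate, assigned p = 1 and never selected: their F statistic is
0/0 and exclusion is conservative.  Genes with zero within-group but
positive between-group variance get p = 0 (infinite F).

## Distances

Both metrics operate on per-group mean profiles restricted to the selected
genes, matching the pipeline order (filter before distances).  The Pearson
correlation distance d = 1 − r (range [0, 2]) is the default because the
in-vitro outgroups are far from every tumor group in absolute intensity; a
constant profile makes r undefined and is reported as an error naming the
group.  Euclidean distance is the alternative for the parameter sweep.

## Tree reconstruction

Four distance-based methods are implemented:

* **WLS (Fitch–Margoliash)** — minimizes E = Σ_{i<j} (δ_ij − d^T_ij)²/δ_ij².
  The 1/δ² weights down-weight deviations between distant groups, which
  matters with very distant stem-cell outgroups.  Branch lengths solve the
  weighted path-incidence system; the unconstrained solution is used when it
  is already non-negative, otherwise NNLS enforces lengths ≥ 0.
* **ME (minimum evolution)** — same branch-length machinery, but the
  topology with the smallest *sum* of branch lengths wins.  The sum is taken
  over the unconstrained (possibly negative) least-squares estimates, the
  classical convention: summing clamped lengths lets wrong topologies shed
  length artificially and is demonstrably inconsistent even on additive
  inputs, whereas the unconstrained sum recovers generating topologies.
  Returned trees always carry the non-negative constrained fit.
* **NJ** — Saitou–Nei agglomeration with the Q criterion; negative pendant
  estimates are clamped to 0.
* **UPGMA** — size-weighted average-linkage agglomeration; heights are half
  the merge distance, so ultrametric inputs are reproduced exactly.  Note
  its molecular-clock assumption is generally wrong for tumor subtypes; it
  is included for the methods comparison.

Topology search is exhaustive for ≤ 8 leaves — all (2n−5)!! unrooted
topologies are enumerated once per leaf count, their path-incidence
matrices cached, and scored with batched normal-equation solves plus a
branch-and-bound over the unconstrained objective (the unconstrained E
lower-bounds the constrained E, so most NNLS solves are skipped).  Beyond 8
leaves, stepwise addition in label order followed by
nearest-neighbor-interchange hill climbing runs to a local optimum.  All
ties (Q criterion, merge choice, equal scores) break deterministically: by
first index pair for agglomerative methods, by canonical Newick string for
searches.  The canonical form roots an unrooted tree above its
lexicographically smallest leaf and sorts children recursively, which makes
topology keys invariant to rotation and child order.

Fit quality is reported as E and as the average percent standard deviation,

    apsd = 100 · sqrt( (1/m) Σ_{i<j} ((d^T_ij − δ_ij)/δ_ij)² ),

with m = number of unordered pairs.  Zero observed distances between
distinct groups make the 1/δ² weight (and apsd) undefined: strict mode
raises; lenient mode (the default in pipelines, where tiny bootstrap gene
draws can produce exact ties) substitutes the smallest positive δ.

Numerical details: the batched normal equations carry a relative ridge
(1e-10 of the mean diagonal) because correlation distances near zero give
weights spanning many orders of magnitude; a singular system falls back to
least-squares.  Score ties use a relative tolerance of 1e-12.

## Bootstrap and consensus

Each replicate draws a gene subset of size n ~ DiscreteUniform{1..N} with
replacement from the N selected genes (the uniform law over {1..N} is the
"subsets of varying size" convention) and, independently, resamples every
group's n_i samples with replacement — including the non-subtype groups, so
classification and profile uncertainty both propagate.  Replicate r under
seed s uses the RNG stream seeded (s, r, attempt), making runs reproducible
and replicates independent of execution order.  Replicates whose distance
matrix is undefined (e.g. a single-gene draw under the correlation metric)
are redrawn; more than max(10, 10% of R) redraws abort with a diagnostic —
the fractional threshold is the meaningful guard at scale, the small floor
keeps low-R runs from aborting on the occasional single-gene draw.

The consensus is extended majority rule: splits in > 50% of replicates are
kept, the remainder are added greedily in descending frequency when
compatible with everything accepted, with ties (including exact 50/50
conflicts) broken by canonical split order.  Supports are exact empirical
percentages rounded to 0.1.  The consensus topology is then given WLS
branch lengths against the *original* (non-bootstrap) distance matrix,
rooted at the midpoint of the outgroup's pendant edge, and ranked.

## Ranking

The path from the root leaf to the differentiated-reference leaf is the
differentiation path.  Every subtype leaf attaches to it at the node where
its own path to the root first meets it; subtypes attaching at the same
node share a tier (they cannot be distinguished in maturity).  The
reference endpoint is what disambiguates the two deepest subtypes, which
otherwise share their last common ancestor.

## Profile clustering

Mean profiles over the ordered columns (root, ranked subtypes, reference)
are z-scored per gene with the sample (n−1) standard deviation — the
common profile-standardization convention, pinned so tests are exact;
constant rows are dropped and reported.  Fuzzy c-means is implemented
in-repo: memberships u_ik ∝ (1/‖x_i−v_k‖²)^(1/(m−1)) normalized per gene,
centroids v_k = Σ u^m x / Σ u^m, iterated until the largest centroid
movement < 1e-6 or 300 iterations.  Defaults: c = 20 clusters (the value
used for the liposarcoma-scale analyses; c for other cohorts is a free
choice) and fuzzifier m = 1.25, a mildly fuzzy setting appropriate for
standardized profiles — the tool the method descends from does not fix m,
so it is configurable.  Centroids coinciding with a point get a hard
indicator membership.

Monotonicity is judged on centroids, not individual genes (cluster first,
interpret shapes second): a cluster is monotone iff its centroid is
non-decreasing or non-increasing with at least one strict step (tolerance
1e-9).  Genes whose maximal membership is in a monotone cluster and
≥ 0.5 are reported.  Fold changes between outgroup and reference use the
signed convention 2^Δ for Δ ≥ 0 and −2^(−Δ) otherwise, so a halving
displays as −2 rather than 0.5.

## Baselines

Greedy ordering sorts subtypes by distance to the anchor (ties
lexicographic) and supports the same replicate bootstrap, reporting the
fraction of replicates in which each label occupies each position.  The
MST uses Prim's algorithm from the first label with smallest-index ties;
because there is no established consensus procedure for MSTs, bootstrap
output is per-edge occurrence frequencies rather than a consensus tree.

## Synthetic data

The generator emulates the structure the analysis assumes: group means on
the log2 scale with i.i.d. Gaussian sample noise, a trajectory position
t ∈ [0, 1] per group (root 0, reference 1, subtypes evenly spaced unless
given), and three gene classes — monotone (mean a + tΔ, Δ uniform in ± the
effect range), subtype-specific spikes (shapes profile clustering must
reject), and nulls (FDR calibration).  Defaults: 2000 genes (60% null, 10%
spike), K = 5 subtypes, 10 samples/group, effects of 2–4 log2 units across
the trajectory, noise sd 0.5 log2 units, baselines uniform on 6–12 —
magnitudes typical of RMA-normalized arrays.

What the generator does *not* emulate: batch/source effects of
meta-analyses, probe-level artifacts, correlated gene modules,
heavy-tailed noise, or misclassified samples.  Passing tests therefore
demonstrate correctness of the algorithms and calibration of the
statistics under the assumed model, not robustness to those real-data
complications (the sample bootstrap addresses classification uncertainty
only to the extent the labels are noisy, which the generator does not
inject).

## Problem sizes in the test and validation runs

The validation experiments use scaled study conditions chosen once:
planted-order recovery runs 50 simulation seeds with 200 bootstrap
replicates each at the default generator settings; the null-FDR
calibration uses 200 datasets of 1000 null genes (3 groups × 5 samples);
heuristic-vs-exhaustive agreement uses 50 noisy additive matrices of 5–7
leaves; subset-size calibration uses 10,000 draws at N = 101.  The full
10,000-replicate bootstrap is the production default but is not exercised
in tests; supports stabilize far earlier at these effect sizes.

## Known limitations

* Exhaustive search grows as (2n−5)!!; beyond ~10 leaves the heuristic is
  the only practical route, and it is a local optimum (though it matched
  the exhaustive optimum in every tested instance).
* The apsd denominator is m (all pairs); other conventions (m−1, m−2)
  exist, so printed fit percentages are comparable only within this tool.
* Consensus branch lengths are fit to the original distance matrix, so
  multifurcating consensus nodes can absorb length that a fully resolved
  tree would split.
* Expression distances are phenotype distances: the resulting phylogeny
  ranks dissimilarity in expression space and must not be read as the
  evolutionary history or cell of origin of any tumor.
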