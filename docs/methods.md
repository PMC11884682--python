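# Methods

`cnpdr` implements feature selection for datasets whose predictors are
pairwise correlations between named units.  The motivating data type is
resting-state fMRI functional connectivity — one symmetric correlation matrix
per subject over n ROIs, vectorized to n(n−1)/2 predictors — but nothing in
the package is specific to neuroimaging: any case/control study with
correlation-based features fits.

## The NPDR contrastive regression

Nearest-neighbor projected-distance regression (NPDR) turns feature selection
into a regression over *pairs of samples*.  For samples i, j the outcome is
the contrast indicator δ_ij (1 if the two samples belong to different classes,
a "miss"; 0 if the same class, a "hit"), and the predictors are projected
distances:

* pair-level (one column per ROI pair p):  d_ij(p) = |A_p^i − A_p^j|,
  the absolute difference of that correlation between the two subjects;
* node-level "correlation-diff" (one column per ROI r):
  d_ij(CD, r) = Σ_{k≠r} |A_rk^i − A_rk^j|, the total absolute change of r's
  correlation profile between the two subjects.

The two designs satisfy Σ_r d_ij(CD, r) = 2 Σ_p d_ij(p) — every pair diff is
counted once for each of its two endpoint ROIs; this identity is asserted in
the test suite on random instances.

Regression rows are nearest-neighbor sample pairs.  The default
neighborhood is the multiSURF-style adaptive radius: j is a neighbor of i
when dist(i, j) < mean_i − sd_i/2, where mean_i and sd_i summarize i's
Manhattan distances (on standardized pair features) to all other samples;
a fixed-k alternative is available.  Ordered neighborhoods are deduplicated
to unordered pairs before fitting so no sample pair contributes two identical
rows; the toggle `deduplicate=False` restores the raw ordered rows.  Rows are
treated as independent observations, as is conventional for this family of
methods; they are not, since rows share samples, and the practical
consequences are quantified below.

Fitting is a binomial GLM of δ on each single projected-diff column
(univariate mode; jit-compiled per-column Newton solver, cross-checked in the
tests against statsmodels to ~1e-7).  P-values are one-sided for β > 0
because only a positive association between a feature's diff and class
discordance indicates importance; Benjamini–Hochberg adjustment is applied
across columns and features with adjusted P > 0.05 are removed.  The
multivariate mode fits all columns at once with a LASSO or Ridge penalty;
the penalty strength is chosen by 10-fold cross-validated binomial deviance
with the one-standard-error rule.  We use the 1-SE rule rather than the
deviance minimizer because the shared-sample structure of the rows flattens
the CV deviance curve and makes the minimizer unstable — in simulation it
oscillates between the null model and a weakly penalized model, whereas the
1-SE choice is stable and yields the expected sparse LASSO supports.

## From pair importance to node importance

* **corr-diff NPDR** regresses on the node-level design directly; ROIs are
  ranked by the (signed) Ridge coefficient on standardized columns, or by
  univariate P-value.  Ranking uses signed coefficients in descending order,
  consistent with the one-sided univariate convention: a large *negative*
  coefficient is noise, not importance.
* **centrality NPDR (c-NPDR)** keeps the FDR-surviving ROI pairs, graphs
  them (all ROIs retained as nodes, so isolates score zero), and ranks
  individual ROIs by a centrality: raw degree, unnormalized shortest-path
  betweenness, the principal eigenvector of the adjacency matrix (computed
  by dense symmetric eigendecomposition — deterministic and well-defined on
  disconnected selections, where it concentrates on the component with the
  largest adjacency eigenvalue), or IVI.
* **centrality random forest (c-rf)** replaces NPDR with random-forest
  importance: Breiman out-of-bag permutation importance from a 5000-tree
  forest (scikit-learn classification defaults otherwise), the top 200 pairs
  by importance form the network, then centralities as above.  The OOB
  permutation step is computed per tree in a jit-compiled kernel and only
  permutes features a tree actually splits on (others contribute an exact
  zero), which makes 5000-tree forests tractable on one core.

IVI (Integrated Value of Influence) is implemented from its published
definition: six constituent measures — degree, local H-index, neighborhood
connectivity (the "hubness" side) and ClusterRank, betweenness, collective
influence with sphere radius 2 (the "spreading" side) — are each range-scaled
to [1, 100]; hubness and spreading are the rescaled sums of their three
components, and IVI is their product, rescaled to [1, 100].  The tests verify
it component-wise against an independent brute-force evaluation on toy
graphs.  Ties in every ranking are broken by ROI identifier so runs are
exactly reproducible.

## The simulator

The generator plants ground truth directly in correlation space; it does not
simulate time series.  Steps:

1. A base network on n ROIs (Erdos-Renyi G(n, p) by default; a user-supplied
   edge list is passed through unchanged).  Defaults: n = 100, p = 0.1.
2. Baseline correlations per subject: Normal(0.5, 0.1) on base-graph edges,
   Normal(0.1, 0.1) on non-edges, clipped to (−0.99, 0.99) — connected ROIs
   get the higher correlations.  The matrices are treated as tabular
   predictors; positive semidefiniteness is not enforced by default (an
   optional nearest-PSD projection flag exists, off by default, because the
   matrices are never reused as covariances downstream).
3. Functional structure: n_functional nodes (default 10) drawn uniformly
   from the largest connected component.  The `multiway` parameter is the
   interaction order: functional nodes are partitioned at random into groups
   of `multiway` mutually differentially-correlated nodes and every
   within-group pair becomes a differential edge; `multiway="max"` makes all
   functional pairs differential.  At the default multiway = 5 the 10
   functional nodes form two disjoint differential 5-cliques (20 edges).
   Among the readings consistent with a per-node edge budget we chose this
   one because it reproduces the benchmark phenomenology the method family
   is known for: with differential structure confined to disjoint clusters,
   degree spreads credit across all functional nodes while eigenvector
   centrality locks onto a single cluster and betweenness finds no
   shortest-path brokerage inside cliques.
4. Effect injection: on each differential edge the sampling mean is shifted
   by +d·σ/2 for cases and −d·σ/2 for controls (σ = 0.1, d = 0.5 by
   default), so the parameter *is* the realized Cohen's d between groups;
   the tests confirm the empirical d averages 0.5 ± 0.1 over 50 replicates.
5. Seeding: one master seed spawns independent child streams for the graph,
   the functional structure and the subject draws, so datasets are
   bit-reproducible and replicates independently reproducible.

What the generator deliberately omits: spatial autocorrelation between ROIs,
subject-level covariates (age, sex, motion), heavy-tailed or bounded-support
correlation distributions, and any guarantee of a positive-semidefinite
matrix per subject.  Passing benchmarks here therefore demonstrates correct
mechanics and the relative behavior of the ranking methods under a clean,
exchangeable noise model — not performance on real functional-connectivity
data.

## The benchmark

Each replicate simulates a dataset, runs every requested method, and scores
the method's top-k ROIs against the k planted functional ROIs with F1
(= overlap/k when both sets have size k; k defaults to n_functional = 10).
Between-method differences use the two-sided Wilcoxon rank-sum test on
replicate F1 values; replicates share seeds across methods, so comparisons
are paired by dataset even though the test itself is rank-based.

Problem sizes used by the shipped tests and acceptance script: the six-method
comparison runs 25 replicates of the default design; the acceptance script's
four-method comparison runs 25 replicates; null-calibration checks use 10
replicates.  The benchmark's random-forest arm uses a 1000-tree forest (500
under the null), a deliberate desk-scale choice.  Ensemble size does shift
the c-rf mean F1 (larger forests stabilize the importance ranking and lift
it somewhat), but it does not change any of the between-method conclusions
the tests draw, which were spot-checked against 5000-tree runs.

## Calibration facts worth knowing

Measured on this implementation (they are also asserted or reported in the
test suite):

* Under the null (effect 0), the univariate P-values are close to uniform
  but mildly conservative: the pooled fraction below 0.05 is ≈ 0.041 over
  ten 100-ROI replicates.  The deficit is the footprint of treating
  neighbor-pair rows as independent when they share samples.  A pooled
  one-sample KS test against the uniform at iid critical values is extremely
  sensitive to this (and to the strong cross-feature dependence within a
  replicate — 4950 p-values per replicate share one neighborhood and one
  δ vector), so it rejects at large pooled n even though per-feature
  calibration is adequate for FDR control at the 0.05 level.
* Because calibration is clean, FDR-selected networks at d = 0.5 are small
  (tens of edges) and dominated by true differential edges.  Degree
  centrality then recovers functional ROIs well; eigenvector and betweenness
  recover them poorly (structurally, per the clique argument above); IVI,
  whose hubness side is degree-like, tracks degree closely on such clean
  selections and only degrades when selections are noisy.

## Known limitations

* Neighbor-pair dependence is documented, not corrected; P-values are
  slightly conservative and would become anticonservative if deduplication
  were disabled.
* The Ridge/LASSO coefficients carry no standard errors; selection for the
  penalized modes is support- or rank-based only.
* Betweenness is computed on the unweighted selected network even when
  importance weights are attached to edges (weights are carried for export
  and display only).
* `compare_methods` requires ≥ 5 replicates per method and switches to an
  asymptotic rank-sum; exact small-sample tests are out of scope.
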