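# Methods

This note documents the models, estimators, and numerical choices behind
`rppanet`, and what the synthetic benchmark does and does not establish.

## The inference problem

Input is a samples × antibodies real matrix per cohort (tumor type), assumed
normalized upstream (replicate-based batch normalization is out of scope;
inputs arrive normalized). The target is an undirected network over the
antibodies in which an edge means a *direct* statistical dependence. The
dominant failure mode is the transitive correlation: in a cascade A→B→C, or
a fan-in/fan-out, the non-adjacent pair correlates without interacting.
Partial-correlation and mutual-information methods attack this by
conditioning or by the data-processing inequality (DPI); plain correlation
does not and serves as the baseline family.

## Estimators

All estimators return a symmetric weight matrix with zero diagonal.
Correlation and partial-correlation weights are signed (positive = levels
rise and fall together, negative = mutual exclusivity); mutual-information
weights are nonnegative. Edge significance is |weight|; ranks are
tie-averaged for consensus use and traversed in a deterministic
(descending |weight|, then lexicographic pair) order for PR curves.

**Inverse covariance.** `simpleparcor` uses the Moore–Penrose pseudo-inverse
of the sample covariance, which degrades when samples < ~2× antibodies —
this is deliberate; it is the unregularized reference point. `genenet`
applies Schäfer–Strimmer analytic shrinkage of the correlation matrix toward
the identity with intensity
λ* = Σ_{i≠j} Var̂(r_ij) / Σ_{i≠j} r_ij², clipped to [0, 1]; λ* → 0 as
n → ∞, so it converges to `simpleparcor` (tested). `glasso` estimates the
precision by ℓ1-penalized maximum likelihood (penalty ρ) on the correlation
matrix.

**Node-wise regression.** Each antibody is regressed on all others
(columns standardized first). The penalty is selected per node by 5-fold
cross-validated prediction error over the grid; folds are shuffled with the
global seed. Grids (the originals for this design were never published, so
they are re-specified to span the under- to over-regularization regimes):
ridge/lasso/elastic-net penalties log-spaced 1e-4…1e2 (10 points;
elastic-net crossed with mixing ∈ {0.25, 0.5, 0.75}), PLS components 1…8.
The coefficient matrix is symmetrized by
pĉ_ij = sign(B_ij)·√(max(0, B_ij·B_ji)); coefficients that disagree in sign
yield weight 0. With a vanishing ridge penalty this route coincides with the
inverse-covariance partial correlation (tested to 1e-2).

**Mutual information.** Pairwise MI is estimated with the k-nearest-neighbor
(Kraskov) estimator, k = 3 by default (the upstream convention; the value
was never published for this design), clamped at 0 nats.
`aracne_a` zeroes w_ij when MI_ij < min(MI_ik, MI_jk) − ε for any k
(additive DPI tolerance); `aracne_m` uses the multiplicative form
MI_ij < min(MI_ik, MI_jk)·(1 − τ). Note the direction: a larger tolerance
prunes *less*; ε = τ = 0 is the most aggressive setting. Tolerance grids
are {0, 0.05, 0.1, 0.15, 0.2}. `clr` standardizes MI_ij against the
off-diagonal mean/sd of row i and row j and combines the positive parts as
√(z_i² + z_j²). `mrnet` scores each (target, predictor) pair by the
max-relevance/min-redundancy objective at the moment the predictor enters a
forward selection (selection stops when the best objective is ≤ 0), then
symmetrizes by the maximum of the two directed scores (the common
convention; the choice was open). Adaptive-lasso refinement of the lasso
variant is omitted; plain cross-validated lasso is used.

## Benchmarking

Precision at cutoff t is TP(t)/t over the top-t ranked pairs, recall is
TP(t)/|gold|; pairs with an endpoint outside the gold universe are excluded
before traversal, so antibodies without benchmark coverage cannot distort
the curve. The comparison metric is AUPR restricted to recall ∈ [0, 0.1]:
beyond that window precision collapses toward the gold density and methods
become indistinguishable. Integration is trapezoidal, with the curve
anchored at (0, precision of the top edge) and linearly interpolated at the
window edge; the step-rule alternative shifts absolute values slightly but
not method order on our tests. Parameterized methods (glasso ρ, ARACNE
ε/τ) are optimized by exhaustive grid search on this limited-recall AUPR,
ties breaking to the first grid cell; the regression family self-selects by
inner CV and contributes a single configuration. Cross-cohort scores are
the sum of per-cohort AUPRs and the sum of per-cohort AUPR ranks
(rank 1 = best, tie-averaged).

## Consensus and discovery set

Method p-values are unavailable or not independently combinable (all
methods see the same data), so edge ranks act as a nonparametric
significance proxy. For a chosen method set (default: the intersection of
the top-6 by both overall criteria, falling back to top-6 by rank sum if
the intersection is degenerate), the consensus rank is the mean of
tie-averaged ranks and the consensus weight is the mean over methods of
|weight| min–max-scaled to [0, 1] per method — without scaling,
mutual-information magnitudes (nats) would dominate correlations — with the
sign taken by majority vote among the signed methods (zero-sum ties count
positive). Whether the original analysis rescaled before averaging is
unstated; tracking signs separately is consistent with its published
consensus tables.

The rank threshold is selected by sweeping candidates (default 25…2000 in
steps of 25), building per candidate the union edges × cohorts weight
matrix of pairs significant in ≥ 1 cohort, and recording the summed
explained-variance percentage of the first three principal components
(cohorts as variables). The threshold is the candidate at the inflection:
the largest-magnitude discrete second difference after a window-3 moving
average (valid-mode — edge padding would fabricate curvature at the sweep
boundaries). A flat or exactly linear series returns the median candidate
with a warning; with 3 cohorts the first three PCs always explain 100%, so
small studies exercise this fallback by construction. Discovery pairs carry
their full consensus weight in every cohort (not 0 where non-significant);
recurrence counts the cohorts beating the threshold.

## Edge groups, modules, statistics

Discovery edges are Ward/Euclidean-clustered on their per-cohort weight
vectors and cut at 3; clusters are named by mean pan-cancer weight (highest
→ positive dominant, lowest → negative dominant, rest heterogeneous).
Recurrence is annotation only, not a clustering feature (the ambiguity was
resolved in favor of annotation-only). The discovery graph is partitioned
by five community-detection algorithms — fast-greedy, spin-glass (run per
connected component, since it requires connectivity; module ids offset),
multilevel, infomap, walktrap — on the unweighted graph by default
(weighted mode available). Co-assignment frequencies (fraction of
algorithms placing a pair in one module) form a symmetric matrix with unit
diagonal and entries in {0, 0.2, …, 1}; Ward clustering of its rows cut at
6 gives the consensus modules, ids ordered by size. Per-module statistics
count intra-module edges split by group, antibodies split by
phosphospecificity (only antibodies with ≥ 1 intra-module edge are counted,
matching the convention that an antibody with only inter-module edges does
not appear in its module's tally), average degree 2E/N, and the top-3
intra-module hubs with per-group edge counts.

## Gene-list mapping

Each significant pair is reduced to the gene sets of its antibodies;
pairs whose sets intersect are gene-level self-interactions and are
skipped. A gene list matches when both sets hit it; the contribution is
|consensus weight| divided by the list size (the signed variant is
available but absolute value is the default, matching the published
pseudocode over the figure caption's wording), and the cell value is the
mean over matched interactions — unmatched cells are missing, not zero.
The hierarchy is a DAG (multi-parent children allowed); every list traces
to the top-level roots reachable by parent links, with cycles rejected by
name. Species filtering is a caller-supplied id predicate at load time.

## Synthetic data: the stated world

Real tumor cohorts have no known truth, so the benchmark world is a
Gaussian graphical model — exactly the estimator class of the
partial-correlation family, which makes parameter recovery a meaningful
test surface. `generate_ground_truth` draws round(density·C(n,2)) edges
uniformly (default density 9.29%, the benchmark network's), gives each a
coupling of magnitude U(0.4, 0.9) with ~30% negative (so negative-dominant
grouping is exercised), and guarantees positive definiteness by diagonal
dominance (diag = 1 + row sum of |couplings|). Cohorts are i.i.d.
multivariate normal with covariance Ω⁻¹ plus independent N(0, noise_sd²)
measurement noise; noise_sd defaults to 0.1 (≈10% of the unit-scale
marginals — a high-signal-to-noise assay). Optional per-cohort rescaling of
a random edge subset (support unchanged) emulates tumor-type heterogeneity
in interaction strength. Antibody annotation marks ~27% of antibodies
phosphospecific (51/187, the panel's ratio), a configurable fraction as
two-gene (paralog) antibodies, and always includes one antibody pair
sharing a gene so self-interaction skipping is exercised. The gene-list
generator grows a forest in which every child list is a subset of its
parent; defaults (40 lists, 6 roots) are desk scale versus the ~1669 lists
and 24 top-level processes of the real collection.

What a green benchmark does *not* establish: real RPPA data are
non-Gaussian, batch-structured, and antibody cross-reactive; the real gold
standard is ascertainment-biased and incomplete; and cohort differences in
vivo are not mere coupling rescalings. Quantities tied to the real data —
the exact rank-425 threshold, the 1008-edge discovery set, specific module
counts and tumor groupings — are not reproduction targets; the pipeline
reproduces the *procedures* and their arithmetic, not those constants.

## Determinism and numerical edge cases

All stochastic components (sampling, CV folds, the MI estimator's
tie-breaking noise, spin-glass annealing) flow from one seed; pipeline
outputs are TSV with 12-significant-digit floats and are byte-identical
across runs of the same config. Zero-variance antibodies are rejected by
name. An empty penalty grid, an empty gold standard, an empty discovery
set, infeasible densities and cohort sizes < 3 are rejected. Unsigned
networks reject negative weights at construction. Consensus rank ties and
PR-curve ties have the deterministic conventions described above.
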