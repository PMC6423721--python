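# Methods

`psnkit` implements supervised patient classification over patient
similarity networks (PSNs): every feature of patient data — a whole data
type, a single variable, or a pathway's gene subset — becomes a weighted
graph whose nodes are patients, and classification reduces to asking which
class's feature-selected, integrated network places a held-out patient
closest to that class's known members.

## Similarity metrics

For a single continuous variable with observed value set G, similarity
between patients a and b is the normalized similarity

    S(a, b, G) = 1 − |a − b| / (max G − min G),

and a small multivariate layer (k ≤ 5 variables) uses the average S′ of the
per-variable values. Layers with six or more variables use Pearson
correlation of the patient profiles instead; the boundary at six follows
the minimum-sample argument for stable correlation estimates. Pathway
features correlate the expression sub-vectors of a gene set's member genes;
sets with fewer than 10 or more than 200 genes present in the matrix are
skipped. Missing values are handled pairwise-complete with a minimum of
three shared observations per edge; an undefined correlation (too few
pairs, zero variance) omits the edge rather than inventing a weight.

An optional locally scaled exponential kernel supports Euclidean- and
correlation-distance variants: w = exp(−d² / (μ·ε)), with each patient's
local bandwidth the mean distance to its k nearest neighbors and a pair's
bandwidth the average of the two local bandwidths and the pair distance
itself. Defaults μ = 0.5, k = 20 are configurable; the scalar kernel op
averages only the two patients' bandwidths, per its contract.

## Sparsification

Networks are pruned by (1) a weight cutoff (default 0.3 for correlation
networks; the smallest positive float for exponential kernels, whose
weights are all positive); (2) a per-node top-X rule (default 50) in which
an edge survives if it ranks in the top X of either endpoint — the
endpoint-union rule preserves symmetry; and (3) an optional global cap on
edge count. Any patient orphaned by the cap is re-attached through its
single strongest original edge, raised to the cutoff if weaker, so every
patient remains classifiable. Ties are broken by weight descending, then
partner/edge ID ascending, making the operation deterministic and
idempotent. Sparsification is applied once at network construction.

## Network weighting (feature relevance)

Given a query (a subset of one class's training patients) within a patient
universe of size n, let u be the zero-mean label vector (u_i = n_o/n for
query members, −n_q/n otherwise). Each unordered patient pair (i, j)
contributes a regression row: the targets t_ij = u_i·u_j are positive for
same-group pairs and negative for cross-group pairs, and the predictors are
the pair's edge weights in each candidate network (zero when absent), plus
an unpenalized intercept. Ridge regression (default λ = 1) fits per-network
coefficients; features with non-positive coefficients are dropped and the
system re-solved until all remaining coefficients are positive (the active
set shrinks strictly, so the loop terminates). A round can end with no
positive feature; that is a signal, not an error.

Numerical notes. The ridge system is solved as an augmented least-squares
problem, which at λ = 0 degrades gracefully to the minimum-norm ordinary
solution — this keeps duplicated (collinear) networks well defined, where
the duplicate copies split the single-network weight equally and their sum
equals the single-network weight exactly in the unpenalized limit. With a
fixed λ the penalty couples to the scale of the design, so the
positive-weight set is exactly invariant to a common rescaling of all edge
weights only as λ → 0; the property suite asserts both identities in that
limit. Pairs among non-query patients are included in the target by default
(t > 0 for them): dropping them (toggle `include_nonquery_pairs=False`)
makes selection for the queried class more specific but leaves a class with
no within-class signal unable to select contrastive features, which costs
held-out accuracy on the standard cohort (mean AUROC 0.89 vs 1.00 in the
package's own end-to-end test conditions).

## Label propagation and classification

Selected networks are combined by uniform averaging (a network missing an
edge contributes zero), keeping combined weights in [0, 1]. For a class's
integrated network W, the bias vector sets y = +1 on the query (all
training members of the class) and (n_q − n_o)/(n_q + n_o) elsewhere, and
propagation solves

    f = (I + λ·L_sym)⁻¹ y,   L_sym the symmetric-normalized Laplacian,

with λ = 1 by default. Isolated nodes keep f_i = y_i (their Laplacian row
is zeroed). The system is positive definite, solved directly at small n and
by conjugate gradients (`iterative_propagate`) at scale; because all
eigenvalues are ≥ 1, a residual 2-norm below the tolerance bounds the
max-norm solution error by the same tolerance. Ranks order patients by
descending f with ties broken by ascending patient ID.

Raw propagation scores from different class databases are not on a common
scale, so classification compares normalized ranks r = 1 − (rank−1)/(n−1):
the predicted label is the class giving the highest r, ties to the
lexicographically smallest label, and the binary decision score is the rank
difference oriented toward the lexicographically larger label.

## Feature scoring and the predictor loop

Feature scores count, per class, the resampling rounds (default 10) in
which a feature earns a positive weight for a query drawn as a
without-replacement 80% subsample of the class's training members; features
scoring ≥ 9 of 10 are selected. Per-class RNG streams are derived by
hashing the class label with the master seed, so scores do not depend on
class iteration order. Scoring networks are restricted to training patients
before any query runs, making held-out patients structurally unable to
influence selection.

The full predictor repeats, per stratified 80:20 split: optional
training-median imputation (test entries filled with training medians),
optional lasso prefiltering (L1-penalized logistic regression on
standardized training data, penalty chosen by internal cross-validation on
training folds; variables with non-zero coefficients are kept, an empty
result omits the layer for that split), network construction on training
patients, feature scoring and selection, reconstruction of the selected
networks over train ∪ test with the identical sparsifier, rank-based
classification, and AUROC / AUPR / accuracy via the standard rank and
step-integration estimators. A class with an empty selection falls back,
loudly, to all features so every split remains classifiable. Everything
derives from one master seed; identical seeds reproduce reports byte for
byte.

## Integrated network and class separation

Features attaining the maximum score in every split (or, optionally, a
consistency floor in ≥ 70% of splits) are combined by uniform averaging
into one integrated PSN over all patients. Similarity converts to
dissimilarity d = 1 − w (absent edges stay absent), shortest paths are
computed with Dijkstra's algorithm, and the one-tailed
Wilcoxon–Mann–Whitney test asks whether within-class path distances are
collectively shorter than between-class ones — exact null for a combined
pair count up to 20, tie-corrected normal approximation beyond. Unreachable
pairs are excluded from the means and counted rather than assigned an
arbitrary maximum. Display exports keep either the shortest 40% of edge
distances or, in figure mode, edges of weight ≥ 0.7 with the top 20% of
each node's surviving edges.

## Synthetic cohort

The generator emulates a two-class expression cohort with planted pathway
effects. Defaults — 60 patients per class, 30 disjoint 20-gene sets, 3
predictive sets, per-gene effect magnitude d = 1.5 — are the package's
standard study conditions. Baseline expression is standard normal; each
predictive-set gene is shifted in the case class by ±d with alternating
sign. The sign structure is essential: a constant shift across a pathway's
genes is removed by the per-patient centering inside Pearson correlation,
whereas sign-varying shifts give cases a shared profile whose expected
within-case correlation is d²/(d²+1) (≈ 0.69 at d = 1.5), well above the
0.3 sparsifier cutoff. Optional clinical variables carry stated mean shifts
or pure noise; missingness is completely at random, which is all the
leak-free imputation contract requires. The truth record lists the
predictive sets and per-gene offsets.

What the generator does not emulate: realistic gene–gene covariance,
batch or library-size artifacts, heavy-tailed expression, informative
missingness, and multi-omic cross-layer correlation. Passing tests
therefore demonstrate the machinery's correctness and its behavior under
clean mean-shift signal, not performance on real cohorts.

A caveat the tests surface deliberately: with the cohort fixed and only the
query resampled, a noise network whose random edges are by chance enriched
within a class keeps a stably positive fitted weight, so roughly one in ten
noise features reaches the selection threshold for a given class in a
single scoring pass. This is intrinsic to resampling-within-one-cohort;
the cross-split consistency criterion (maximum score in *all* splits) is
the mechanism that removes such features, and the integrated-network tests
rely on it.

## Problem sizes and runtime

Test and acceptance runs use the standard 120-patient cohort (30 pathway
networks, 5 train/test splits), 50-node solver-agreement instances, and
scaled-down 30–40 patient cohorts for leakage and reproducibility checks;
these sizes give stable statistics while keeping the whole suite fast on a
single CPU. All sizes are configuration, not limits: the solvers are
O(n³) dense or sparse-CG, and the pair regression is O(n²) rows per fit.
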