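# Methods

## Problem and pipeline

The package addresses supervised marker-gene discovery: given single-cell
(or bulk) expression profiles with a categorical condition label per cell,
find a small gene subset that discriminates the conditions, together with
interpretable expression-threshold rules. The procedure is
filter-then-wrap: six importance rankings produce candidate orderings of
all genes; incremental feature selection (IFS) then evaluates growing
prefixes of each ordering with actual classifiers and picks the prefix
that maximizes weighted F1 (the *optimal* classifier) and the shortest
prefix within δ of that maximum (the *suboptimal* classifier, whose genes
are the *essential genes*). Expression values are used as-is: the
pipeline applies no normalization or log transform and is agnostic to
the value scale, which also means rankings and rules are only comparable
across datasets processed the same way upstream.

## Evaluation measures

All classifiers are scored on pooled out-of-fold predictions (per-fold
averaging is available via `fold_aggregation="mean"`). Four measures:

- **ACC** — fraction correct.
- **Weighted F1** — per-class precision Pᵢ and recall Rᵢ are averaged
  with class-share weights wᵢ (share of class *i* among the true
  labels), and the weighted F1 is the harmonic mean
  2·P_w·R_w/(P_w+R_w). This is deliberately *not* the common
  "weighted-average of per-class F1": on the 4-sample example
  true=[A,A,A,B], pred=[A,A,B,B] it yields 0.80769 where the
  conventional statistic yields 0.76667. Ratios 0/0 are defined as 0
  (affects only never-predicted classes).
- **Macro F1** — unweighted mean of per-class F1.
- **MCC** — multiclass Matthews correlation from one-hot truth and
  prediction matrices, cov(X,Y)/√(cov(X,X)·cov(Y,Y)) (Gorodkin's R_K);
  0 when a covariance degenerates (e.g. constant predictions).

A brute-force evaluator of these definitions, written independently in
the test suite, agrees with the implementation to 1e-12 on a thousand
random label configurations.

## Class balancing (SMOTE)

Minority classes are oversampled to the majority size by interpolating
between a class member and one of its k = 5 nearest same-class
neighbours (Euclidean), s = x + λ(x′−x), λ ~ U(0,1). Originals are kept
verbatim; each synthetic row records its generating pair, which makes
the convexity property directly checkable. Classes with n ≤ k use
k = n−1; singleton classes are replicated verbatim with a warning.

**Placement matters.** Two modes exist:

- `infold` (default): SMOTE runs inside each training fold only; test
  folds never contain synthetic points. This is the statistically clean
  choice and is what new analyses should use.
- `prefold`: the whole dataset is balanced once, then folds are drawn
  from the augmented data — the protocol the motivating study describes
  (balance first, then 10-fold CV). Interpolated copies of test cells
  leak into training, so scores are optimistic; the package's
  replication benchmark uses this mode *because it is the study's
  protocol*, and the shuffled-label negative control is run under the
  honest default instead. On the desk benchmark the same RF pipeline
  scores ≈ 0.89 weighted F1 in-fold and ≈ 0.97 prefold — the gap is the
  leakage, worth keeping in mind when comparing numbers to the
  literature.

## Ranking methods and their defaults

Uncited hyperparameters are package choices, picked for the n ≪ p
expression regime and recorded in every feature list's provenance:

- **rf_mdi** — random forest Mean Decrease Impurity; 100 trees, √p
  features per split.
- **lightgbm_gain / xgboost_gain** — the libraries' gain importances
  (total, resp. average, training-loss reduction from a feature's
  splits). XGBoost uses 500 rounds of depth-2 trees: with hundreds of
  cells and thousands of genes, many shallow trees spread importance
  across all informative genes, whereas few deep trees concentrate it
  on a handful and leave the rest indistinguishable from noise.
- **catboost_pvc** — "prediction values change": fit a gradient-boosted
  tree model (sklearn HistGradientBoosting, 300 iterations, depth 3,
  5 % of features per split), then shuffle each gene's column once and
  record the mean absolute change in predicted class probabilities.
  Only trees that split on the shuffled gene are re-evaluated (all
  others provably cancel), so unused genes score exactly 0 and the scan
  is fast. The feature subsampling forces the model to touch many
  informative genes instead of a minimal subset.
- **lasso** — features standardized per gene; L1 multinomial logistic
  regression (saga), inverse penalty chosen by stratified 5-fold CV
  over 20 log-spaced values spanning C ∈ [1e-2, 1e2]; a gene's
  importance is the maximum |coefficient| over classes (max preserves
  class-specific markers that mean-aggregation dilutes). Zero-variance
  genes score 0.
- **mcfs** — Monte Carlo Feature Selection, implemented from first
  principles: s random projections of m genes × t stratified 0.66/0.34
  splits, one entropy decision tree each; a gene used by tree τ gains
  (wAcc_τ)^u · Σ IG(node)·coverage(node)^v, with wAcc the mean of
  per-class recalls on τ's test part, IG in bits, coverage the fraction
  of τ's training samples reaching the node. Defaults u = v = 1,
  t = 5, s·t ≥ 2000 trees, and m = 3⌈√p⌉ — deliberately above the √p
  rule of thumb: when informative genes are ~0.5 % of all genes,
  √p-sized projections rarely present a marker with enough company to
  win splits, and the importance estimate stays noisy. Projections are
  drawn over the sorted gene list, so scores do not depend on column
  order. Importance profiles of independent 2000-tree populations
  correlate at ≈ 0.94 (Pearson); rank correlation over *all* genes is
  not a meaningful stability measure because the ranks of thousands of
  near-zero noise genes are arbitrary.

Every method returns a full-coverage list: unused genes score 0 and are
ordered after scored genes, ties broken by gene id, so lists are
bitwise reproducible given a seed.

## IFS, selection, rules, intersections

Prefixes k = step, 2·step, …, max_k (defaults 5 and 1000; the grid may
be thinned beyond a `coarse_after` point once curves have flattened).
Folds are stratified, fixed once per scan, and shared by all k and both
classifiers, so curve differences are attributable to the prefix alone.
Classifiers: CART (Gini, unlimited depth) and random forest (100 trees,
√p features per split), both seeded. Optimal k maximizes weighted F1
(ties → smallest k); suboptimal k is the smallest within δ = 0.01
(observed optimal-to-suboptimal gaps in the motivating study are below
that). Final classifiers are refit on the full SMOTE-balanced dataset.

Rules are the best decision tree's root-to-leaf paths with per-gene
bounds merged to the tightest interval; they reproduce the tree's
predictions exactly and form a partition of feature space (mutually
exclusive, jointly exhaustive — both are asserted on random probes).
Essential-gene sets from the six suboptimal RF classifiers feed an
upset-style exclusive-region count over all non-empty method subsets.

## Synthetic data

The generator emulates what the analysis assumes and nothing more: a
per-gene baseline mean μ_g drawn once from a lognormal (median
`base_mean` = 8, log-sd `mean_sdlog` = 0.5), counts from a negative
binomial with size `dispersion` = 2 (variance m + m²/2), marker genes
multiplied by `fold_change` = 4 in their own class, and independent
dropout zeroing each observation with probability 0.5. Class
compositions: the three study presets (CF 21,034 / CM 73,296 /
Endo 35,673 cells over six conditions) and a `desk` preset
(120/115/40/70/25/45 = 415 cells, 2000 genes, 10 markers per class)
sized for minutes-scale end-to-end runs.

The expression scale deserves a note: with negative-binomial noise the
per-gene coefficient of variation saturates at 1/√dispersion for large
means, so `base_mean` mainly controls how many genes sit in the
low-count, dropout-dominated regime. The defaults put the desk preset
in the strongly separable regime the benchmark requires: a
likelihood-ratio oracle that knows the true generative parameters
reaches weighted F1 ≈ 0.98 there (against ≈ 0.93 at base_mean 2, where
no classifier whatsoever could meet the benchmark bar). The desk
problem sizes were chosen so the full six-method benchmark completes in
minutes on one CPU.

What the generator does *not* model: batch effects, library-size
variation beyond the lognormal mean jitter, doublets, gene–gene
correlation, down-regulated markers (available via `fold_change` < 1
with `allow_downregulated=True`, off by default). Passing the recovery
benchmark therefore shows the pipeline's machinery is sound — rankings
find planted univariate mean shifts, IFS concentrates them, selection
and rules are internally consistent — not that it would recover markers
under confounded real-world structure.

## Numerical and degenerate-input choices

- Artifact floats are written with 17 significant digits (exact binary64
  round-trip); rule thresholds render at 4 significant digits in the
  human-readable text form only.
- Metric ratios 0/0 → 0; MCC with a degenerate covariance → 0.
- Stratified CV reduces the fold count (with a warning) when the
  smallest class has fewer members than folds.
- A feature list shorter than the grid lowers max_k with a warning;
  constant genes are never scored; a single-class dataset is rejected
  for any training operation.
- All sub-seeds derive from one master seed by hashing
  (master, stage, method), so adding a method leaves other stages'
  draws untouched; reruns are byte-identical.

## Known limitations

- Importance rankings are correlational; essential genes are predictive
  markers, not causal claims.
- The suboptimal-δ rule inherits the noise of the IFS curve: on flat
  curves the essential-set size can swing between adjacent grid points.
- The prefold replication protocol overstates absolute performance (see
  the SMOTE section); only the in-fold numbers estimate generalization.
- MCFS and PVC costs grow linearly in trees × cells; full-scale inputs
  (10⁵ cells × 3·10⁴ genes) are feasible for the tree ensembles but the
  LASSO CV grid becomes the bottleneck and would need its grid reduced.
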