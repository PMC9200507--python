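# Methods

This note documents the models and procedures implemented in `mmaselect`,
the parameters that matter, the design choices made where more than one
reasonable option existed, and what the synthetic-data experiments do and do
not demonstrate.

## Data model

A dataset is a `DataTable`: an n × d cell grid with per-column type tags
(numeric or categorical), a binary label vector, and the two original label
tokens. Files are read as delimited text with a header; a column is typed
numeric iff every non-missing cell parses as a number; the label column
defaults to the last column (the convention of the public clinical tables
this toolkit targets) and must carry exactly two tokens, mapped to {0, 1} in
lexicographic order. Missing-value tokens default to `{"", "?", "NA"}`
("?" being the common convention in hepatitis-style files).

## Preprocessing

*Imputation.* Numeric missing cells take the column mean of observed
values; categorical cells take the column mode, with ties broken to the
lexicographically smallest level for determinism. Averaging only makes
sense for numerics, which is why categoricals use the mode. A fully missing
column is an error. Imputation is idempotent.

*Normalization.* Min-max scaling p′ = (p − min_p)/(max_p − min_p) maps each
numeric column's training range onto [0, 1]. A constant column (max_p =
min_p) maps to 0.0 rather than NaN: the ratio is undefined there and 0
keeps the range invariant. By default the scaler is fitted once on the full
table before selection and cross-validation — the sequential-pipeline
convention for this family of methods — and `refit_per_fold=True` switches
to leakage-free per-training-fold refitting for users who want the
conservative estimate.

*Encodings.* Categorical columns stay integer-coded for Naive Bayes (its
likelihoods are level frequencies) but are one-hot expanded — one {0,1}
coordinate per level — whenever Euclidean geometry is involved (K-means),
since squared-difference distances presuppose real vectors.

## Naive Bayes

Mixed Gaussian/categorical Naive Bayes for two classes: posterior ∝ prior ×
Π per-feature likelihood, evaluated entirely in log space so thousand-column
rows neither underflow nor overflow, then normalized. Numeric likelihoods
are class-conditional Gaussians with variances floored at `var_floor`
(default 1e-9, appropriate on the normalized [0,1] scale — constant columns
otherwise produce zero variance). Categorical likelihoods are Laplace
smoothed with `alpha` (default 1.0); a level unseen in training receives
the smoothed zero-count probability, never zero. Prediction is argmax
posterior; an exact tie goes to the class with the larger prior, then the
lower class index. The mixed variant was chosen because the target tables
mix numeric and categorical attributes.

## Cross-validation and metrics

Stratified k-fold (default k = 10): within each class, shuffled indices are
dealt round-robin, so per-class counts across folds differ by at most one.
Stratification is the default because these cohorts are class-imbalanced
and averaging per-fold accuracies is otherwise high-variance; a
non-stratified shuffled split is available. Each fold is held out once;
fold accuracies are averaged, and held-out predictions are pooled into one
confusion matrix from which precision, recall, F-score (2TP/(2TP+FP+FN),
identically the harmonic mean of precision and recall) and the Matthews
correlation coefficient are computed. Per-fold metric values are also kept
for users who prefer fold-mean summaries. Zero-denominator metrics return 0
with a warning. Latency = training time + testing time is reported but
never asserted anywhere, being hardware-dependent.

## The subset search

The search space is non-empty bit masks over the d feature columns.

*Fitness.* fitness(S) = mean stratified inner-CV Naive Bayes accuracy on
the columns of S (default 5 folds, fixed once per evaluator from its seed)
minus λ·|S|/d. Values are memoized per mask, so any number of strategies
sharing an evaluator see one landscape and repeated queries are free.

*Choosing λ (default 0.1).* The per-feature penalty λ/d must referee a
specific contest: an uninformative column that correlates with the labels
by chance improves inner-CV accuracy by a small but systematic amount —
measured at up to ~0.6% for the luckiest of 7 noise columns at n = 500 —
while a genuinely informative column contributes on the order of several
percent. λ = 0.1 puts the penalty (≈1% at d = 10) between those two scales,
so parsimony strips chance correlations without touching real signal.
λ = 0 recovers a pure wrapper.

*The walk.* Start from a random subset (each bit Bernoulli(½), rerolled if
empty). Each iteration enumerates the Hamming-1 neighborhood in ascending
flip-index order, discards neighbors currently in the metalist unless they
would beat the global best (aspiration), and moves to the best admissible
neighbor — accepting a worse-than-current move when nothing better exists,
which is the escape mechanism. The move target is pushed onto the metalist,
a strict-FIFO buffer of capacity `tenure` (default 10). If every neighbor
is tabu and none aspirates, the walk is forced onto the neighbor whose
buffer entry is oldest. Termination: `max_iter` (default 100) iterations,
`stall_limit` (default 20) consecutive iterations without global
improvement, or an optional absolute `fitness_threshold` (no default — the
natural stopping criteria are budget and stall). `restarts` (default 5)
independent walks share one evaluator and one global best. Ties everywhere
break to higher fitness, then smaller subset, then lexicographically
smallest mask, making every routine fully deterministic given its seed.

*Relevance scores.* `restarts` fully independent searches are run, each
with its own derived seed **and its own inner-fold split**; a feature's
score is 10 × its selection frequency. With a single shared fold split the
landscape is deterministic and all restarts can converge to the same
optimum, collapsing the score to a 0/10 indicator that echoes one split's
quirks; varying the folds makes the score a stability measure. Features
under `drop_threshold` (default 3.0) are flagged low-relevance. Inside a
single `mmas_select` call, by contrast, restarts deliberately share one
evaluator so that comparisons against the exhaustive oracle are exact.

*Oracle.* `exhaustive_select` scores all 2^d − 1 subsets with the same
tie-break (guarded at d ≤ 20) and is used as ground truth in tests.

## Baseline selectors

Greedy forward stepwise (start from the best singleton, add the best
strictly improving feature), best-first search (priority queue over
subsets, backtracking, stop after 5 non-improving expansions), a canonical
GA (population 20, 50 generations, tournament size 2, uniform crossover
0.6, bit-flip mutation 1/d, elitism 1, empty offspring repaired by setting
a random bit), and binary PSO (20 particles, 50 iterations, inertia 0.7,
c1 = c2 = 1.5, velocities clamped to ±6 so the sigmoid transfer never
saturates). These are fixed textbook parameterizations chosen for
reproducible comparison, not replicas of any particular legacy toolkit.
All share the memoized fitness evaluator.

## K-means outlier filtering

Lloyd's algorithm with Euclidean distance: Forgy initialization (k distinct
rows drawn by seed; k-means++ behind a flag), nearest-centroid assignment
with ties to the lowest cluster index, means recomputed until assignments
stabilize or `max_iter` (default 300). An emptied cluster is reseeded at
the row currently farthest from its centroid. Inertia is asserted
non-increasing at every step. k defaults to 2, the convention for
presence/absence cohorts.

Record-level filtering drops rows whose centroid distance exceeds their
cluster's mean distance + `z_cut` (default 3) standard deviations. Two
guards: (1) a cluster holding fewer than `min_cluster_frac` (default 5%) of
rows — or fewer than 2 rows — is dropped whole, because a centroid seated
on an extreme point has distance 0 to itself and its distance statistics
are meaningless; (2) the filter never drops more than `max_drop_frac`
(default 10%) of rows, keeping the most extreme if the cut is exceeded.
Whether this stage should remove *records* or *attributes* is genuinely
ambiguous in the tradition this design follows; rows are the default
(`outlier_axis="rows"`), and a column mode — dropping features whose
encoded values have point-biserial |r| < 0.1 with the 2-cluster split — is
provided for the literal attribute reading. Neither is claimed as the
"intended" one.

## Pipeline

Default stage order: impute → normalize → subset selection → K-means
record filtering → 10-fold CV. The reverse selection/clustering order is
available via `order="cluster-first"`; the two orders answer slightly
different questions (filter on all attributes vs. on the selected ones) and
both are kept as configuration. The global seed is deterministically split
into per-stage seeds; reports echo the full config and seed, and re-running
from that echo reproduces the report exactly. Feature and row accounting is
conserved at every stage and recorded in the report.

## Synthetic data

The generator emulates small clinical tables: binary labels with
configurable balance; informative numeric features Normal(±δ/2, 1) by
class, so m of them give closed-form Bayes-optimal accuracy Φ(δ√m/2)
(balanced case; the implementation handles unbalanced priors analytically);
redundant features as affine copies of informative ones plus N(0, 0.05²)
jitter — detectable redundancy, not collinearity; noise features
class-independent; categorical features with 3 levels, class-biased via
Dirichlet-perturbed odds for informative ones; optional missing cells
(never a whole column); optional planted outlier rows at
`magnitude × data radius` along random directions. Column order is
shuffled; ground-truth indices, the Bayes rate, and planted-row indices are
returned. Everything is reproducible from the spec seed.

`compact_blobs` generates bounded clusters (uniform inside balls) for
outlier-filter fixtures. This choice is load-bearing: for a uniform-ball
cluster the maximum centroid distance is below mean + 3 SD, so the z-rule
has *zero* false positives on clean rows and exact planted-outlier recovery
is a well-posed check. With Gaussian clusters the same rule has an
irreducible ~0.1–0.5% per-row false-positive rate (chi-distributed
distances), so "exactly the planted rows" would fail occasionally no matter
how the filter is implemented — a property of the fixture distribution, not
of the filter.

What the synthetic experiments show: that selection recovers planted
conditional-mean structure, that the filter recovers planted extreme rows,
and that the pipeline's accuracy tracks analytic Gaussian Bayes rates. What
they do not show: performance on real clinical marginals (skewed,
heavy-tailed, bounded counts), correlated informative features, label
noise, or non-random missingness. Results on real cohorts should be
expected to be less clean than the planted-structure recoveries here.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run oracle-equivalence
comparisons at d = 8 (255 subsets) over 20 seeds, planted-feature recovery
at n = 500, d = 10 over 10 seeds with 20 relevance restarts each,
outlier recovery at n = 150 + 3 planted rows over 20 seeds, and statistical
sanity at n = 2000 (null) and n = 5000 (single strong feature). These sizes
give tight binomial intervals while keeping the whole battery around half a
minute on one CPU.

## Known limitations

- The wrapper fitness uses inner-CV accuracy; under heavy class imbalance a
  cost-sensitive or MCC-based fitness would be preferable (not implemented).
- Selection before outer CV, with full-table normalization, follows the
  sequential-pipeline convention and is mildly optimistic; the
  `refit_per_fold` flag mitigates normalization leakage but selection
  itself is still performed once on the full table.
- Binary labels only; no multi-class support.
- K-means with k fixed at 2 is a filtering device, not a model of the
  data's cluster structure; no automatic k selection is attempted.
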