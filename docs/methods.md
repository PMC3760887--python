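# Methods

## Model and procedure

The pipeline selects features for a binary outcome by smoothing per-feature
absolute t-statistics over an interaction network and testing the smoothed
scores by permutation.

1. **Kernel.** For a simple undirected graph with adjacency `A` and degree
   matrix `D`, the normalized Laplacian is `L̃ = D^(-1/2)(D − A)D^(-1/2)`,
   with the convention that rows/columns of isolated nodes are zero. The
   p-step random walk kernel is `K = (a·I − L̃)^p`, computed by repeated
   dense matrix multiplication and symmetrized against float round-off.
   Since the spectrum of `L̃` lies in `[0, 2]`, `a ≥ 2` guarantees positive
   semi-definiteness; `a < 2` is rejected with an error. `K` depends only on
   the graph and `(a, p)` — never on expression data — so it is computed
   once and reused across cross-validation folds and permutations.

2. **Smoothing.** Per feature, the pooled-variance two-sample t-statistic is
   computed on training data (constant features score 0 rather than NaN) and
   the absolute values are smoothed as `s = K|t|`. The implementation checks
   at run time that the smoothed scores are non-negative rather than
   assuming it. No row-normalization is applied by default: the raw product
   deliberately boosts well-connected nodes and nodes near hubs, which is
   the intended behavior of the score. A row-normalized variant (each kernel
   row scaled to sum 1, turning the score into a neighborhood average) is
   available behind a flag.

3. **Selection.** The top 10% of features by smoothed score are tested by a
   label-permutation test: in each of `n_perm` permutations (default 1000)
   the class labels are shuffled, `|t|` and `s` are recomputed for all
   nodes, and the p-value of feature g is the add-one estimator
   `(1 + #{b : s_g^(b) ≥ s_g^obs}) / (1 + n_perm)`, so p ≥ 1/(n_perm+1) and
   ties count against the observed score. Benjamini–Hochberg adjustment is
   applied over the tested features and the signature is `{g : q_g < 0.05}`.
   Permuting labels (rather than gene values) preserves the gene–gene
   correlation structure under the null; each feature is compared to its own
   permutation distribution, not a pooled one.

4. **Classifier.** Signature features are standardized to train-fold mean 0
   and sd 1 (population sd; zero-variance features map to 0) and a linear
   soft-margin SVM is trained. `C` is picked from a log-spaced grid
   {10⁻³…10³} by the span rule: support vector p is predicted to flip in
   leave-one-out iff `α_p S_p² ≥ y_p f(x_p)`, where for an unbounded support
   vector `S_p²` comes from the inverse of the extended Gram matrix
   `[[K_SV, 1],[1ᵀ, 0]]` (diagonal jittered by 1e-8; pseudo-inverse on
   singularity) and for a box-bounded one (`α = C`) the squared SV-set
   diameter is used as its classical upper bound. Ties in the estimate
   resolve to the smallest C.

5. **Evaluation.** 10×10-fold stratified cross-validation; every
   data-dependent quantity (t-statistics, permutation test, scaling, C, SVM)
   is derived from the training folds only, and fold assignments depend only
   on the labels and the seed, which is what the poisoning audit in the test
   suite verifies. AUC is computed per fold (Mann–Whitney, ties ½) and
   summarized by the median over the 100 folds. Stability index:
   `SI = mean_g∈S (c_g / c_max)` over ever-selected features, reported next
   to the raw counts so any alternative summary can be recomputed.

6. **Integration.** miRNA expression enters by extending the graph with
   miRNA→target edges (treated as undirected for smoothing; regulatory
   direction is not modeled) and the t-vector with miRNA statistics. The
   alternative meta-classifier route fits a logistic regression on two SVM
   ranking functions; in the cross-validated harness the combiner is fit on
   *out-of-fold* ranking scores from an inner CV of each training fold.
   Fitting it on in-sample scores lets an overfit channel look informative:
   with a pure-noise miRNA layer, in-sample stacking costs ~0.1 AUC on
   held-out folds while out-of-fold stacking tracks the gene-only classifier
   to within ~0.01.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `a` | 2.0 | kernel constant; 2 is the smallest PSD-guaranteeing value |
| `p` | 2 | walk steps; 2 reaches two-hop neighborhoods, matching the intended hub-proximity effect |
| `n_perm` | 1000 | permutations; p-value floor is 1/(n_perm+1) |
| `top_frac` | 0.10 | fraction of features given permutation p-values |
| `fdr` | 0.05 | BH threshold for the signature |
| C grid | 10⁻³…10³ | span-rule candidates, log-spaced |
| folds × repeats | 10 × 10 | stratified cross-validation |

If no feature passes the FDR cut, the top 10 features by smoothed score are
selected with a logged warning so the downstream SVM is always trainable
(capped at the size of the tested set, preserving signature ⊆ tested).

## Synthetic data

The generator emulates the structure the method assumes: a connected
scale-free gene graph (preferential attachment, m = 2, seeded from a
connected pair, so a 100-gene graph has 1 + 2·98 = 197 edges; an
Erdős–Rényi option exists), Gaussian expression with unit noise sd, a
*connected* module of genes (grown by seeded BFS) shifted by
`effect_size`·sd in the positive class, an optional bipartite miRNA layer in
which miRNAs targeting the module are shifted in the opposite direction
(repressive regulation), and class imbalance defaulting to 30% positives, in
line with relapse cohorts. Everything is reproducible from a config + seed.

What it does **not** emulate: microarray platform/probe effects, batch
structure, heavy-tailed or correlated background noise, survival-time
censoring beyond pre-dichotomized labels, and realistic degree-dependent
expression variance. Passing tests therefore show the pipeline's statistical
machinery behaves as designed under its own assumptions, not that the
particular AUCs transfer to real cohorts.

## Numerical and design choices

- Node order is lexicographic everywhere, making kernels and downstream
  tables bit-reproducible; ties at the top-fraction cutoff break by node id.
- Probesets mapped to one gene are averaged; probesets with no gene mapping
  are dropped with a logged count. Measured features missing from the
  network are kept as isolated nodes (kernel diagonal a^p), so they stay in
  the ranking; network nodes without expression are dropped along with their
  edges.
- Survival dichotomization: event within the cutoff → +1; event-free past
  the cutoff (or an event after it) → −1; event-free and censored before the
  cutoff → excluded, since such patients fit neither class.
- All randomness flows from a single integer seed through
  `numpy.random.default_rng`; identical seeds give byte-identical selection
  results and CV reports.
- Permutations are evaluated in one batch (a matrix of permuted t-vectors,
  one kernel multiplication) — algebraically identical to the
  per-permutation loop but orders of magnitude faster.
- Enrichment uses the upper-tail hypergeometric test with the universe
  defaulting to the features present on the analysis network (the population
  the signature is drawn from); Bonferroni by default, BH optional.

## Known limitations

- **Restrict-then-test selection bias.** The permutation test is calibrated
  marginally (on null data ~5% of *all* features get p < 0.05), but the
  procedure only tests the top 10% of features ranked by the same observed
  score being tested. Conditioning on a high observed rank enriches for
  small p-values: on null data ~27% of the *tested* subset falls below 0.05,
  and in ~15% of null datasets the FDR step selects a handful of correlated
  features. This is a property of the published restrict-then-test design,
  not of the implementation; testing all features removes it at a
  computational cost.
- The span rule is an estimate, not a bound certified per dataset: it can
  over-predict leave-one-out errors when the support-vector set changes on
  removal (e.g. very sparse support sets), and the box-bounded diameter
  surrogate is deliberately conservative at small C.
- Recovery gains from smoothing are most visible when single-gene effects
  are marginal; with strong per-gene effects both smoothed and unsmoothed
  selection saturate and differ by at most a gene or two.
- Dense kernel representation is used throughout; it is comfortable to
  ~10–20k nodes and is the practical ceiling of this implementation.
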