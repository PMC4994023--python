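# Methods

## Model

`drugmtl` fits T linear drug-response models jointly by minimizing

    L(W, b) = Σ_t Σ_{i ∈ obs(t)} (y_ti − w_tᵀ x_i − b_t)²  +  λ ‖W‖_*

over the coefficient matrix W ∈ ℝ^{P×T} (column t belongs to drug t) and
unpenalized intercepts b ∈ ℝ^T. `obs(t)` is the set of cell lines with an
observed response for drug t — the per-task mask is what distinguishes the
transductive setting (each drug hides its own entries while all feature
vectors remain in play) from the inductive one (whole cell lines are
hidden). The trace norm ‖W‖_* = Σ σ_i(W) is the tightest convex surrogate
for rank; shrinking it pulls the per-drug coefficient vectors into a common
low-dimensional subspace, which is how predictive signal flows between
drugs with related mechanisms.

The loss is the plain sum of squared residuals (no 1/2N factor); the
elastic-net baseline deliberately uses the glmnet scaling (1/2N) instead so
its α/λ grid semantics match the convention users of that family expect.
The two λ scales are never compared to each other directly — each learner
selects its own λ by cross-validation.

## ADMM solver

The objective splits as f(W, b) + λ‖Z‖_* subject to W = Z, with the
augmented Lagrangian parameterized by the (unscaled) dual Γ and penalty ρ.
Each iteration:

1. **(W, b)-update.** With v_t = z_t − γ_t/ρ, each task solves
   `min_w ‖yc − Xc w‖² + (ρ/2)‖w − v_t‖²` on its centered design
   (centering is the exact profile of the unpenalized intercept). The
   closed form `(2 XcᵀXc + ρI)⁻¹ (2 Xcᵀyc + ρ v_t)` is applied through a
   thin SVD of Xc cached once per fit (the designs never change across
   iterations), so the per-iteration cost is O(T · P · r) after the
   one-time factorizations.
2. **Z-update.** Singular-value soft-thresholding of W + Γ/ρ at threshold
   λ/ρ — the proximal operator of the trace norm.
3. **Dual ascent.** Γ ← Γ + ρ (W − Z).

Stopping uses the joint primal/dual residual criterion
(r = ‖W − Z‖_F, s = ρ‖Z_k − Z_{k−1}‖_F) with tol_abs = 1e-4,
tol_rel = 1e-3, and max_iter = 2000. ρ defaults to 1.0 and stays fixed;
`adapt_rho=True` enables the standard residual-balancing heuristic (double
or halve when one residual exceeds the other tenfold, checked every 10
iterations; the unscaled dual needs no rescaling). Warm starts dominate ρ
sensitivity in practice, so adaptation is off by default and used where
whole λ paths are fitted repeatedly (cross-validation, ablations).

Reported coefficients are taken from the Z block, which is exactly low
rank at the shrinkage threshold; intercepts are recomputed against Z so
the exported (W, b) pair is internally consistent. The model's `rank`
field counts singular values above 1e-8 · σ_max.

Two exact special cases bypass the iteration: λ = 0 is solved by per-task
minimum-norm least squares (ADMM at λ = 0 degenerates to a slow fixed-point
iteration toward the same solution), and λ ≥ λ_max returns W = 0 with
b_t = mean(y_t). λ_max is computed as the spectral norm of the loss
gradient at W = 0 — the matrix whose column t is 2 X^(t)ᵀ(y_t − ȳ_t) —
which is the exact boundary of the all-zero solution by the subgradient
condition. Trace-norm paths use 50 geometric points in
[0.01 λ_max, λ_max] by default; evaluation code scales this down.

**Feature standardization** (default on) maps columns to zero mean / unit
variance over the union of training rows before fitting and
back-transforms coefficients for reporting. The trace norm is not
invariant to per-feature rescaling, and pharmacogenomic designs mix
expression-scale continuous columns with {0,1} mutation indicators, so
unstandardized fits would let high-variance blocks dominate the shared
subspace. The flag is recorded in model exports. Standardization consults
only X and the mask — never response values — so masked entries still have
provably zero influence on the fit (asserted bit-for-bit in the tests).

## Baselines

**Elastic net** (per task): glmnet objective
(1/2N)‖y − Xw − b‖² + λ(α‖w‖₁ + (1−α)/2 ‖w‖₂²), solved by scikit-learn's
coordinate descent on standardized, centered data (ridge closed form at
α = 0). Selection is two-stage: α over the uniform 11-point grid
{0, 0.1, …, 1} with λ free along its path (5-fold CV, shared fold split
across the α grid so the comparison is paired), then λ re-optimized at the
chosen α over 100 geometric values in [0.01 λ_max, λ_max] with ties broken
toward larger λ. λ_max follows the glmnet formula
max_l |x_lᵀ(y − ȳ)|/(N α); the α = 0 grid is built from an α = 0.001
surrogate since ridge has no finite sparsity point.

**Nearest drug response neighbor**: a feature-free control for the
transductive setting. For target drug d at cell c, the neighbor is the
drug observed at c whose training responses are most Pearson-correlated
with d over jointly observed cells (minimum overlap 3; ties break to the
lowest drug index), and the prediction is the univariate regression of d
on that neighbor evaluated at the neighbor's response for c. When no
candidate qualifies the prediction falls back to d's training mean.

## Cross-validation and comparison

Nested K-fold (K = 5 by default). Split plans are built per task over
observed entries — a single row partition shared by all tasks in inductive
mode, independent per-task partitions in transductive mode (the holdouts of
different drugs are not coordinated) — and serialized to JSON so competing
learners score identical test sets. Within each outer fold,
hyperparameters are selected by an inner CV run on outer-training entries
only: a single λ jointly for all tasks for trace norm (pooled inner MSE
across tasks, warm-started paths, ties toward larger λ), and per-task
(α, λ) for elastic net with α pre-selected on the outer-training entries.
An explicit guard errors out if any inner training mask touches an outer
test entry.

Paired comparisons use the one-sided Wilcoxon signed-rank test on per-task
mean MSE differences — exact null distribution for T ≤ 25 without ties,
normal approximation with continuity correction otherwise; identical
inputs report p = 0.5 by symmetry. The summary also reports win/loss/tie
counts and the mean percent MSE reduction Σ_t (MSE_B − MSE_A)/MSE_B / T.

The task-number ablation permutes tasks once per seed, chunks them into
consecutive groups of each requested size (a smaller remainder group is
allowed), and runs the transductive trace-norm CV per group under a plan
shared across group sizes, so every task is scored exactly once per size.

## Label-noise test

Per drug: 200 replicates (default) of a random 80/20 split fit on true
labels, 1000 on permuted labels (more, because that arm is noisier), each
recording held-out MSE; one-sided Wilcoxon rank-sum asks whether the
true-label MSE distribution is stochastically smaller; pass at p < 0.01.
"Repeated with replacement" is read as independent redraws of the split
each replicate (cells recur across test sets), not bootstrap resampling of
rows within a replicate — the two readings are statistically similar and
the alternative is noted here for transparency. To keep 1200 fits cheap,
the elastic net inside the test uses a fixed fast configuration: α chosen
once on the full data (or passed explicitly) and λ per replicate from a
short geometric path scored on a single validation split of the training
part. The cohort summary reports pass counts, a cumulative pass curve over
thresholds, and the Pearson correlation between each drug's response IQR
(dynamic range) and −log10(p), whose positive sign is the expected
signature of range-limited screens.

## Interpretation

Drug models (columns of W) are clustered with Ward's minimum-variance
linkage on Euclidean distances (scipy's `ward`, the hclust ward.D2
topology — equivalently the Lance–Williams recursion on squared
distances; the dialect is recorded in output metadata). Flat cuts use
`fcluster(maxclust)`. Agreement with mechanism-of-action annotations is
scored by the adjusted Rand index (permutation-model, contingency-table
form); unannotated drugs shape the tree but are excluded from the ARI.

Enrichment takes a drug's top-100 features by |weight| (the convention for
dense low-rank models; a `positive` mode ranks by signed weight and falls
back to all positive features when a sparse model has fewer than 100) and
tests each user-supplied gene set with the upper-tail hypergeometric
P(X ≥ k) against the background of the model's feature universe
intersected with the GMT. P-values are raw — flat tests, no ontology
conditioning, no multiplicity correction — matching how such heatmaps are
usually drawn; callers can correct downstream.

## Synthetic cohorts

The generator emulates the shape, not the biology, of a pharmacogenomic
screen: continuous features are i.i.d. standard normal; a configurable
fraction (default 20%) of columns are Bernoulli(0.1) mutation indicators;
W_true = UVᵀ has exact rank r with Gaussian factors, rescaled so the mean
per-task signal variance is ≈ 1; responses add N(0, noise_sd²) noise
(default noise_sd = 0.5, signal-to-noise 4:1 in variance — a clearly
learnable but non-trivial regime); intercepts are standard normal. Group
mode ties V rows within mechanism groups (jitter 0.1) to give a
ground-truth partition for ARI checks; a `frac_noisy_tasks` fraction of
response columns is independently permuted to emulate uninformative drug
profiles. Holdout masks reproduce both CV geometries.

What this does **not** emulate: the correlation structure within and
between expression/copy-number blocks, heavy-tailed and bounded response
metrics (activity area ∈ [0,8], AUC ∈ [0,16], −log10 GI50), batch
structure, or missingness that correlates with response. Passing tests
therefore establish algorithmic correctness and the direction of the
method's comparative advantages under its own assumptions, not effect
sizes on real screens.

## Problem sizes used in tests and the acceptance script

Synthetic experiments run at desk scale, chosen as the smallest cohorts
where the phenomena are stable across seeds: solver-vs-reference checks on
20 random instances with N ≤ 50, P ≤ 30, T ≤ 8; the transductive
benchmark at N = 80, P = 50, T = 20, rank 2, one 20% transductive holdout
per seed with λ by 3-fold inner CV (10-point path) and the full 11-point α
grid with a 30-point λ path for elastic net; the task-number ablation at
T = 32, N = 60, P = 40 comparing groups of 32 vs 2; noise-test calibration
at 25/50 replicates over 50 null runs; the mechanism-group ARI comparison
at T = 24 in 6 groups with 25% noisy tasks. Full-scale defaults (50-point
trace-norm path, 100-point elastic-net path, 200/1000 noise replicates,
5-fold everywhere) remain the library defaults.

## Numerical notes and limitations

* The W-update's cached SVD drops singular values below σ_max · 1e-12;
  ρ > 0 keeps the augmented system nonsingular regardless.
* `svd_shrink` rejects non-finite inputs; thresholded singular values are
  clipped at exactly zero, so reported models are exactly low rank.
* Ties in all grid selections resolve toward more regularization; all
  randomness flows through explicit integer seeds (numpy Generator), and
  repeated runs are bit-identical.
* The rank-along-path monotonicity is a statistical property (asserted on
  seed-averaged means); individual instances can locally violate it near
  shrinkage thresholds.
* ADMM convergence is declared by residual tolerances; `converged=False`
  results are still returned (with a warning) and carry the best iterate.
* The nearest-drug predictor is undefined for T < 2 and falls back to the
  training mean when pairwise overlaps are below 3 cells; both behaviours
  are part of its contract, not error states.
* Single-CPU throughput is adequate for thousands of features; there is no
  GPU path, no stochastic variant, and no kernelization — by design, since
  the point of the primal linear model is interpretability of W.
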