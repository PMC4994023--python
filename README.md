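# drugmtl

Multitask prediction of cancer drug sensitivity from cell-line molecular
profiles, using trace-norm (nuclear-norm) regularized linear regression
solved by ADMM.

## The problem

Pharmacogenomic screens measure the response of hundreds of cancer cell
lines to panels of drugs, alongside expression, copy-number, and mutation
profiles. The standard approach fits an independent elastic-net regression
per drug, but single-task models are starved for training examples, fragile
to label noise, and hard to interpret because many different sparse models
predict equally well. Drugs are not independent: compounds sharing a target
or mechanism of action elicit correlated response profiles, so learning all
drug models *jointly* lets each task borrow strength from the others.

## The model

Given a feature matrix **X** ∈ ℝ^{N×P} (cell lines × molecular features)
and a response matrix **Y** ∈ ℝ^{N×T} (cell lines × drugs, possibly with
missing entries), we learn a coefficient matrix **W** = (w₁ … w_T) ∈ ℝ^{P×T}
and intercepts b ∈ ℝ^T minimizing

```
Σ_t Σ_{i ∈ obs(t)} (y_ti − w_tᵀ x_i − b_t)²  +  λ ‖W‖_*
```

where ‖W‖_* is the trace norm (sum of singular values). Penalizing the
trace norm drives the task coefficient vectors into a shared low-dimensional
subspace — the convex surrogate for "drug models have low rank" — which is
where the cross-task sharing comes from.

The solver is ADMM on the split `f(W, b) + λ‖Z‖_*` subject to `W = Z`:
the (W, b) step decomposes into T independent ridge-augmented regressions
(each solved in closed form from a cached thin SVD of its design), the Z
step is singular-value soft-thresholding, and the dual step is gradient
ascent. Warm starts along a decreasing λ path make whole-path fits cheap.

Two evaluation geometries are supported:

* **inductive** — the same cell lines are held out across all drugs; models
  are scored on fully unseen samples;
* **transductive** — each drug holds out its own 20% of responses while
  every feature vector stays visible; prediction becomes response-matrix
  completion, the setting where multitask sharing pays off most.

The package also ships the single-task elastic-net baseline (glmnet
parameterization, 11-point α grid, 100-point λ path in [0.01 λ_max, λ_max]),
a feature-free nearest-drug-response control, a permutation label-noise test
per drug (true-label vs permuted-label MSE distributions, one-sided Wilcoxon
rank-sum), weight-matrix interpretation (Ward clustering of drug models,
adjusted Rand index against mechanism-of-action labels, hypergeometric
gene-set enrichment of top-weighted features), and a synthetic low-rank
cohort generator so every pipeline stage is testable offline.

## Worked example

```python
import numpy as np
from drugmtl import (SyntheticSpec, generate, holdout_mask,
                     fit_trace_norm, lambda_max_trace_norm)

spec = SyntheticSpec(n_cells=100, n_features=50, n_tasks=20, rank=2,
                     noise_sd=0.5, seed=0)
fm, rm, truth = generate(spec)                    # X: 100x50, Y: 100x20
held = holdout_mask(rm, 0.2, "transductive", seed=0)

lam = 0.1 * lambda_max_trace_norm(fm.values, rm.values, held.mask)
model = fit_trace_norm(fm.values, rm.values, lam, mask=held.mask)

test = rm.mask & ~held.mask
mse = np.mean((model.predict(fm.values)[test] - rm.values[test]) ** 2)
print(f"rank(W) = {model.rank}, held-out MSE = {mse:.3f}")
```

prints

```
rank(W) = 9, held-out MSE = 0.311
```

The fitted coefficient matrix is numerically low-rank (9 of a possible 20
directions survive the shrinkage; the planted structure has rank 2 and the
trailing fitted singular values are tiny) and the held-out MSE sits near
the injected noise floor (noise_sd² = 0.25), far below the ≈1.7 variance
of the responses themselves.

The same pipeline is scriptable from the shell:

```bash
drugmtl simulate  --config config.yaml   # write a synthetic cohort as TSV
drugmtl fit       --config config.yaml   # CV-selected lambda, exports W, b
drugmtl benchmark --config config.yaml   # trace norm vs elastic net, shared splits
drugmtl noise     --config config.yaml   # per-drug permutation noise test
drugmtl interpret --config config.yaml   # cluster W, ARI vs annotation, GMT enrichment
```

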