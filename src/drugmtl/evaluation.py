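"""Cross-validation machinery: inductive/transductive splits, nested CV,
paired model comparison, and the task-number ablation.

Two holdout geometries matter for multitask response prediction:

* inductive — the same cell lines (feature vectors and all their labels) are
  held out across every drug, so the model is scored on fully unseen samples;
* transductive — each drug holds out its own 20% of observed responses while
  every feature vector stays visible to the learner, which turns evaluation
  into response-matrix completion.

Hyperparameters are always selected by an inner cross-validation run on the
outer-training entries only; outer test entries never touch model selection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .baselines import (
    ElasticNetConfig,
    default_lambda_grid,
    fit_elastic_net,
    fit_elastic_net_path,
    select_alpha_lambda,
)
from .data import FeatureMatrix, ResponseMatrix
from .solver import fit_path, fit_trace_norm, lambda_grid, lambda_max_trace_norm

__all__ = [
    "SplitPlan",
    "CVResult",
    "ComparisonReport",
    "make_split_plan",
    "nested_cv",
    "compare_paired",
    "task_group_ablation",
]


@dataclass
class SplitPlan:
    """Per-task K-fold partition of the observed response entries.

    ``folds[t]`` is a list of K (train_rows, test_rows) index pairs for task
    t.  In inductive mode the test rows of a fold are shared by every task
    (intersected with each task's observed set); in transductive mode each
    task partitions its observed entries independently.
    """

    mode: str
    k: int
    seed: int
    folds: list[list[tuple[np.ndarray, np.ndarray]]] = field(default_factory=list)

    @property
    def n_tasks(self) -> int:
        return len(self.folds)

    def restrict(self, tasks) -> "SplitPlan":
        return SplitPlan(self.mode, self.k, self.seed, [self.folds[t] for t in tasks])

    def take_folds(self, fold_indices) -> "SplitPlan":
        """Keep only the given folds (e.g. a single 20% holdout from a k=5 plan)."""
        fold_indices = list(fold_indices)
        return SplitPlan(
            self.mode,
            len(fold_indices),
            self.seed,
            [[task[j] for j in fold_indices] for task in self.folds],
        )

    def to_json(self, path) -> None:
        payload = {
            "mode": self.mode,
            "k": self.k,
            "seed": self.seed,
            "folds": [
                [[tr.tolist(), te.tolist()] for tr, te in task] for task in self.folds
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "SplitPlan":
        with open(path) as fh:
            payload = json.load(fh)
        folds = [
            [(np.asarray(tr, int), np.asarray(te, int)) for tr, te in task]
            for task in payload["folds"]
        ]
        return cls(payload["mode"], payload["k"], payload["seed"], folds)


@dataclass
class CVResult:
    """Per-task, per-fold test MSE with the hyperparameters selected per fold."""

    learner: str
    fold_mse: np.ndarray  # T x K
    selected: list[list[dict]]  # [task][fold] -> params
    drug_ids: list[str] | None = None

    @property
    def mean_mse(self) -> np.ndarray:
        return np.nanmean(self.fold_mse, axis=1)

    def to_frame(self) -> pd.DataFrame:
        idx = self.drug_ids or [f"task{t}" for t in range(self.fold_mse.shape[0])]
        df = pd.DataFrame(
            self.fold_mse, index=idx, columns=[f"fold{j}" for j in range(self.fold_mse.shape[1])]
        )
        df["mean_mse"] = self.mean_mse
        return df


@dataclass
class ComparisonReport:
    """Paired per-task comparison of two CV results (A vs B, one-sided A < B)."""

    delta_mse: np.ndarray  # per task, A - B
    wins: int
    losses: int
    ties: int
    p_value: float
    percent_reduction: float
    drug_ids: list[str] | None = None

    def to_frame(self) -> pd.DataFrame:
        idx = self.drug_ids or [f"task{t}" for t in range(len(self.delta_mse))]
        return pd.DataFrame({"delta_mse": self.delta_mse}, index=idx)


def _mask_of(rm) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(rm, ResponseMatrix):
        return rm.values, rm.mask
    rm = np.asarray(rm, dtype=float)
    return rm, np.isfinite(rm)


def make_split_plan(rm, mode: str, k: int = 5, seed: int = 0) -> SplitPlan:
    """Build a deterministic K-fold plan over observed response entries."""
    if mode not in ("inductive", "transductive"):
        raise ValueError(f"unknown mode {mode!r}")
    values, mask = _mask_of(rm)
    n, T = values.shape
    counts = mask.sum(axis=0)
    drug_ids = rm.drug_ids if isinstance(rm, ResponseMatrix) else None
    for t in range(T):
        if counts[t] < k:
            name = drug_ids[t] if drug_ids else str(t)
            raise ValueError(
                f"task {name!r} has only {counts[t]} observed entries; needs >= k={k}"
            )
    rng = np.random.default_rng(seed)
    folds: list[list[tuple[np.ndarray, np.ndarray]]] = []
    if mode == "inductive":
        perm = rng.permutation(n)
        row_folds = np.array_split(perm, k)
        for t in range(T):
            obs = mask[:, t]
            task = []
            for j in range(k):
                te = np.sort(np.asarray([i for i in row_folds[j] if obs[i]], int))
                tr = np.sort(
                    np.concatenate(
                        [[i for i in row_folds[m] if obs[i]] for m in range(k) if m != j]
                    ).astype(int)
                )
                task.append((tr, te))
            folds.append(task)
    else:
        for t in range(T):
            obs = np.flatnonzero(mask[:, t])
            perm = rng.permutation(obs)
            parts = np.array_split(perm, k)
            task = []
            for j in range(k):
                te = np.sort(parts[j])
                tr = np.sort(np.concatenate([parts[m] for m in range(k) if m != j]))
                task.append((tr.astype(int), te.astype(int)))
            folds.append(task)
    return SplitPlan(mode, k, seed, folds)


def _train_mask_for_fold(plan: SplitPlan, base_mask: np.ndarray, j: int) -> np.ndarray:
    train = np.zeros(base_mask.shape, bool)
    for t in range(base_mask.shape[1]):
        tr, _ = plan.folds[t][j]
        train[tr, t] = True
    if not (train <= base_mask).all():
        raise RuntimeError("split plan references unobserved entries")
    return train


def _select_lambda_trace_norm(
    X, Y, train_mask, mode, inner_k, seed, n_lambda, lambda_min_ratio, **fit_kw
):
    inner_plan = make_split_plan(
        np.where(train_mask, Y, np.nan), mode, k=inner_k, seed=seed
    )
    lam_max = lambda_max_trace_norm(X, Y, train_mask, fit_kw.get("standardize", True))
    grid = lambda_grid(lam_max, n=n_lambda, ratio=lambda_min_ratio)
    se = np.zeros(len(grid))
    n_val = 0
    for j in range(inner_k):
        inner_train = _train_mask_for_fold(inner_plan, train_mask, j)
        if not (inner_train <= train_mask).all():  # leakage guard
            raise RuntimeError("inner-CV training mask leaks outer test entries")
        models = fit_path(X, Y, grid, mask=inner_train, **fit_kw)
        for t in range(Y.shape[1]):
            _, va = inner_plan.folds[t][j]
            if va.size == 0:
                continue
            for i, m in enumerate(models):
                pred = X[va] @ m.W[:, t] + m.b[t]
                se[i] += float(np.sum((pred - Y[va, t]) ** 2))
        n_val += sum(inner_plan.folds[t][j][1].size for t in range(Y.shape[1]))
    mse = se / max(n_val, 1)
    return float(grid[int(np.argmin(mse))])  # decreasing grid: ties -> larger lambda


def nested_cv(
    X,
    Y,
    plan: SplitPlan,
    learner: str,
    inner_k: int = 5,
    enet_config: ElasticNetConfig | None = None,
    n_lambda: int = 50,
    lambda_min_ratio: float = 0.01,
    alpha_folds: int = 5,
    **fit_kw,
) -> CVResult:
    """Nested cross-validation under a shared split plan.

    ``learner`` is one of ``trace_norm`` (single lambda selected jointly for
    all tasks by inner CV), ``elastic_net`` (per-task alpha pre-selected on
    outer-training entries, then lambda by inner CV), ``nearest_drug`` (the
    feature-free response-neighbor control), or ``mean`` (predicts the
    per-task training mean; selection-free control).
    """
    if isinstance(X, FeatureMatrix):
        X = X.values
    X = np.asarray(X, dtype=float)
    values, base_mask = _mask_of(Y)
    drug_ids = Y.drug_ids if isinstance(Y, ResponseMatrix) else None
    T, K = values.shape[1], plan.k
    if plan.n_tasks != T:
        raise ValueError("plan task count does not match response matrix")
    fold_mse = np.zeros((T, K))
    selected: list[list[dict]] = [[{} for _ in range(K)] for _ in range(T)]
    enet_config = enet_config or ElasticNetConfig()

    for j in range(K):
        train_mask = _train_mask_for_fold(plan, base_mask, j)
        if learner == "trace_norm":
            lam = _select_lambda_trace_norm(
                X, values, train_mask, plan.mode, inner_k,
                plan.seed * 1000 + j + 1, n_lambda, lambda_min_ratio, **fit_kw,
            )
            model = fit_trace_norm(X, values, lam, mask=train_mask, **fit_kw)
            for t in range(T):
                _, te = plan.folds[t][j]
                if te.size == 0:
                    fold_mse[t, j] = np.nan
                    continue
                pred = X[te] @ model.W[:, t] + model.b[t]
                fold_mse[t, j] = float(np.mean((pred - values[te, t]) ** 2))
                selected[t][j] = {"lambda": lam}
        elif learner == "elastic_net":
            for t in range(T):
                tr, te = plan.folds[t][j]
                if te.size == 0:
                    fold_mse[t, j] = np.nan
                    continue
                Xt, yt = X[tr], values[tr, t]
                alpha, _ = select_alpha_lambda(
                    Xt, yt, enet_config, folds=alpha_folds, seed=plan.seed * 1000 + j + 1
                )
                lam = _select_lambda_enet(
                    Xt, yt, alpha, enet_config, inner_k, plan.seed * 1000 + j + 1
                )
                m = fit_elastic_net(Xt, yt, alpha, lam, enet_config.standardize)
                pred = m.predict(X[te])
                fold_mse[t, j] = float(np.mean((pred - values[te, t]) ** 2))
                selected[t][j] = {"alpha": alpha, "lambda": lam}
        elif learner == "mean":
            for t in range(T):
                tr, te = plan.folds[t][j]
                mu = values[tr, t].mean()
                fold_mse[t, j] = float(np.mean((values[te, t] - mu) ** 2))
        elif learner == "nearest_drug":
            from .baselines import nearest_drug_predict

            for t in range(T):
                _, te = plan.folds[t][j]
                if te.size == 0:
                    fold_mse[t, j] = np.nan
                    continue
                pred = nearest_drug_predict(values, t, te, mask=train_mask)
                fold_mse[t, j] = float(np.mean((pred - values[te, t]) ** 2))
        else:
            raise ValueError(f"unknown learner {learner!r}")
    return CVResult(learner, fold_mse, selected, drug_ids)


def _select_lambda_enet(Xt, yt, alpha, config, inner_k, seed) -> float:
    from .baselines import _cv_mse_per_lambda

    grid = default_lambda_grid(Xt, yt, alpha, config)
    mse = _cv_mse_per_lambda(Xt, yt, alpha, grid, inner_k, seed, config.standardize)
    return float(grid[int(np.argmin(mse))])


def compare_paired(a: CVResult, b: CVResult, alternative: str = "less") -> ComparisonReport:
    """One-sided Wilcoxon signed-rank comparison of per-task mean MSE (A vs B).

    Exact null distribution for T <= 25, normal approximation with
    continuity correction above.  Identical results give p = 0.5 (no
    evidence in either direction).
    """
    if a.fold_mse.shape != b.fold_mse.shape:
        raise ValueError("CV results cover different tasks or folds")
    if a.drug_ids and b.drug_ids and a.drug_ids != b.drug_ids:
        raise ValueError("CV results cover different drugs")
    ma, mb = a.mean_mse, b.mean_mse
    d = ma - mb
    wins = int(np.sum(d < 0))
    losses = int(np.sum(d > 0))
    ties = int(np.sum(d == 0))
    if np.all(d == 0):
        p = 0.5
    else:
        method = "exact" if len(d) <= 25 and ties == 0 else "approx"
        try:
            p = float(
                stats.wilcoxon(d, alternative=alternative, method=method,
                               correction=(method == "approx")).pvalue
            )
        except ValueError:
            p = float(stats.wilcoxon(d, alternative=alternative, method="approx",
                                     correction=True, zero_method="zsplit").pvalue)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = float(np.mean((mb - ma) / mb) * 100.0)
    return ComparisonReport(d, wins, losses, ties, p, pct, a.drug_ids or b.drug_ids)


def task_group_ablation(
    X,
    Y,
    group_sizes,
    seed: int = 0,
    k: int = 5,
    inner_k: int = 3,
    n_lambda: int = 10,
    **fit_kw,
) -> pd.DataFrame:
    """Transductive trace-norm CV error as a function of tasks-per-model.

    Tasks are randomly permuted once, then chunked into consecutive groups of
    the requested size (a smaller remainder group is allowed); a separate
    multitask model is trained per group under a split plan shared across all
    group sizes, so every task is scored exactly once per size.
    """
    values, mask = _mask_of(Y)
    T = values.shape[1]
    plan = make_split_plan(Y, "transductive", k=k, seed=seed)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(T)
    rows = []
    for size in group_sizes:
        if size < 1:
            raise ValueError("group size must be >= 1")
        for start in range(0, T, size):
            tasks = np.sort(perm[start : start + size])
            res = nested_cv(
                X,
                values[:, tasks] if not isinstance(Y, ResponseMatrix) else _subset(Y, tasks),
                plan.restrict(tasks),
                "trace_norm",
                inner_k=inner_k,
                n_lambda=n_lambda,
                **fit_kw,
            )
            for local, t in enumerate(tasks):
                rows.append(
                    {"group_size": size, "task": int(t), "mse": float(res.mean_mse[local])}
                )
    return pd.DataFrame(rows)


def _subset(rm: ResponseMatrix, tasks) -> ResponseMatrix:
    return ResponseMatrix(
        rm.values[:, tasks],
        rm.mask[:, tasks],
        list(rm.cell_line_ids),
        [rm.drug_ids[t] for t in tasks],
    )
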