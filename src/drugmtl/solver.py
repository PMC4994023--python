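"""Trace-norm-regularized multitask least squares solved by ADMM.

The model couples T linear regression tasks (drugs) through a nuclear-norm
penalty on the stacked coefficient matrix W = (w_1 ... w_T) in R^{P x T}:

    minimize_{W, b}  sum_t sum_{i in obs(t)} (y_ti - w_t' x_i - b_t)^2
                     + lambda * ||W||_*

where obs(t) is the set of cell lines with an observed response for drug t
and ||W||_* is the sum of singular values of W.  Penalizing the trace norm
drives the task coefficient vectors into a shared low-dimensional subspace,
which is how information moves between drugs with related mechanisms.

ADMM splits the problem as f(W, b) + lambda*||Z||_* subject to W = Z, with
intercepts unpenalized and kept in the smooth block.  Each iteration:

  1. W-update: T independent ridge-augmented regressions (closed form via a
     cached thin SVD of each task's centered design matrix);
  2. Z-update: singular-value soft-thresholding of W + Gamma/rho at
     threshold lambda/rho (the proximal operator of the trace norm);
  3. dual ascent: Gamma <- Gamma + rho * (W - Z).

Warm starts across a decreasing lambda path make the per-lambda cost small;
the cached task factorizations are reused for the whole path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import FeatureMatrix, ResponseMatrix

__all__ = [
    "MultitaskModel",
    "ADMMState",
    "TaskDesign",
    "svd_shrink",
    "w_update",
    "z_update",
    "dual_update",
    "objective",
    "lambda_max_trace_norm",
    "lambda_grid",
    "fit_trace_norm",
    "fit_path",
]


@dataclass
class MultitaskModel:
    """Fitted multitask linear model: coefficients W (P x T), intercepts b (T)."""

    W: np.ndarray
    b: np.ndarray
    lam: float
    converged: bool = True
    n_iter: int = 0
    rank: int = field(init=False, default=0)

    def __post_init__(self) -> None:
        if not (np.isfinite(self.W).all() and np.isfinite(self.b).all()):
            raise ValueError("model contains non-finite coefficients")
        s = np.linalg.svd(self.W, compute_uv=False)
        smax = s[0] if s.size else 0.0
        self.rank = int(np.sum(s > 1e-8 * max(smax, 1e-300)))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X) @ self.W + self.b


@dataclass
class ADMMState:
    """Iterates of the split problem for one lambda (in fit coordinates)."""

    W: np.ndarray
    b: np.ndarray
    Z: np.ndarray
    Gamma: np.ndarray
    rho: float
    primal_residual: float = np.inf
    dual_residual: float = np.inf


class TaskDesign:
    """Per-task training design with a cached thin SVD of the centered X^(t).

    The W-update solves, for each task t with v_t = z_t - gamma_t / rho,

        argmin_w ||yc - Xc w||^2 + (rho/2) ||w - v_t||^2

    whose solution is (2 Xc'Xc + rho I)^{-1} (2 Xc'yc + rho v_t).  With the
    thin SVD Xc = U S V' the inverse applies in O(P * r) per task per
    iteration after a one-time factorization.
    """

    def __init__(self, X_t: np.ndarray, y_t: np.ndarray, rows: np.ndarray):
        if X_t.shape[0] == 0:
            raise ValueError("task has no observed training rows")
        self.rows = rows
        self.x_mean = X_t.mean(axis=0)
        self.y_mean = float(y_t.mean())
        self.Xc = X_t - self.x_mean
        self.yc = y_t - self.y_mean
        U, s, Vt = np.linalg.svd(self.Xc, full_matrices=False)
        keep = s > s[0] * 1e-12 if s.size and s[0] > 0 else np.zeros(s.shape, bool)
        self.V = Vt[keep].T  # P x r
        self.s2 = s[keep] ** 2
        self.Xty = self.Xc.T @ self.yc  # P

    def solve(self, v: np.ndarray, rho: float) -> tuple[np.ndarray, float]:
        c = 2.0 * self.Xty + rho * v
        Vtc = self.V.T @ c
        w = c / rho + self.V @ ((1.0 / (2.0 * self.s2 + rho) - 1.0 / rho) * Vtc)
        b = self.y_mean - float(w @ self.x_mean)
        return w, b

    def ols(self) -> tuple[np.ndarray, float]:
        """Minimum-norm per-task least squares (exact lambda = 0 solution)."""
        w, *_ = np.linalg.lstsq(self.Xc, self.yc, rcond=None)
        return w, self.y_mean - float(w @ self.x_mean)


def _coerce(X, Y, mask):
    if isinstance(X, FeatureMatrix):
        X = X.values
    if isinstance(Y, ResponseMatrix):
        if mask is None:
            mask = Y.mask
        Y = Y.values
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if mask is None:
        mask = np.ones(Y.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if X.shape[0] != Y.shape[0] or mask.shape != Y.shape:
        raise ValueError("X, Y and mask shapes are inconsistent")
    return X, Y, mask


def build_designs(X, Y, mask) -> list[TaskDesign]:
    X, Y, mask = _coerce(X, Y, mask)
    designs = []
    for t in range(Y.shape[1]):
        rows = np.flatnonzero(mask[:, t])
        if rows.size == 0:
            raise ValueError(f"task {t} has no observed training entries")
        designs.append(TaskDesign(X[rows], Y[rows, t], rows))
    return designs


def svd_shrink(M: np.ndarray, tau: float) -> np.ndarray:
    """Proximal operator of the trace norm: shrink singular values by tau, clip at 0."""
    M = np.asarray(M, dtype=float)
    if not np.isfinite(M).all():
        raise ValueError("svd_shrink: non-finite input")
    if tau < 0:
        raise ValueError("svd_shrink: tau must be nonnegative")
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    s = np.maximum(s - tau, 0.0)
    return (U * s) @ Vt


def w_update(state: ADMMState, designs: list[TaskDesign]) -> tuple[np.ndarray, np.ndarray]:
    """Exact per-task minimization of the augmented Lagrangian in (W, b)."""
    P = state.Z.shape[0]
    W = np.empty((P, len(designs)))
    b = np.empty(len(designs))
    V = state.Z - state.Gamma / state.rho
    for t, d in enumerate(designs):
        W[:, t], b[t] = d.solve(V[:, t], state.rho)
    return W, b


def z_update(state: ADMMState, lam: float) -> np.ndarray:
    return svd_shrink(state.W + state.Gamma / state.rho, lam / state.rho)


def dual_update(state: ADMMState) -> np.ndarray:
    return state.Gamma + state.rho * (state.W - state.Z)


def objective(X, Y, W, b, lam: float, mask=None) -> float:
    """Full trace-norm objective: summed squared loss over observed entries + lam*||W||_*."""
    X, Y, mask = _coerce(X, Y, mask)
    resid = (X @ W + b - np.where(mask, Y, 0.0)) * mask
    loss = float(np.sum(resid**2))
    return loss + lam * float(np.sum(np.linalg.svd(W, compute_uv=False)))


def _standardizer(X, mask):
    rows = np.flatnonzero(mask.any(axis=1))
    mu = X[rows].mean(axis=0)
    sd = X[rows].std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mu, sd


def lambda_max_trace_norm(X, Y, mask=None, standardize: bool = True) -> float:
    """Smallest lambda at which the trace-norm solution is exactly W = 0.

    At W = 0 the optimal intercepts are the per-task training means, and zero
    is a minimizer iff the spectral norm of the loss gradient is <= lambda.
    Column t of that gradient matrix is 2 * X^(t)' (y_t - mean(y_t)).
    """
    X, Y, mask = _coerce(X, Y, mask)
    if standardize:
        mu, sd = _standardizer(X, mask)
        X = (X - mu) / sd
    G = np.zeros((X.shape[1], Y.shape[1]))
    for t in range(Y.shape[1]):
        rows = np.flatnonzero(mask[:, t])
        yc = Y[rows, t] - Y[rows, t].mean()
        G[:, t] = 2.0 * X[rows].T @ yc
    return float(np.linalg.svd(G, compute_uv=False)[0])


def lambda_grid(lam_max: float, n: int = 50, ratio: float = 0.01) -> np.ndarray:
    """Geometric path of n values from lam_max down to ratio * lam_max."""
    if lam_max <= 0:
        raise ValueError("lambda_max must be positive")
    return np.geomspace(lam_max, ratio * lam_max, n)


def _fit_admm(
    designs: list[TaskDesign],
    P: int,
    lam: float,
    rho: float,
    tol_abs: float,
    tol_rel: float,
    max_iter: int,
    init: ADMMState | None,
    adapt_rho: bool,
) -> tuple[np.ndarray, np.ndarray, ADMMState, bool, int]:
    T = len(designs)
    if init is None:
        Z = np.zeros((P, T))
        Gamma = np.zeros((P, T))
        W = np.zeros((P, T))
        b = np.zeros(T)
    else:
        Z, Gamma, W, b = init.Z.copy(), init.Gamma.copy(), init.W.copy(), init.b.copy()
        rho = init.rho
    state = ADMMState(W, b, Z, Gamma, rho)
    sqrt_pt = np.sqrt(P * T)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        state.W, state.b = w_update(state, designs)
        Z_old = state.Z
        state.Z = z_update(state, lam)
        state.Gamma = dual_update(state)
        r = float(np.linalg.norm(state.W - state.Z))
        s = float(state.rho * np.linalg.norm(state.Z - Z_old))
        state.primal_residual, state.dual_residual = r, s
        eps_pri = sqrt_pt * tol_abs + tol_rel * max(
            np.linalg.norm(state.W), np.linalg.norm(state.Z)
        )
        eps_dual = sqrt_pt * tol_abs + tol_rel * np.linalg.norm(state.Gamma)
        if r <= eps_pri and s <= eps_dual:
            converged = True
            break
        # residual balancing keeps rho in a useful range; the (unscaled) dual
        # variable needs no rescaling when rho changes
        if adapt_rho and it % 10 == 0:
            if r > 10.0 * s:
                state.rho *= 2.0
            elif s > 10.0 * r:
                state.rho /= 2.0
    return state.Z, state.b, state, converged, it


def _finalize(designs, Z, lam, converged, n_iter, mu, sd) -> MultitaskModel:
    # report W from the Z block (exactly low rank); recompute intercepts
    # consistently with it, then undo the feature standardization
    b = np.array([d.y_mean - float(Z[:, t] @ d.x_mean) for t, d in enumerate(designs)])
    if mu is None:
        W_out, b_out = Z, b
    else:
        W_out = Z / sd[:, None]
        b_out = b - mu @ W_out
    return MultitaskModel(W_out.copy(), b_out, lam, converged=converged, n_iter=n_iter)


def fit_trace_norm(
    X,
    Y,
    lam: float,
    mask=None,
    rho: float = 1.0,
    tol_abs: float = 1e-4,
    tol_rel: float = 1e-3,
    max_iter: int = 2000,
    init: ADMMState | None = None,
    standardize: bool = True,
    adapt_rho: bool = False,
) -> MultitaskModel:
    """Fit the trace-norm multitask model at a single lambda.

    Only entries of Y with mask=True enter the objective.  With
    ``standardize=True`` features are scaled to zero mean / unit variance over
    the union of training rows before fitting (the penalty is not
    scale-invariant across heterogeneous feature blocks) and coefficients are
    returned on the original scale.  lambda = 0 is solved exactly by per-task
    least squares.
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    X, Y, mask = _coerce(X, Y, mask)
    mu = sd = None
    if standardize:
        mu, sd = _standardizer(X, mask)
        X = (X - mu) / sd
    designs = build_designs(X, Y, mask)
    P = X.shape[1]
    if lam == 0.0:
        W = np.column_stack([d.ols()[0] for d in designs])
        return _finalize(designs, W, lam, True, 0, mu, sd)
    Z, b, state, converged, n_iter = _fit_admm(
        designs, P, lam, rho, tol_abs, tol_rel, max_iter, init, adapt_rho
    )
    if not converged:
        warnings.warn(
            f"ADMM did not converge in {max_iter} iterations at lambda={lam:g}",
            stacklevel=2,
        )
    model = _finalize(designs, Z, lam, converged, n_iter, mu, sd)
    model._state = state  # type: ignore[attr-defined]  # warm-start handle
    return model


def fit_path(
    X,
    Y,
    lambdas,
    mask=None,
    rho: float = 1.0,
    tol_abs: float = 1e-4,
    tol_rel: float = 1e-3,
    max_iter: int = 2000,
    standardize: bool = True,
    adapt_rho: bool = False,
) -> list[MultitaskModel]:
    """Fit a strictly decreasing lambda path with warm starts.

    The first model starts from the all-zero state (the solution at the top of
    the path is near zero); each subsequent model starts from the previous
    full ADMM state.  Task factorizations are built once for the whole path.
    """
    lambdas = np.asarray(lambdas, dtype=float)
    if lambdas.ndim != 1 or lambdas.size == 0:
        raise ValueError("lambdas must be a nonempty 1-D sequence")
    if np.any(lambdas <= 0):
        raise ValueError("path lambdas must be positive (fit lambda=0 separately)")
    if lambdas.size > 1 and np.any(np.diff(lambdas) >= 0):
        raise ValueError("lambdas must be strictly decreasing")
    X, Y, mask = _coerce(X, Y, mask)
    mu = sd = None
    if standardize:
        mu, sd = _standardizer(X, mask)
        X = (X - mu) / sd
    designs = build_designs(X, Y, mask)
    P = X.shape[1]
    models = []
    state: ADMMState | None = None
    for lam in lambdas:
        Z, b, state, converged, n_iter = _fit_admm(
            designs, P, float(lam), rho, tol_abs, tol_rel, max_iter, state, adapt_rho
        )
        if not converged:
            warnings.warn(
                f"ADMM did not converge in {max_iter} iterations at lambda={lam:g}",
                stacklevel=2,
            )
        models.append(_finalize(designs, Z, float(lam), converged, n_iter, mu, sd))
    return models
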