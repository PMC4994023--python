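"""Independent reference implementations used only as test oracles.

Nothing here shares code paths with the package's solvers: the trace-norm
reference is accelerated proximal gradient (FISTA) with its own SVD-based
proximal step, the ARI reference counts pairs explicitly, and the
nearest-drug reference is a direct transcription of the predictor's
definition.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def _shrink(M: np.ndarray, tau: float) -> np.ndarray:
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    return (U * np.maximum(s - tau, 0.0)) @ Vt


def proxgrad_trace_norm(
    X: np.ndarray,
    Y: np.ndarray,
    lam: float,
    mask: np.ndarray | None = None,
    max_iter: int = 30000,
    tol: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray]:
    """FISTA on the intercept-eliminated trace-norm objective.

    minimize_W sum_t ||yc_t - Xc_t w_t||^2 + lam * ||W||_* with per-task
    centered designs (which is the exact profile of the intercept).  Returns
    (W, b) with b recovered as the per-task training means.
    """
    N, P = X.shape
    T = Y.shape[1]
    if mask is None:
        mask = np.ones(Y.shape, bool)
    Xc, yc, xm, ym = [], [], [], []
    for t in range(T):
        rows = np.flatnonzero(mask[:, t])
        xbar = X[rows].mean(axis=0)
        ybar = Y[rows, t].mean()
        Xc.append(X[rows] - xbar)
        yc.append(Y[rows, t] - ybar)
        xm.append(xbar)
        ym.append(ybar)
    L = 2.0 * max(np.linalg.svd(Xt, compute_uv=False)[0] ** 2 for Xt in Xc)
    W = np.zeros((P, T))
    Wm = W.copy()
    tk = 1.0
    obj_prev = np.inf
    for k in range(max_iter):
        G = np.column_stack(
            [2.0 * Xc[t].T @ (Xc[t] @ Wm[:, t] - yc[t]) for t in range(T)]
        )
        W_new = _shrink(Wm - G / L, lam / L)
        tk_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * tk * tk))
        Wm = W_new + ((tk - 1.0) / tk_new) * (W_new - W)
        W, tk = W_new, tk_new
        if k % 50 == 0:
            obj = trace_norm_objective_parts(Xc, yc, W, lam)
            if abs(obj_prev - obj) < tol * max(1.0, abs(obj)):
                break
            obj_prev = obj
    b = np.array([ym[t] - float(xm[t] @ W[:, t]) for t in range(T)])
    return W, b


def trace_norm_objective_parts(Xc, yc, W, lam) -> float:
    loss = sum(float(np.sum((Xc[t] @ W[:, t] - yc[t]) ** 2)) for t in range(len(Xc)))
    return loss + lam * float(np.sum(np.linalg.svd(W, compute_uv=False)))


def optimal_intercepts(X, Y, W, mask) -> np.ndarray:
    b = np.empty(Y.shape[1])
    for t in range(Y.shape[1]):
        rows = np.flatnonzero(mask[:, t])
        b[t] = Y[rows, t].mean() - float(X[rows].mean(axis=0) @ W[:, t])
    return b


def brute_force_ari(a, b) -> float:
    """Adjusted Rand index by explicit pair counting over all C(n,2) pairs."""
    a = list(a)
    b = list(b)
    n = len(a)
    n11 = n00 = n10 = n01 = 0
    for i, j in combinations(range(n), 2):
        same_a = a[i] == a[j]
        same_b = b[i] == b[j]
        n11 += same_a and same_b
        n00 += (not same_a) and (not same_b)
        n10 += same_a and not same_b
        n01 += (not same_a) and same_b
    total = n11 + n00 + n10 + n01
    expected = (n11 + n10) * (n11 + n01) / total
    max_index = 0.5 * ((n11 + n10) + (n11 + n01))
    if max_index == expected:
        return 1.0 if n10 + n01 == 0 else 0.0
    return (n11 - expected) / (max_index - expected)


def reference_nearest_drug(values, mask, d, cells, min_overlap=3):
    """Literal re-implementation of the nearest-drug predictor's contract."""
    T = values.shape[1]
    corrs = np.full(T, -np.inf)
    for e in range(T):
        if e == d:
            continue
        both = mask[:, d] & mask[:, e]
        if both.sum() < min_overlap:
            continue
        x, y = values[both, e], values[both, d]
        if x.std() == 0 or y.std() == 0:
            continue
        corrs[e] = np.corrcoef(x, y)[0, 1]
    out = []
    fallback = values[mask[:, d], d].mean()
    for c in cells:
        candidates = [e for e in range(T) if e != d and mask[c, e] and np.isfinite(corrs[e])]
        if not candidates:
            out.append(fallback)
            continue
        best = max(candidates, key=lambda e: (corrs[e], -e))
        both = mask[:, d] & mask[:, best]
        x, y = values[both, best], values[both, d]
        slope, intercept = np.polyfit(x, y, 1) if x.std() > 0 else (0.0, y.mean())
        out.append(slope * values[c, best] + intercept)
    return np.array(out)


def exact_hypergeom_upper_tail(k, M, K, n) -> float:
    """P(X >= k) for X ~ Hypergeometric(M, K, n), summed from the log-pmf."""
    from math import comb

    denom = comb(M, n)
    total = 0
    for kk in range(k, min(K, n) + 1):
        total += comb(K, kk) * comb(M - K, n - kk)
    return total / denom
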