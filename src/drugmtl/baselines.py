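"""Single-task baselines: elastic net regression and the nearest-drug predictor.

Elastic net follows the glmnet parameterization

    (1/2N) sum_i (y_i - w'x_i - b)^2 + lambda * (alpha*||w||_1 + (1-alpha)/2*||w||_2^2)

with mixing parameter alpha in [0, 1] and strength lambda.  Model selection
mirrors the standard protocol: alpha over an 11-point uniform grid with
lambda free along its path, then lambda re-optimized at the chosen alpha
over 100 values in [0.01*lambda_max, lambda_max].

The nearest-drug predictor is a feature-free control for the transductive
setting: a held-out response of drug d on cell line c is predicted by
regressing d on the training responses of the drug most correlated with d
among drugs observed at c.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import ElasticNet, enet_path
from sklearn.model_selection import KFold

from .data import ResponseMatrix

__all__ = [
    "ElasticNetConfig",
    "SingleTaskModel",
    "lambda_max_elastic_net",
    "fit_elastic_net",
    "fit_elastic_net_path",
    "select_alpha_lambda",
    "nearest_drug_predict",
]

MIN_OVERLAP = 3  # cells two drugs must share before a correlation is trusted


@dataclass
class ElasticNetConfig:
    """Grids and preprocessing for elastic-net model selection."""

    n_alpha_grid: int = 11
    n_lambda_grid: int = 100
    lambda_min_ratio: float = 0.01
    standardize: bool = True

    def alphas(self) -> np.ndarray:
        if self.n_alpha_grid < 1:
            raise ValueError("alpha grid must be nonempty")
        return np.linspace(0.0, 1.0, self.n_alpha_grid)


@dataclass
class SingleTaskModel:
    w: np.ndarray
    b: float
    alpha: float
    lam: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X) @ self.w + self.b

    @property
    def support_size(self) -> int:
        return int(np.count_nonzero(self.w))


def _prep(X, y, standardize: bool):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    mu = X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
    else:
        sd = np.ones(X.shape[1])
    Xs = (X - mu) / sd
    ym = float(y.mean())
    return Xs, y - ym, mu, sd, ym


def _back_transform(ws: np.ndarray, mu, sd, ym) -> tuple[np.ndarray, float]:
    w = ws / sd
    return w, ym - float(mu @ w)


def lambda_max_elastic_net(X, y, alpha: float, standardize: bool = True) -> float:
    """Smallest lambda at which all elastic-net slopes are zero.

    glmnet formula max_l |x_l'(y - ybar)| / (N * alpha); for alpha = 0 the
    path has no finite zero point, so grids use the alpha = 0.001 surrogate.
    """
    y = np.asarray(y, dtype=float)
    if y.std() == 0:
        raise ValueError("response has zero variance")
    if alpha <= 0:
        raise ValueError("lambda_max requires alpha > 0 (use a small surrogate)")
    Xs, yc, *_ = _prep(X, y, standardize)
    return float(np.max(np.abs(Xs.T @ yc)) / (len(y) * alpha))


def _grid_alpha(alpha: float) -> float:
    return alpha if alpha > 0 else 1e-3


def default_lambda_grid(X, y, alpha: float, config: ElasticNetConfig) -> np.ndarray:
    lam_max = lambda_max_elastic_net(X, y, _grid_alpha(alpha), config.standardize)
    return np.geomspace(lam_max, config.lambda_min_ratio * lam_max, config.n_lambda_grid)


def _ridge_coef(Xs, yc, lam_vec: np.ndarray) -> np.ndarray:
    """Closed-form ridge path: minimize (1/2N)||yc - Xs w||^2 + (lam/2)||w||^2."""
    n = Xs.shape[0]
    U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
    Uty = U.T @ yc
    # (Xs'Xs + N*lam I)^{-1} Xs' yc  for each lam
    coefs = np.stack(
        [(Vt.T * (s / (s**2 + n * lam))) @ Uty for lam in lam_vec], axis=1
    )
    return coefs  # P x n_lambda


def fit_elastic_net(
    X, y, alpha: float, lam: float, standardize: bool = True
) -> SingleTaskModel:
    """Fit one elastic-net model at fixed (alpha, lambda)."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training rows")
    Xs, yc, mu, sd, ym = _prep(X, y, standardize)
    if alpha == 0.0:
        ws = _ridge_coef(Xs, yc, np.array([lam]))[:, 0]
    else:
        est = ElasticNet(
            alpha=lam, l1_ratio=alpha, fit_intercept=False, max_iter=20000, tol=1e-8
        )
        est.fit(Xs, yc)
        ws = est.coef_
    w, b = _back_transform(ws, mu, sd, ym)
    return SingleTaskModel(w, b, alpha, lam)


def fit_elastic_net_path(
    X, y, alpha: float, lambdas: np.ndarray, standardize: bool = True
) -> list[SingleTaskModel]:
    """Fit a decreasing lambda path at fixed alpha (warm-started coordinate descent)."""
    lambdas = np.asarray(lambdas, dtype=float)
    Xs, yc, mu, sd, ym = _prep(X, y, standardize)
    if alpha == 0.0:
        coefs = _ridge_coef(Xs, yc, lambdas)
    else:
        _, coefs, _ = enet_path(
            Xs, yc, l1_ratio=alpha, alphas=lambdas, tol=1e-8, max_iter=20000
        )
    out = []
    for j, lam in enumerate(lambdas):
        w, b = _back_transform(coefs[:, j], mu, sd, ym)
        out.append(SingleTaskModel(w, b, alpha, float(lam)))
    return out


def _cv_mse_per_lambda(X, y, alpha, lambdas, folds, seed, standardize) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    se = np.zeros(len(lambdas))
    n = 0
    for tr, va in kf.split(X):
        if len(tr) < 2:
            raise ValueError("cross-validation fold has fewer than 2 training rows")
        models = fit_elastic_net_path(X[tr], y[tr], alpha, lambdas, standardize)
        preds = np.stack([m.predict(X[va]) for m in models], axis=1)
        se += np.sum((preds - y[va][:, None]) ** 2, axis=0)
        n += len(va)
    return se / n


def select_alpha_lambda(
    X,
    y,
    config: ElasticNetConfig | None = None,
    folds: int = 5,
    seed: int = 0,
) -> tuple[float, float]:
    """Two-stage selection: alpha by K-fold CV with lambda free, then lambda at fixed alpha.

    Ties in CV error break toward larger lambda (more regularization); the
    same fold split is reused across the alpha grid so the comparison is
    paired.  Deterministic for fixed inputs and seed.
    """
    config = config or ElasticNetConfig()
    best_alpha, best_err = None, np.inf
    for alpha in config.alphas():
        lambdas = default_lambda_grid(X, y, alpha, config)
        mse = _cv_mse_per_lambda(X, y, alpha, lambdas, folds, seed, config.standardize)
        err = float(mse.min())
        if err < best_err - 1e-15:
            best_alpha, best_err = float(alpha), err
    assert best_alpha is not None
    lambdas = default_lambda_grid(X, y, best_alpha, config)
    mse = _cv_mse_per_lambda(X, y, best_alpha, lambdas, folds, seed, config.standardize)
    best_lam = float(lambdas[int(np.argmin(mse))])  # grid decreasing -> first min = largest lam
    return best_alpha, best_lam


def _pairwise_corr(values: np.ndarray, mask: np.ndarray, d: int, e: int) -> float:
    both = mask[:, d] & mask[:, e]
    if both.sum() < MIN_OVERLAP:
        return -np.inf
    a, b = values[both, d], values[both, e]
    if a.std() == 0 or b.std() == 0:
        return -np.inf
    return float(np.corrcoef(a, b)[0, 1])


def nearest_drug_predict(
    Ytrain: ResponseMatrix | np.ndarray,
    target_drug: int | str,
    target_cells,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Predict held-out responses of one drug from its best-correlated neighbor.

    For each target cell c the neighbor is the drug observed at c (in the
    training mask) with the highest Pearson correlation to the target drug on
    jointly observed training cells (>= 3 overlapping cells; ties break to
    the lowest drug index).  The prediction is the univariate regression of
    the target on the neighbor, fit on the jointly observed training pairs,
    evaluated at the neighbor's training response for c.  Falls back to the
    target's observed training mean when no neighbor qualifies.  The feature
    matrix is never consulted.
    """
    if isinstance(Ytrain, ResponseMatrix):
        values, msk = Ytrain.values, Ytrain.mask
        if isinstance(target_drug, str):
            target_drug = Ytrain.drug_ids.index(target_drug)
    else:
        values = np.asarray(Ytrain, dtype=float)
        msk = np.ones(values.shape, bool) if mask is None else np.asarray(mask, bool)
    d = int(target_drug)
    T = values.shape[1]
    if T < 2:
        raise ValueError("nearest-drug prediction needs at least 2 drugs")
    corr = np.array([_pairwise_corr(values, msk, d, e) if e != d else -np.inf for e in range(T)])
    fallback = float(values[msk[:, d], d].mean())
    preds = np.empty(len(target_cells))
    for i, c in enumerate(target_cells):
        avail = msk[c] & (corr > -np.inf)
        avail[d] = False
        if not avail.any():
            preds[i] = fallback
            continue
        cand = np.flatnonzero(avail)
        e = int(cand[np.argmax(corr[cand])])  # argmax takes the lowest index on ties
        both = msk[:, d] & msk[:, e]
        x, yy = values[both, e], values[both, d]
        slope = float(np.cov(x, yy, bias=True)[0, 1] / x.var()) if x.var() > 0 else 0.0
        intercept = float(yy.mean() - slope * x.mean())
        preds[i] = slope * values[c, e] + intercept
    return preds
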