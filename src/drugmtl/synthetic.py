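"""Synthetic data with the low-rank multitask structure the solver assumes.

The generator emulates the shape of a pharmacogenomic screen at fixture
scale: a feature matrix mixing continuous (expression-like, standard normal)
columns with sparse binary (mutation-like, 10% prevalence) columns; a true
coefficient matrix W_true = U V' of exact rank r shared across T drug tasks;
responses Y = X W_true + 1 b' + Gaussian noise.  Two optional layers add the
structure the downstream analyses test for:

* mechanism groups — tasks in the same group share a V row (plus small
  jitter), giving a ground-truth partition for clustering/ARI checks;
* noisy tasks — a chosen fraction of response columns are independently
  permuted, emulating drugs whose labels carry no signal, which is what the
  permutation noise test is built to flag.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import FeatureMatrix, ResponseMatrix

__all__ = ["SyntheticSpec", "SyntheticTruth", "generate", "holdout_mask"]

BINARY_PREVALENCE = 0.1  # mutation-like columns are rare events
GROUP_JITTER = 0.1  # within-group spread of task loadings, relative to V scale


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic cohort."""

    n_cells: int = 100
    n_features: int = 50
    n_tasks: int = 20
    rank: int = 2
    noise_sd: float = 0.5
    frac_binary_features: float = 0.2
    frac_noisy_tasks: float = 0.0
    group_assignment: list[int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rank > min(self.n_features, self.n_tasks):
            raise ValueError("rank must not exceed min(P, T)")
        for name in ("frac_binary_features", "frac_noisy_tasks"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.group_assignment is not None and len(self.group_assignment) != self.n_tasks:
            raise ValueError("group_assignment length must equal n_tasks")


@dataclass
class SyntheticTruth:
    W_true: np.ndarray
    b_true: np.ndarray
    noisy_task_ids: set[int] = field(default_factory=set)
    group_assignment: list[int] | None = None


def _ids(prefix: str, n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(n)]


def generate(spec: SyntheticSpec) -> tuple[FeatureMatrix, ResponseMatrix, SyntheticTruth]:
    """Draw one cohort: features, responses (all observed), and the ground truth."""
    rng = np.random.default_rng(spec.seed)
    N, P, T, r = spec.n_cells, spec.n_features, spec.n_tasks, spec.rank

    n_bin = int(round(spec.frac_binary_features * P))
    X = rng.standard_normal((N, P))
    if n_bin:
        X[:, P - n_bin :] = (rng.random((N, n_bin)) < BINARY_PREVALENCE).astype(float)

    U = rng.standard_normal((P, r))
    if spec.group_assignment is not None:
        groups = np.asarray(spec.group_assignment)
        V = np.empty((T, r))
        for g in np.unique(groups):
            members = np.flatnonzero(groups == g)
            base = rng.standard_normal(r)
            V[members] = base + GROUP_JITTER * rng.standard_normal((len(members), r))
    else:
        V = rng.standard_normal((T, r))
    W = U @ V.T
    # scale so the mean per-task signal variance (~ ||w_t||^2 under unit-variance
    # features) is about 1
    fnorm = np.linalg.norm(W)
    if fnorm > 0:
        W *= np.sqrt(T) / fnorm
    b = rng.standard_normal(T)

    Y = X @ W + b + spec.noise_sd * rng.standard_normal((N, T))

    n_noisy = int(round(spec.frac_noisy_tasks * T))
    noisy = set(rng.choice(T, size=n_noisy, replace=False).tolist()) if n_noisy else set()
    for t in sorted(noisy):
        Y[:, t] = rng.permutation(Y[:, t])

    fm = FeatureMatrix(X, _ids("CL", N), _ids("F", P - n_bin) + _ids("MUT", n_bin))
    rm = ResponseMatrix(Y, np.ones((N, T), bool), _ids("CL", N), _ids("D", T))
    truth = SyntheticTruth(W, b, noisy, list(spec.group_assignment) if spec.group_assignment else None)
    return fm, rm, truth


def holdout_mask(
    rm: ResponseMatrix, frac: float, mode: str, seed: int = 0
) -> ResponseMatrix:
    """Mask a fraction of observed responses per the holdout geometry.

    inductive: a common set of round(frac*N) cell lines is hidden across all
    drugs; transductive: each drug independently hides round(frac * n_obs)
    of its observed entries.  Errors out if any drug would lose all its
    observed entries.
    """
    if not 0.0 < frac < 1.0:
        raise ValueError("frac must be in (0, 1)")
    if mode not in ("inductive", "transductive"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    mask = rm.mask.copy()
    N, T = mask.shape
    if mode == "inductive":
        n_hide = int(round(frac * N))
        rows = rng.choice(N, size=n_hide, replace=False)
        mask[rows, :] = False
    else:
        for t in range(T):
            obs = np.flatnonzero(rm.mask[:, t])
            n_hide = int(round(frac * obs.size))
            hide = rng.choice(obs, size=n_hide, replace=False)
            mask[hide, t] = False
    empty = np.flatnonzero(mask.sum(axis=0) == 0)
    if empty.size:
        raise ValueError(
            f"holdout leaves drugs with no training entries: "
            f"{[rm.drug_ids[t] for t in empty]}"
        )
    return ResponseMatrix(rm.values.copy(), mask, list(rm.cell_line_ids), list(rm.drug_ids))
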