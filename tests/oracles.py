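"""Independent oracles used to cross-check the implementation.

Each helper here deliberately takes a different computational route from
the code under test: brute-force iteration instead of a linear solve,
exhaustive grid search instead of a QP solver, an eigendecomposition of
K'K instead of an SVD, and explicit pair counting instead of a ranking
formula.
"""
from __future__ import annotations

import numpy as np


def iterative_propagation(
    K: np.ndarray, H0: np.ndarray, theta: float, steps: int = 500
) -> np.ndarray:
    """Run the label-propagation recurrence H <- theta*K@H + (1-theta)*H0."""
    H = H0.copy()
    for _ in range(steps):
        H = theta * (K @ H) + (1.0 - theta) * H0
    return H


def simplex_grid_min_objective(
    G: np.ndarray, c: np.ndarray, step: float = 1e-4
) -> float:
    """Exhaustive grid search of w'Gw - 2c'w over the probability simplex.

    Supports k <= 3 variables; the k = 3 case sweeps the 2-simplex in
    vectorized slices to stay fast at step 1e-4.
    """
    k = len(c)
    if k == 1:
        return float(G[0, 0] - 2.0 * c[0])
    if k == 2:
        w1 = np.arange(0.0, 1.0 + step / 2, step)
        W = np.stack([w1, 1.0 - w1], axis=1)
        obj = np.einsum("ij,jk,ik->i", W, G, W) - 2.0 * W @ c
        return float(obj.min())
    if k == 3:
        best = np.inf
        grid = np.arange(0.0, 1.0 + step / 2, step)
        for w1 in grid:
            w2 = np.arange(0.0, 1.0 - w1 + step / 2, step)
            w3 = 1.0 - w1 - w2
            W = np.stack([np.full_like(w2, w1), w2, w3], axis=1)
            obj = np.einsum("ij,jk,ik->i", W, G, W) - 2.0 * W @ c
            best = min(best, float(obj.min()))
        return best
    raise ValueError("grid oracle supports k <= 3 only")


def reconstruction_objective(
    T_neighbors: np.ndarray, t: np.ndarray, w: np.ndarray, ridge: float
) -> float:
    """||t - w'T||^2 + ridge*||w||^2, the (ridge-regularized) QP objective."""
    resid = t - w @ T_neighbors
    return float(resid @ resid + ridge * w @ w)


def eig_low_rank(K: np.ndarray, r: int) -> np.ndarray:
    """Best rank-r approximation via the eigendecomposition of K'K."""
    evals, V = np.linalg.eigh(K.T @ K)
    order = np.argsort(evals)[::-1][:r]
    approx = np.zeros_like(K, dtype=float)
    for idx in order:
        sigma = np.sqrt(max(evals[idx], 0.0))
        if sigma == 0.0:
            continue
        v = V[:, idx]
        u = K @ v / sigma
        approx += sigma * np.outer(u, v)
    return approx


def pair_count_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by explicit counting over every positive-negative pair."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def random_row_stochastic(rng: np.random.Generator, n: int) -> np.ndarray:
    """A random strictly positive row-stochastic matrix."""
    K = rng.random((n, n)) + 1e-3
    return K / K.sum(axis=1, keepdims=True)
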