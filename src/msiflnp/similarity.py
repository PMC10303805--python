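"""Association-derived similarity matrices.

Three similarities are computed per entity type (microbes = rows of A,
diseases = columns of A), all from the binary association matrix alone:

* cosine similarity between association profiles,
* the Gaussian interaction-profile (GIP) kernel, with bandwidth scaled
  by the mean squared profile norm,
* linear-neighborhood similarity: the nonnegative, sum-to-one weights
  that best reconstruct each profile from its k nearest neighbors'
  profiles (one small simplex-constrained quadratic program per entity).
"""
from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import cdist
from sklearn.metrics.pairwise import cosine_similarity as _sk_cosine

from .io import AssociationMatrix, SimilarityMatrix

#: ridge added to the neighbor Gram matrix; duplicate profiles otherwise
#: make the QP singular
QP_RIDGE = 1e-6


class NeighborSet(NamedTuple):
    """k nearest neighbors of one entity (self excluded), nondecreasing distance."""

    indices: np.ndarray
    distances: np.ndarray


def _profiles(assoc: AssociationMatrix, axis: str) -> tuple[np.ndarray, list[str]]:
    if axis == "microbe":
        return assoc.values, assoc.microbe_ids
    if axis == "disease":
        return assoc.values.T, assoc.disease_ids
    raise ValueError(f"axis must be 'microbe' or 'disease', got {axis!r}")


def cosine_profile_similarity(assoc: AssociationMatrix, axis: str) -> SimilarityMatrix:
    """Cosine similarity between binary association profiles.

    An all-zero profile has similarity 0 to everything, including
    itself; downstream selective normalization skips the resulting
    all-zero columns rather than dividing by zero.
    """
    X, ids = _profiles(assoc, axis)
    S = _sk_cosine(X)
    nonzero = X.any(axis=1)
    S[np.ix_(~nonzero, ~nonzero)] = 0.0
    S = (S + S.T) / 2.0
    S[np.diag_indices_from(S)] = np.where(nonzero, 1.0, 0.0)
    np.clip(S, 0.0, 1.0, out=S)
    return SimilarityMatrix(S, ids, "cosine")


def gip_similarity(
    assoc: AssociationMatrix, axis: str, gamma: float = 1.0
) -> SimilarityMatrix:
    """Gaussian interaction-profile kernel between association profiles.

    The bandwidth is gamma divided by the mean squared profile norm over
    all entities on the axis, so the kernel adapts to the overall
    association density.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    X, ids = _profiles(assoc, axis)
    mean_sq_norm = float((X**2).sum(axis=1).mean())
    if mean_sq_norm == 0.0:
        raise ValueError("GIP bandwidth undefined: all association profiles are zero")
    bandwidth = gamma / mean_sq_norm
    sq_dists = cdist(X, X, metric="sqeuclidean")
    S = np.exp(-bandwidth * sq_dists)
    S = (S + S.T) / 2.0
    S[np.diag_indices_from(S)] = 1.0
    return SimilarityMatrix(S, ids, "gip")


def nearest_neighbors(X: np.ndarray, i: int, k: int) -> NeighborSet:
    """k nearest neighbors of row i by Euclidean distance, self excluded.

    Ties at the cutoff break toward the smaller entity index (stable
    argsort), so neighbor sets are deterministic.
    """
    d = np.linalg.norm(X - X[i], axis=1)
    d[i] = np.inf
    order = np.argsort(d, kind="stable")[:k]
    return NeighborSet(order, d[order])


def _solve_simplex_qp(G: np.ndarray, c: np.ndarray, entity: str) -> np.ndarray:
    """Minimize w'Gw - 2c'w over the probability simplex."""
    k = len(c)
    if k == 1:
        return np.array([1.0])
    x0 = np.full(k, 1.0 / k)
    res = minimize(
        lambda w: float(w @ G @ w - 2.0 * c @ w),
        x0,
        jac=lambda w: 2.0 * (G @ w - c),
        method="SLSQP",
        bounds=[(0.0, 1.0)] * k,
        constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0, "jac": lambda w: np.ones(k)}],
        options={"maxiter": 500, "ftol": 1e-14},
    )
    if not res.success:
        raise RuntimeError(f"neighborhood QP failed for entity {entity!r}: {res.message}")
    w = np.clip(res.x, 0.0, None)
    return w / w.sum()


def linear_neighborhood_similarity(
    assoc: AssociationMatrix, axis: str, k: int, ridge: float = QP_RIDGE
) -> SimilarityMatrix:
    """Linear-neighborhood reconstruction weights as a similarity matrix.

    For each entity i with profile t_i, solve

        min_w || t_i - sum_j w_j t_j ||^2   s.t.  sum_j w_j = 1, w_j >= 0

    over its k nearest neighbors (self excluded); weights for
    non-neighbors are 0, so each row has at most k nonzeros and sums to
    1. A small ridge on the neighbor Gram matrix keeps the program
    well-posed when neighbor profiles are identical. An all-zero profile
    yields an all-zero row: there is nothing to reconstruct.
    """
    X, ids = _profiles(assoc, axis)
    n = len(ids)
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must be in [1, {n - 1}], got {k}")
    W = np.zeros((n, n))
    for i in range(n):
        if not X[i].any():
            continue
        nbrs = nearest_neighbors(X, i, k)
        T = X[nbrs.indices]
        G = T @ T.T + ridge * np.eye(k)
        c = T @ X[i]
        W[i, nbrs.indices] = _solve_simplex_qp(G, c, ids[i])
    return SimilarityMatrix(W, ids, "linear_neighborhood")
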