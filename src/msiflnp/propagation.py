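"""Closed-form linear-neighborhood label propagation.

Labels diffuse over a similarity network K: at each step a node takes a
fraction theta of its neighbors' labels and keeps its initial label at
rate 1 - theta. The fixed point of

    H_{m+1} = theta * K @ H_m + (1 - theta) * H0

is the Neumann-series closed form (1 - theta) (I - theta K)^-1 H0,
which is what we compute (by a linear solve, never an explicit
inverse). Convergence requires rho(theta K) < 1, guaranteed by
row-normalizing K to a stochastic transition matrix first.
"""
from __future__ import annotations

import numpy as np

from .io import SimilarityMatrix


def normalize_transition(K: SimilarityMatrix) -> SimilarityMatrix:
    """Row-normalize a nonnegative similarity into a (sub)stochastic transition.

    All-zero rows stay zero; a node with no outgoing similarity simply
    keeps its initial label, scaled by 1 - theta, during propagation.
    """
    V = K.values
    if (V < 0).any():
        raise ValueError("transition normalization requires nonnegative entries")
    sums = V.sum(axis=1)
    out = V.copy()
    nz = sums > 0
    out[nz] /= sums[nz, None]
    # row normalization breaks the symmetry promised by cosine/gip tags
    kind = "fused" if K.kind in ("cosine", "gip") else K.kind
    return SimilarityMatrix(out, K.entity_ids, kind)


def propagate_closed_form(
    K: SimilarityMatrix | np.ndarray, H0: np.ndarray, theta: float
) -> np.ndarray:
    """Evaluate (1 - theta)(I - theta K)^-1 H0 by solving the linear system."""
    KV = K.values if isinstance(K, SimilarityMatrix) else np.asarray(K, dtype=float)
    n = KV.shape[0]
    if KV.shape != (n, n):
        raise ValueError(f"K must be square, got {KV.shape}")
    H0 = np.asarray(H0, dtype=float)
    if H0.shape[0] != n:
        raise ValueError(f"H0 has {H0.shape[0]} rows, expected {n}")
    if not 0.0 < theta < 1.0:
        raise ValueError(f"theta must lie strictly in (0, 1), got {theta}")
    system = np.eye(n) - theta * KV
    try:
        sol = np.linalg.solve(system, H0)
    except np.linalg.LinAlgError:
        rho = float(np.max(np.abs(np.linalg.eigvals(theta * KV))))
        raise np.linalg.LinAlgError(
            f"(I - theta*K) is singular: spectral radius of theta*K is {rho:.6g} "
            "(requires < 1; row-normalize K first)"
        ) from None
    return (1.0 - theta) * sol


def minmax_rows(Y: np.ndarray) -> np.ndarray:
    """Map each row to [0, 1] by (y - rowmin) / (rowmax - rowmin).

    A constant row carries no ranking contrast and maps to all zeros.
    """
    Y = np.asarray(Y, dtype=float)
    lo = Y.min(axis=1, keepdims=True)
    hi = Y.max(axis=1, keepdims=True)
    span = hi - lo
    out = np.zeros_like(Y)
    nz = (span > 0).ravel()
    out[nz] = (Y[nz] - lo[nz]) / span[nz]
    return out
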