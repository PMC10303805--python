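"""Similarity-network fusion with SVD denoising (the MSIF stage).

From the three similarities of one entity type, build three selectively
column-normalized initial kernels and three top-N neighbor-constraint
kernels, cross-iterate them (each kernel conjugates the average of the
other two neighbor kernels), average, and denoise the result by
truncated SVD, keeping a fixed fraction of the singular values.

"Selective" normalization always skips all-zero columns or rows instead
of dividing by zero, so entities with no associations ride through the
pipeline harmlessly.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .config import MsifLnpParams
from .io import AssociationMatrix, SimilarityMatrix
from .similarity import (
    cosine_profile_similarity,
    gip_similarity,
    linear_neighborhood_similarity,
)

logger = logging.getLogger(__name__)

#: kernel order: cosine, GIP, linear-neighborhood (the fusion is
#: symmetric in this order; it only affects logs and dump filenames)
KERNEL_NAMES = ("cosine", "gip", "linear_neighborhood")


@dataclass
class KernelSet:
    """The three initial and three neighbor-constraint kernels for one axis."""

    initial_kernels: list[SimilarityMatrix]
    neighbor_kernels: list[SimilarityMatrix]
    entity_axis: str
    n_neighbors: int

    @property
    def entity_ids(self) -> list[str]:
        return self.initial_kernels[0].entity_ids


@dataclass
class FusedNetwork:
    """Fused similarity network before and after SVD denoising."""

    raw: SimilarityMatrix
    denoised: SimilarityMatrix
    singular_values: np.ndarray
    rank_kept: int
    clipped_mass_fraction: float
    #: low-rank reconstruction before the nonnegativity clip
    reconstruction: np.ndarray | None = None
    kernels: "KernelSet | None" = None

    @property
    def entity_ids(self) -> list[str]:
        return self.denoised.entity_ids


def selective_column_normalize(S: SimilarityMatrix) -> SimilarityMatrix:
    """Divide each column by its sum; all-zero columns stay zero."""
    V = S.values
    if (V < 0).any():
        raise ValueError("selective column normalization requires nonnegative entries")
    sums = V.sum(axis=0)
    out = V.copy()
    nz = sums > 0
    out[:, nz] /= sums[nz]
    return SimilarityMatrix(out, S.entity_ids, "initial_kernel")


def neighbor_constraint_kernel(S: SimilarityMatrix, n_neighbors: int) -> SimilarityMatrix:
    """Keep each row's top-``n_neighbors`` entries (self always kept), row-normalize.

    Entries outside the neighbor set are zeroed. Ties at the cutoff
    break toward the smaller entity index. Rows whose kept entries sum
    to zero remain all-zero.
    """
    V = S.values
    n = V.shape[0]
    if not 1 <= n_neighbors <= n:
        raise ValueError(f"n_neighbors must be in [1, {n}], got {n_neighbors}")
    out = np.zeros_like(V)
    for i in range(n):
        order = np.argsort(-V[i], kind="stable")
        order = order[order != i]
        keep = np.concatenate(([i], order[: n_neighbors - 1])).astype(int)
        kept = V[i, keep]
        total = kept.sum()
        if total > 0:
            out[i, keep] = kept / total
    return SimilarityMatrix(out, S.entity_ids, "neighbor_kernel")


def build_kernels(
    assoc: AssociationMatrix, axis: str, n_neighbors: int, gip_gamma: float = 1.0
) -> KernelSet:
    """Compute the three similarities for one axis and derive both kernel triples."""
    n = assoc.n_microbes if axis == "microbe" else assoc.n_diseases
    # the reconstruction QP excludes self, so it supports at most n-1 neighbors
    ln_k = min(n_neighbors, n - 1)
    sims = [
        cosine_profile_similarity(assoc, axis),
        gip_similarity(assoc, axis, gamma=gip_gamma),
        linear_neighborhood_similarity(assoc, axis, ln_k),
    ]
    initial = [selective_column_normalize(S) for S in sims]
    neighbor = [neighbor_constraint_kernel(S, n_neighbors) for S in sims]
    return KernelSet(initial, neighbor, axis, n_neighbors)


def cross_iterate(kernels: KernelSet, x: int) -> list[SimilarityMatrix]:
    """Run x cross-iteration steps and return the three iterated kernels.

    Each step replaces neighbor kernel l with

        MS_l @ (mean of the other two neighbor kernels) @ MS_l'

    where MS_l is the matching initial kernel. All three are updated
    simultaneously from the previous iterate (Jacobi style). x = 0
    returns the neighbor kernels untouched.
    """
    if x < 0:
        raise ValueError("iteration count must be nonnegative")
    ids = kernels.entity_ids
    MS = [k.values for k in kernels.initial_kernels]
    LMS = [k.values for k in kernels.neighbor_kernels]
    dims = {m.shape for m in MS} | {m.shape for m in LMS}
    if len(dims) != 1:
        raise ValueError(f"mismatched kernel dimensions: {sorted(dims)}")
    for _ in range(x):
        LMS = [
            MS[l] @ ((LMS[(l + 1) % 3] + LMS[(l + 2) % 3]) / 2.0) @ MS[l].T
            for l in range(3)
        ]
    return [SimilarityMatrix(m.copy(), ids, "fused") for m in LMS]


def fuse(kernels: KernelSet, x: int) -> SimilarityMatrix:
    """Entrywise mean of the three cross-iterated kernels."""
    iterated = cross_iterate(kernels, x)
    mean = sum(k.values for k in iterated) / 3.0
    return SimilarityMatrix(mean, kernels.entity_ids, "fused")


def svd_denoise(K: SimilarityMatrix, keep_fraction: float) -> FusedNetwork:
    """Reconstruct K from its top ceil(keep_fraction x dim) singular triplets.

    Negative entries of the low-rank reconstruction are clipped to zero
    (a similarity cannot be negative, and propagation normalization
    assumes nonnegative weights); the clipped mass fraction is logged.
    """
    if not 0.0 < keep_fraction <= 1.0:
        raise ValueError("keep_fraction must lie in (0, 1]")
    V = K.values
    n = V.shape[0]
    U, s, Vt = np.linalg.svd(V, full_matrices=False)
    r = max(1, math.ceil(keep_fraction * n))
    recon = (U[:, :r] * s[:r]) @ Vt[:r]
    neg = recon[recon < 0]
    total = np.abs(recon).sum()
    clipped = float(-neg.sum() / total) if total > 0 else 0.0
    if clipped > 0:
        logger.debug(
            "SVD denoising clipped %.3g of matrix mass to zero (rank %d of %d)",
            clipped,
            r,
            n,
        )
    denoised = np.clip(recon, 0.0, None)
    return FusedNetwork(
        raw=K,
        denoised=SimilarityMatrix(denoised, K.entity_ids, "denoised"),
        singular_values=s,
        rank_kept=r,
        clipped_mass_fraction=clipped,
        reconstruction=recon,
    )


def build_network(
    assoc: AssociationMatrix, axis: str, params: MsifLnpParams
) -> FusedNetwork:
    """End-to-end fused, denoised similarity network for one entity axis."""
    assoc.require_nonempty()
    n_neighbors = (
        params.n_neighbors_microbe if axis == "microbe" else params.n_neighbors_disease
    )
    kernels = build_kernels(assoc, axis, n_neighbors, gip_gamma=params.gip_gamma)
    fused = fuse(kernels, params.fusion_iters)
    network = svd_denoise(fused, params.svd_keep_fraction)
    network.kernels = kernels
    return network
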