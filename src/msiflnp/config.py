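"""Tunable parameters of the MSIF-LNP pipeline."""
from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Any, Mapping, Optional

import yaml


@dataclass(frozen=True)
class MsifLnpParams:
    """All pipeline tunables in one place.

    Attributes
    ----------
    n_neighbors_microbe : int
        Neighbor count Nm used for both the microbe linear-neighborhood
        similarity and the microbe neighbor-constraint kernel.
    n_neighbors_disease : int
        Same for diseases (Nd).
    fusion_iters : int
        Number of cross-iteration fusion steps x (0 leaves the initial
        neighbor kernels untouched).
    theta : float
        Propagation probability in (0, 1); each propagation step keeps
        the initial labels at rate 1 - theta.
    gip_gamma : float
        Scale of the GIP kernel bandwidth (the bandwidth itself is
        gamma over the mean squared profile norm).
    svd_keep_fraction : float
        Fraction of singular values kept when denoising the fused
        network (rank = ceil(fraction x dimension)).
    cv_folds, cv_repeats : int
        Cross-validation protocol: known associations split into
        cv_folds groups, whole protocol repeated cv_repeats times.
    seed : int
        Seed for every source of randomness (fold shuffles).
    """

    n_neighbors_microbe: int = 5
    n_neighbors_disease: int = 26
    fusion_iters: int = 2
    theta: float = 0.2
    gip_gamma: float = 1.0
    svd_keep_fraction: float = 0.5
    cv_folds: int = 10
    cv_repeats: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neighbors_microbe < 1:
            raise ValueError("n_neighbors_microbe must be a positive integer")
        if self.n_neighbors_disease < 1:
            raise ValueError("n_neighbors_disease must be a positive integer")
        if self.fusion_iters < 0:
            raise ValueError("fusion_iters must be nonnegative")
        if not 0.0 < self.theta < 1.0:
            raise ValueError(f"theta must lie strictly in (0, 1), got {self.theta}")
        if self.gip_gamma <= 0:
            raise ValueError("gip_gamma must be positive")
        if not 0.0 < self.svd_keep_fraction <= 1.0:
            raise ValueError("svd_keep_fraction must lie in (0, 1]")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be at least 2 (need a held-out set)")
        if self.cv_repeats < 1:
            raise ValueError("cv_repeats must be at least 1")

    def check_against(self, n_microbes: int, n_diseases: int) -> None:
        """Neighbor counts cannot exceed the entity counts of a dataset."""
        if self.n_neighbors_microbe > n_microbes:
            raise ValueError(
                f"n_neighbors_microbe={self.n_neighbors_microbe} exceeds "
                f"{n_microbes} microbes"
            )
        if self.n_neighbors_disease > n_diseases:
            raise ValueError(
                f"n_neighbors_disease={self.n_neighbors_disease} exceeds "
                f"{n_diseases} diseases"
            )

    def estimator_kwargs(self) -> dict[str, Any]:
        """Keyword arguments for the ``MsifLnp`` estimator."""
        return {
            "n_neighbors_microbe": self.n_neighbors_microbe,
            "n_neighbors_disease": self.n_neighbors_disease,
            "fusion_iters": self.fusion_iters,
            "theta": self.theta,
            "gip_gamma": self.gip_gamma,
            "svd_keep_fraction": self.svd_keep_fraction,
        }

    def asdict(self) -> dict[str, Any]:
        return asdict(self)

    def with_overrides(self, **overrides: Any) -> "MsifLnpParams":
        overrides = {k: v for k, v in overrides.items() if v is not None}
        unknown = set(overrides) - set(asdict(self))
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return replace(self, **overrides)


def load_params(
    path: Optional[str | Path] = None, overrides: Optional[Mapping[str, Any]] = None
) -> MsifLnpParams:
    """Resolve parameters with precedence: overrides > YAML file > defaults."""
    params = MsifLnpParams()
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"params file {path} must hold a mapping")
        params = params.with_overrides(**loaded)
    if overrides:
        params = params.with_overrides(**dict(overrides))
    return params
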