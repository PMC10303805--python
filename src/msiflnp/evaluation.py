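"""Repeated k-fold cross-validation, AUC scoring, and parameter sweeps.

The protocol splits only the *known* associations into folds. In each
fold the test positives are zeroed in the training matrix, every
similarity is recomputed from that masked matrix (the similarities all
derive from A, so anything less would leak the test labels), the full
pipeline produces a score matrix, and the fold AUC ranks the test
positives against all pairs that are 0 in the original matrix. Fold
AUCs are averaged per repeat; the reported spread is the standard
deviation over repeats.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Any, Mapping, Optional, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .config import MsifLnpParams
from .estimator import MsifLnp
from .io import AssociationMatrix


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve (Mann-Whitney: P(pos > neg) + P(tie)/2)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: need both positive and negative labels")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


@dataclass
class CVResult:
    """Cross-validation outcome: one AUC per repeat, plus per-fold detail."""

    auc_per_run: list[float]
    auc_mean: float
    auc_std: float
    fold_aucs: list[list[float]]
    fold_assignments: list[np.ndarray]
    params: MsifLnpParams

    @property
    def fold_auc_standard_error(self) -> float:
        """Standard error of the mean AUC over all folds of all repeats."""
        flat = np.concatenate([np.asarray(f) for f in self.fold_aucs])
        if len(flat) < 2:
            return float("nan")
        return float(flat.std(ddof=1) / np.sqrt(len(flat)))


def make_fold_assignments(
    n_positives: int, folds: int, repeats: int, seed: int
) -> list[np.ndarray]:
    """Seeded fold labels for each positive pair, one array per repeat."""
    rng = np.random.default_rng(seed)
    assignments = []
    for _ in range(repeats):
        perm = rng.permutation(n_positives)
        labels = np.empty(n_positives, dtype=int)
        for f, chunk in enumerate(np.array_split(perm, folds)):
            labels[chunk] = f
        assignments.append(labels)
    return assignments


def cross_validate(
    assoc: AssociationMatrix,
    params: MsifLnpParams,
    fold_assignments: Optional[list[np.ndarray]] = None,
) -> CVResult:
    """Repeated k-fold cross-validation of the full pipeline.

    ``fold_assignments`` (one array of fold labels per repeat, indexed
    like ``np.argwhere(A == 1)``) may be supplied to share folds across
    parameter settings; by default they are drawn from ``params.seed``.
    """
    assoc.require_nonempty()
    params.check_against(assoc.n_microbes, assoc.n_diseases)
    A = assoc.values
    positives = np.argwhere(A == 1)
    n_pos = len(positives)
    if n_pos < params.cv_folds:
        raise ValueError(
            f"{n_pos} known associations cannot fill {params.cv_folds} folds"
        )
    if fold_assignments is None:
        fold_assignments = make_fold_assignments(
            n_pos, params.cv_folds, params.cv_repeats, params.seed
        )
    negative_mask = A == 0
    neg_rows, neg_cols = np.where(negative_mask)

    auc_per_run: list[float] = []
    fold_aucs_all: list[list[float]] = []
    for labels in fold_assignments:
        fold_aucs: list[float] = []
        for f in range(params.cv_folds):
            test = positives[labels == f]
            train_matrix = A.copy()
            train_matrix[test[:, 0], test[:, 1]] = 0.0
            # leakage guard: every test positive must be absent from the
            # matrix all similarities are computed from
            assert (train_matrix[test[:, 0], test[:, 1]] == 0).all()
            train_assoc = AssociationMatrix(
                train_matrix, assoc.microbe_ids, assoc.disease_ids
            )
            model = MsifLnp(**params.estimator_kwargs()).fit(train_assoc)
            Y = model.scores_
            scores = np.concatenate([Y[test[:, 0], test[:, 1]], Y[neg_rows, neg_cols]])
            fold_labels = np.concatenate(
                [np.ones(len(test), dtype=int), np.zeros(len(neg_rows), dtype=int)]
            )
            fold_aucs.append(auc(scores, fold_labels))
        fold_aucs_all.append(fold_aucs)
        auc_per_run.append(float(np.mean(fold_aucs)))

    arr = np.asarray(auc_per_run)
    return CVResult(
        auc_per_run=auc_per_run,
        auc_mean=float(arr.mean()),
        auc_std=float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
        fold_aucs=fold_aucs_all,
        fold_assignments=list(fold_assignments),
        params=params,
    )


@dataclass
class SweepResult:
    """Grid-sweep outcome: every setting's CV result plus the argmax."""

    grid: list[tuple[dict[str, Any], CVResult]]
    best: dict[str, Any]

    @property
    def best_result(self) -> CVResult:
        for setting, result in self.grid:
            if setting == self.best:
                return result
        raise LookupError("best setting missing from grid")  # pragma: no cover


def sweep(
    assoc: AssociationMatrix,
    grid_spec: Mapping[str, Sequence[Any]],
    base_params: MsifLnpParams,
) -> SweepResult:
    """Cross-validate every point of a parameter grid with shared folds.

    ``grid_spec`` maps parameter names to candidate values; the full
    Cartesian product is evaluated. Fold assignments are drawn once
    from ``base_params`` so grid points differ only in the parameters,
    not in fold noise. Ties in mean AUC break toward smaller parameter
    values.
    """
    if not grid_spec:
        raise ValueError("empty parameter grid")
    names = sorted(grid_spec)
    combos = [
        dict(zip(names, values))
        for values in itertools.product(*(sorted(grid_spec[n]) for n in names))
    ]
    n_pos = int(assoc.values.sum())
    shared = make_fold_assignments(
        n_pos, base_params.cv_folds, base_params.cv_repeats, base_params.seed
    )
    results: list[tuple[dict[str, Any], CVResult]] = []
    best: Optional[dict[str, Any]] = None
    best_auc = -np.inf
    for setting in combos:
        params = base_params.with_overrides(**setting)
        result = cross_validate(assoc, params, fold_assignments=shared)
        results.append((setting, result))
        if result.auc_mean > best_auc:
            best_auc = result.auc_mean
            best = setting
    assert best is not None
    return SweepResult(grid=results, best=best)
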