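"""The MSIF-LNP estimator: fused similarity networks + bidirectional propagation.

``MsifLnp`` is a scikit-learn-style transductive link predictor: ``fit``
takes the binary microbe x disease association matrix and computes a
score for every pair, including the known ones. There is no separate
predict input — the method completes the very matrix it was fitted on.
"""
from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .config import MsifLnpParams
from .fusion import build_network
from .io import AssociationMatrix, ScoreMatrix
from .propagation import minmax_rows, normalize_transition, propagate_closed_form


def _as_association(
    X,
    microbe_ids: Optional[Sequence[str]] = None,
    disease_ids: Optional[Sequence[str]] = None,
) -> AssociationMatrix:
    if isinstance(X, AssociationMatrix):
        return X
    X = np.asarray(X, dtype=float)
    if microbe_ids is None:
        microbe_ids = [f"m{i}" for i in range(X.shape[0])]
    if disease_ids is None:
        disease_ids = [f"d{j}" for j in range(X.shape[1])]
    return AssociationMatrix(X, list(microbe_ids), list(disease_ids))


class MsifLnp(BaseEstimator):
    """Microbe-disease association scoring by similarity fusion and propagation.

    Parameters
    ----------
    n_neighbors_microbe : int, default=5
        Neighbor count for the microbe-side linear-neighborhood
        similarity and neighbor-constraint kernel (Nm).
    n_neighbors_disease : int, default=26
        Same for the disease side (Nd).
    fusion_iters : int, default=2
        Cross-iteration fusion steps (x).
    theta : float, default=0.2
        Propagation probability in (0, 1); labels are retained at rate
        1 - theta each step.
    gip_gamma : float, default=1.0
        GIP kernel bandwidth scale.
    svd_keep_fraction : float, default=0.5
        Fraction of singular values kept when denoising each fused
        network.
    normalize_transition : bool, default=True
        Row-normalize the denoised networks to stochastic transitions
        before propagation (guarantees the closed form converges).

    Attributes
    ----------
    microbe_network_, disease_network_ : FusedNetwork
        The fused, denoised similarity networks KM and KD.
    ym_, yd_ : ScoreMatrix
        Min-max-normalized propagation scores from the microbe network
        (per-microbe rows) and from the disease network (per-disease
        rows of the transposed problem, re-aligned to microbe x disease).
    score_matrix_ : ScoreMatrix
        Final scores Y = (YM + YD) / 2, microbe x disease, in [0, 1].
    scores_ : ndarray
        ``score_matrix_.values``.

    Examples
    --------
    >>> import numpy as np
    >>> A = np.eye(4)[:, :3]
    >>> model = MsifLnp(n_neighbors_microbe=2, n_neighbors_disease=2)
    >>> model.fit(A).scores_.shape
    (4, 3)
    """

    def __init__(
        self,
        n_neighbors_microbe: int = 5,
        n_neighbors_disease: int = 26,
        fusion_iters: int = 2,
        theta: float = 0.2,
        gip_gamma: float = 1.0,
        svd_keep_fraction: float = 0.5,
        normalize_transition: bool = True,
    ):
        self.n_neighbors_microbe = n_neighbors_microbe
        self.n_neighbors_disease = n_neighbors_disease
        self.fusion_iters = fusion_iters
        self.theta = theta
        self.gip_gamma = gip_gamma
        self.svd_keep_fraction = svd_keep_fraction
        self.normalize_transition = normalize_transition

    def _params(self) -> MsifLnpParams:
        return MsifLnpParams(
            n_neighbors_microbe=self.n_neighbors_microbe,
            n_neighbors_disease=self.n_neighbors_disease,
            fusion_iters=self.fusion_iters,
            theta=self.theta,
            gip_gamma=self.gip_gamma,
            svd_keep_fraction=self.svd_keep_fraction,
        )

    def fit(self, X, y=None):
        """Compute fused networks and propagation scores for an association matrix.

        Parameters
        ----------
        X : AssociationMatrix or binary array of shape (n_microbes, n_diseases)
        y : ignored (scikit-learn API compatibility)
        """
        assoc = _as_association(X)
        assoc.require_nonempty()
        params = self._params()
        params.check_against(assoc.n_microbes, assoc.n_diseases)

        self.microbe_network_ = build_network(assoc, "microbe", params)
        self.disease_network_ = build_network(assoc, "disease", params)

        KM = self.microbe_network_.denoised
        KD = self.disease_network_.denoised
        if self.normalize_transition:
            KM = normalize_transition(KM)
            KD = normalize_transition(KD)

        ym = minmax_rows(propagate_closed_form(KM, assoc.values, self.theta))
        # disease side: labels are A' so the nd x nd network applies; scores
        # are min-max normalized per disease, then re-aligned to microbe x disease
        yd_diseasewise = minmax_rows(
            propagate_closed_form(KD, assoc.values.T, self.theta)
        )
        yd = yd_diseasewise.T

        self.ym_ = ScoreMatrix(ym, assoc.microbe_ids, assoc.disease_ids, "ym")
        self.yd_ = ScoreMatrix(yd, assoc.microbe_ids, assoc.disease_ids, "yd")
        self.score_matrix_ = ScoreMatrix(
            (ym + yd) / 2.0, assoc.microbe_ids, assoc.disease_ids, "final"
        )
        self.scores_ = self.score_matrix_.values
        self.association_ = assoc
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        """Fit and return the final score matrix values."""
        return self.fit(X, y).scores_


def predict(assoc: AssociationMatrix, params: Optional[MsifLnpParams] = None) -> ScoreMatrix:
    """Functional wrapper: score all pairs of an association matrix."""
    params = params or MsifLnpParams()
    model = MsifLnp(**params.estimator_kwargs())
    return model.fit(assoc).score_matrix_
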