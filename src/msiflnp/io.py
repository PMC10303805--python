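"""Labeled matrix containers and tabular readers/writers.

Every matrix in the pipeline carries its entity labels so that any
intermediate or final output can be joined back to the input association
table. Two on-disk representations of an association set are supported:
a long edge list (one microbe-disease pair per line) and a dense labeled
0/1 matrix. Prediction scores are written as a ranked long-format table.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

SIMILARITY_KINDS = frozenset(
    {
        "cosine",
        "gip",
        "linear_neighborhood",
        "initial_kernel",
        "neighbor_kernel",
        "fused",
        "denoised",
    }
)
SCORE_STAGES = frozenset({"ym", "yd", "final"})

_SYMMETRIC_KINDS = frozenset({"cosine", "gip"})
_SYMMETRY_TOL = 1e-12


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate {what} labels: {dupes[:5]}")
    return ids


@dataclass
class AssociationMatrix:
    """Binary microbe x disease association matrix with entity labels.

    Rows are microbes, columns are diseases; entry (i, j) is 1 when
    microbe i is known to be associated with disease j. This single
    matrix is the raw input to the whole pipeline: all similarities are
    derived from it and it doubles as the label matrix for propagation.
    """

    values: np.ndarray
    microbe_ids: list[str]
    disease_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("association matrix must be two-dimensional")
        self.microbe_ids = _check_unique(self.microbe_ids, "microbe")
        self.disease_ids = _check_unique(self.disease_ids, "disease")
        nm, nd = self.values.shape
        if nm != len(self.microbe_ids) or nd != len(self.disease_ids):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.microbe_ids)} microbes x {len(self.disease_ids)} diseases"
            )
        if not np.isin(self.values, (0.0, 1.0)).all():
            bad = self.values[~np.isin(self.values, (0.0, 1.0))]
            raise ValueError(f"non-binary entry in association matrix: {bad.flat[0]!r}")

    @property
    def n_microbes(self) -> int:
        return self.values.shape[0]

    @property
    def n_diseases(self) -> int:
        return self.values.shape[1]

    @property
    def n_associations(self) -> int:
        return int(self.values.sum())

    def require_nonempty(self) -> None:
        """The pipeline is undefined on an all-zero matrix (no GIP bandwidth)."""
        if self.n_associations == 0:
            raise ValueError("association matrix has no associations; pipeline undefined")

    def copy(self) -> "AssociationMatrix":
        return AssociationMatrix(
            self.values.copy(), list(self.microbe_ids), list(self.disease_ids)
        )


@dataclass
class SimilarityMatrix:
    """Square nonnegative similarity over one entity type, tagged by provenance."""

    values: np.ndarray
    entity_ids: list[str]
    kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in SIMILARITY_KINDS:
            raise ValueError(f"unknown similarity kind {self.kind!r}")
        n = len(self.entity_ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"similarity must be square over {n} entities, got {self.values.shape}"
            )
        if self.kind in _SYMMETRIC_KINDS:
            asym = np.abs(self.values - self.values.T).max(initial=0.0)
            if asym > _SYMMETRY_TOL:
                raise ValueError(f"{self.kind} similarity asymmetric (max dev {asym:.3g})")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class ScoreMatrix:
    """Real-valued microbe x disease prediction scores."""

    values: np.ndarray
    microbe_ids: list[str]
    disease_ids: list[str]
    stage: str = "final"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.stage not in SCORE_STAGES:
            raise ValueError(f"unknown score stage {self.stage!r}")
        if self.values.shape != (len(self.microbe_ids), len(self.disease_ids)):
            raise ValueError("score matrix shape does not match labels")


def read_edge_list(
    path: str | Path,
    sep: str = "\t",
    header: bool = False,
) -> AssociationMatrix:
    """Read a two-column (microbe, disease) edge list into a binary matrix.

    Row and column orders follow first appearance in the file; duplicate
    pairs collapse to a single 1; names are matched exactly after
    whitespace trimming. Extra columns beyond the first two are ignored.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep=sep, header=0 if header else None, dtype=str, skipinitialspace=True
        )
    except pd.errors.EmptyDataError:
        raise ValueError(f"empty edge list: {path}") from None
    if df.shape[1] < 2:
        raise ValueError(
            f"edge list needs at least two columns (microbe, disease), got {df.shape[1]}"
        )
    microbes = df.iloc[:, 0].astype(str).str.strip()
    diseases = df.iloc[:, 1].astype(str).str.strip()
    keep = (microbes != "") & (diseases != "")
    pairs = list(zip(microbes[keep], diseases[keep]))
    if not pairs:
        raise ValueError(f"no associations parsed from {path}")
    microbe_ids = list(dict.fromkeys(m for m, _ in pairs))
    disease_ids = list(dict.fromkeys(d for _, d in pairs))
    mi = {m: i for i, m in enumerate(microbe_ids)}
    di = {d: j for j, d in enumerate(disease_ids)}
    values = np.zeros((len(microbe_ids), len(disease_ids)))
    for m, d in pairs:
        values[mi[m], di[d]] = 1.0
    return AssociationMatrix(values, microbe_ids, disease_ids)


def read_matrix(path: str | Path) -> AssociationMatrix:
    """Read a dense labeled 0/1 TSV (first row disease ids, first column microbe ids)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError(f"empty matrix file: {path}") from None
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed matrix file {path}: {exc}") from None
    # pandas silently renames duplicate header fields; check the raw header
    with open(path) as fh:
        header_ids = [c.strip() for c in fh.readline().rstrip("\n").split("\t")[1:]]
    _check_unique(header_ids, "disease")
    microbe_ids = _check_unique([str(i).strip() for i in df.index], "microbe")
    disease_ids = _check_unique([str(c).strip() for c in df.columns], "disease")
    raw = df.to_numpy()
    values = np.zeros(raw.shape)
    for idx, cell in np.ndenumerate(raw):
        text = str(cell).strip()
        if text not in ("0", "1"):
            raise ValueError(f"non-binary entry {cell!r} at {idx} in {path}")
        values[idx] = float(text)
    return AssociationMatrix(values, microbe_ids, disease_ids)


def write_matrix(assoc: AssociationMatrix, path: str | Path) -> None:
    """Write an association matrix as a dense labeled TSV (integer cells)."""
    df = pd.DataFrame(
        assoc.values.astype(int), index=assoc.microbe_ids, columns=assoc.disease_ids
    )
    df.to_csv(path, sep="\t")


def write_labeled_matrix(
    values: np.ndarray,
    row_ids: Sequence[str],
    col_ids: Sequence[str],
    path: str | Path,
) -> None:
    """Write any labeled real matrix as TSV (used for intermediate dumps)."""
    pd.DataFrame(np.asarray(values), index=list(row_ids), columns=list(col_ids)).to_csv(
        path, sep="\t", float_format="%.10g"
    )


def scores_to_table(
    scores: ScoreMatrix,
    top_n: Optional[int] = None,
    exclude_known: Optional[AssociationMatrix] = None,
) -> pd.DataFrame:
    """Rank all (or all unknown) pairs by score, descending.

    Ties are broken by (microbe_id, disease_id) lexicographic order so
    the ranking is deterministic. With ``exclude_known``, pairs already
    present in the association matrix are dropped before ranking, which
    is the ranking used to nominate novel candidate associations.
    """
    if top_n is not None and top_n <= 0:
        raise ValueError("top_n must be positive")
    nm, nd = scores.values.shape
    mi, dj = np.meshgrid(np.arange(nm), np.arange(nd), indexing="ij")
    df = pd.DataFrame(
        {
            "microbe": [scores.microbe_ids[i] for i in mi.ravel()],
            "disease": [scores.disease_ids[j] for j in dj.ravel()],
            "score": scores.values.ravel(),
        }
    )
    if exclude_known is not None:
        if exclude_known.values.shape != scores.values.shape:
            raise ValueError("exclude_known shape does not match scores")
        df = df[exclude_known.values.ravel() == 0]
    df = df.sort_values(
        ["score", "microbe", "disease"], ascending=[False, True, True], kind="stable"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    if top_n is not None:
        df = df.head(top_n)
    return df


def write_scores(
    scores: ScoreMatrix,
    path: str | Path,
    top_n: Optional[int] = None,
    exclude_known: Optional[AssociationMatrix] = None,
) -> None:
    """Write the ranked long-format score table as TSV."""
    table = scores_to_table(scores, top_n=top_n, exclude_known=exclude_known)
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")
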