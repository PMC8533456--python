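"""Feature selection: mRMR ranking with a PCA baseline.

mRMR (minimal redundancy, maximal relevance) greedily ranks features by
Phi = D - R, where D is the mean mutual information between the selected
features and the class label (relevance) and R the mean pairwise mutual
information among the selected features (redundancy, normalized by
|S|^2 including self-information, exactly as the criterion is printed in
the mRMR literature).  Mutual information is the plug-in estimate on
discretized features, in nats; the default discretization cuts each
z-scored column at +/-0.5 standard deviations into three states.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .containers import FeatureMatrix

__all__ = [
    "SelectionResult",
    "Discretizer",
    "discretize",
    "mutual_info",
    "mrmr_rank",
    "pca_project",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionResult:
    """Ranked feature indices with the greedy criterion trace."""

    ranked_indices: tuple[int, ...]
    phi_scores: tuple[float, ...]
    relevance: tuple[float, ...]
    method: str

    def __post_init__(self) -> None:
        if len(set(self.ranked_indices)) != len(self.ranked_indices):
            raise ValueError("ranked indices must be unique")


class Discretizer:
    """Per-column discretization with cut points learned from data.

    With ``n_bins=3`` (default) columns are z-scored and thresholded at
    +/-0.5 standard deviations; any other ``n_bins`` uses equal-frequency
    bins.  Zero-variance columns collapse to a single state (logged).
    """

    def __init__(self, n_bins: int = 3) -> None:
        if n_bins < 2:
            raise ValueError("need at least 2 bins")
        self.n_bins = n_bins
        self.cuts_: list[np.ndarray] | None = None

    def fit(self, values: np.ndarray) -> "Discretizer":
        values = np.asarray(values, dtype=float)
        cuts = []
        for j in range(values.shape[1]):
            col = values[:, j]
            sd = col.std()
            if sd == 0:
                logger.info("column %d has zero variance; single state", j)
                cuts.append(np.array([]))
            elif self.n_bins == 3:
                mu = col.mean()
                cuts.append(np.array([mu - 0.5 * sd, mu + 0.5 * sd]))
            else:
                qs = np.quantile(col, np.linspace(0, 1, self.n_bins + 1)[1:-1])
                cuts.append(np.unique(qs))
            # np.searchsorted against the cut points assigns the state.
        self.cuts_ = cuts
        return self

    def transform(self, values: np.ndarray) -> np.ndarray:
        if self.cuts_ is None:
            raise RuntimeError("discretizer not fitted")
        values = np.asarray(values, dtype=float)
        if values.shape[1] != len(self.cuts_):
            raise ValueError("column count differs from the fitted matrix")
        out = np.empty(values.shape, dtype=np.int64)
        for j, cut in enumerate(self.cuts_):
            out[:, j] = np.searchsorted(cut, values[:, j], side="right")
        return out


def discretize(fm: FeatureMatrix | np.ndarray, n_bins: int = 3) -> np.ndarray:
    """Discretize a feature matrix column-wise (fit and apply on the same data)."""
    values = fm.values if isinstance(fm, FeatureMatrix) else np.asarray(fm, dtype=float)
    if values.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    return Discretizer(n_bins=n_bins).fit(values).transform(values)


def mutual_info(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information (nats) between two discrete sequences."""
    x = np.asarray(x).ravel()
    y = np.asarray(y).ravel()
    if len(x) != len(y):
        raise ValueError("sequences must have equal length")
    if len(x) == 0:
        raise ValueError("sequences must be non-empty")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    joint = np.zeros((xi.max() + 1, yi.max() + 1))
    np.add.at(joint, (xi, yi), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log(joint[nz] / (px @ py)[nz])))


def mrmr_rank(
    discrete: np.ndarray, labels: np.ndarray, k: int
) -> SelectionResult:
    """Greedy mRMR ranking of ``k`` features.

    The first pick maximizes relevance I(x_i; c); every subsequent pick
    maximizes Phi(S u {i}) = mean relevance of the enlarged set minus its
    mean pairwise redundancy (1/|S|^2 normalization over all ordered
    pairs, self-information included).  Ties break toward the lowest
    feature index.
    """
    discrete = np.asarray(discrete)
    labels = np.asarray(labels)
    if discrete.ndim != 2:
        raise ValueError("discrete feature matrix must be 2-D")
    n, p = discrete.shape
    if len(labels) != n:
        raise ValueError("label count must match the row count")
    if k > p:
        raise ValueError(f"cannot select {k} of {p} features")
    relevance = np.array([mutual_info(discrete[:, j], labels) for j in range(p)])
    if k == 0:
        return SelectionResult((), (), tuple(relevance), "mrmr")

    self_mi = np.array([mutual_info(discrete[:, j], discrete[:, j]) for j in range(p)])
    selected: list[int] = []
    phis: list[float] = []
    remaining = np.ones(p, dtype=bool)
    cross = np.zeros(p)  # sum of MI(x_i, x_s) over selected s, per candidate i
    rel_sum = 0.0
    red_sum = 0.0  # sum of MI over all ordered pairs of selected features

    first = int(np.argmax(relevance))
    selected.append(first)
    remaining[first] = False
    rel_sum = relevance[first]
    red_sum = self_mi[first]
    phis.append(float(rel_sum / 1 - red_sum / 1))

    while len(selected) < k:
        last = selected[-1]
        for i in np.flatnonzero(remaining):
            cross[i] += mutual_info(discrete[:, i], discrete[:, last])
        m = len(selected) + 1
        cand = np.flatnonzero(remaining)
        d = (rel_sum + relevance[cand]) / m
        r = (red_sum + 2.0 * cross[cand] + self_mi[cand]) / (m * m)
        phi = d - r
        best = cand[int(np.argmax(phi))]
        selected.append(int(best))
        remaining[best] = False
        rel_sum += relevance[best]
        red_sum += 2.0 * cross[best] + self_mi[best]
        phis.append(float(phi[cand == best][0]))
    return SelectionResult(
        ranked_indices=tuple(selected),
        phi_scores=tuple(phis),
        relevance=tuple(relevance),
        method="mrmr",
    )


def pca_project(
    fm: FeatureMatrix | np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean-centered projection onto the top-k principal axes.

    Returns (scores n x k, loadings k x p with orthonormal rows,
    explained variances, non-increasing).

    Raises
    ------
    ValueError
        If ``k`` exceeds min(rows, columns) or the matrix rank.
    """
    values = fm.values if isinstance(fm, FeatureMatrix) else np.asarray(fm, dtype=float)
    if values.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    n, p = values.shape
    if k > min(n, p):
        raise ValueError(f"k={k} exceeds min(rows, columns)={min(n, p)}")
    centered = values - values.mean(axis=0)
    rank = np.linalg.matrix_rank(centered)
    if k > rank:
        raise ValueError(f"k={k} exceeds the matrix rank {rank}")
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(values)
    return scores, pca.components_, pca.explained_variance_
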