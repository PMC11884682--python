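"""Projected distances and nearest-neighbor contrast pairs.

NPDR regresses a between-sample class-contrast indicator on *projected
distances*: for a pair of samples (i, j), the pair-level diff of one
correlation attribute p is ``|A_p^i - A_p^j|``, and the node-level
correlation-diff of ROI r is the sum of those absolute differences over all
pairs involving r.  The regression rows are nearest-neighbor sample pairs
found either with the multiSURF-style adaptive radius (neighbors closer than
that sample's mean distance minus half its standard deviation) or with a
fixed k.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.spatial.distance import pdist, squareform

from .datasets import CorrelationDataset, pair_names

__all__ = [
    "NeighborPairs",
    "ProjectedDesign",
    "pair_diff",
    "correlation_diff",
    "sample_distances",
    "find_neighbor_pairs",
    "pair_design",
    "corr_diff_design",
]

logger = logging.getLogger(__name__)


@dataclass
class NeighborPairs:
    """Ordered sample pairs with the hit/miss contrast indicator.

    ``pairs[r] = (i, j)`` with i < j; ``delta_y[r]`` is 1 when the two samples
    are in different classes (a "miss") and 0 when in the same class (a "hit").
    """

    pairs: np.ndarray  # (m, 2) int
    delta_y: np.ndarray  # (m,) float in {0, 1}
    neighborhood_method: str
    k_or_radius: float | int | None = None
    #: False when the ordered per-sample neighborhoods were kept as-is
    deduplicated: bool = True

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=np.int64)
        self.delta_y = np.asarray(self.delta_y, dtype=float)
        if self.pairs.ndim != 2 or self.pairs.shape[1] != 2:
            raise ValueError("pairs must be an (m, 2) array")
        if np.any(self.pairs[:, 0] == self.pairs[:, 1]):
            raise ValueError("self-pairs (i, i) are not allowed")
        if self.deduplicated:
            canon = np.sort(self.pairs, axis=1)
            if len({(int(a), int(b)) for a, b in canon}) != len(canon):
                raise ValueError("duplicate unordered sample pairs")

    def __len__(self) -> int:
        return len(self.pairs)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"sample_i": self.pairs[:, 0], "sample_j": self.pairs[:, 1], "delta_y": self.delta_y.astype(int)}
        )


@dataclass
class ProjectedDesign:
    """Regression design of nonnegative projected diffs, rows = neighbor pairs."""

    values: np.ndarray  # (m, n_features), Fortran order for the column-wise GLM
    feature_ids: list[str]
    kind: str  # "pair" (one column per ROI pair) or "corr_diff" (one per ROI)
    delta_y: np.ndarray

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


# -- elementary projected distances -----------------------------------------


def pair_diff(dataset: CorrelationDataset, sample_i: int, sample_j: int, pair_p: int) -> float:
    """Absolute difference of one correlation attribute between two samples."""
    x = dataset.feature_matrix
    return float(abs(x[sample_i, pair_p] - x[sample_j, pair_p]))


def correlation_diff(
    dataset: CorrelationDataset, sample_i: int, sample_j: int, roi_r: str | int
) -> float:
    """Node-level projected distance for ROI r: sum over every partner k of
    the absolute correlation difference ``|A_rk^i - A_rk^j|``."""
    r = dataset.roi_position(roi_r) if isinstance(roi_r, str) else int(roi_r)
    if not 0 <= r < dataset.n_rois:
        raise KeyError(f"ROI index {r} out of range 0..{dataset.n_rois - 1}")
    pos = dataset.pair_positions
    involves = (pos[:, 0] == r) | (pos[:, 1] == r)
    diffs = np.abs(
        dataset.feature_matrix[sample_i, involves] - dataset.feature_matrix[sample_j, involves]
    )
    return float(diffs.sum())


# -- distances and neighborhoods ---------------------------------------------


def sample_distances(
    dataset: CorrelationDataset, *, standardize: bool = True, metric: str = "cityblock"
) -> np.ndarray:
    """Symmetric zero-diagonal sample-distance matrix over pair features.

    Features are standardized by default; zero-variance features are dropped
    from the standardization with a logged warning.
    """
    x = dataset.feature_matrix
    if x.shape[0] == 0:
        raise ValueError("dataset has no samples")
    if standardize:
        sd = x.std(axis=0)
        keep = sd > 0
        if not keep.all():
            logger.warning(
                "excluding %d zero-variance feature(s) from distance standardization",
                int((~keep).sum()),
            )
        x = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    return squareform(pdist(x, metric))


def find_neighbor_pairs(
    distance_matrix: np.ndarray,
    phenotype: np.ndarray,
    method: str = "adaptive_radius",
    param: int | None = None,
    *,
    deduplicate: bool = True,
) -> NeighborPairs:
    """Nearest-neighbor sample pairs forming the NPDR regression rows.

    adaptive_radius: j is a neighbor of i iff ``dist(i, j) < mean_i - sd_i/2``
    where mean_i, sd_i summarize i's distances to all other samples.
    fixed_k: the ``param`` smallest distances per sample.  The union of the
    ordered neighborhoods is reduced to unordered pairs (i < j) by default.
    """
    d = np.asarray(distance_matrix, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n):
        raise ValueError("distance matrix must be square")
    phenotype = np.asarray(phenotype)
    if phenotype.shape != (n,):
        raise ValueError("phenotype length must match the distance matrix")

    off = ~np.eye(n, dtype=bool)
    if method == "adaptive_radius":
        vals = np.where(off, d, np.nan)
        mu = np.nanmean(vals, axis=1)
        sd = np.nanstd(vals, axis=1, ddof=1)
        neighbor = (d < (mu - sd / 2.0)[:, None]) & off
        if not neighbor.any():
            raise ValueError(
                "adaptive radius produced no neighbors (distances too uniform); "
                "use method='fixed_k' instead"
            )
        k_or_radius = None
    elif method == "fixed_k":
        if param is None or param < 1:
            raise ValueError("fixed_k requires param >= 1")
        if param >= n:
            raise ValueError(f"k={param} must be smaller than n_samples={n}")
        order = np.argsort(np.where(off, d, np.inf), axis=1, kind="stable")[:, :param]
        neighbor = np.zeros((n, n), dtype=bool)
        np.put_along_axis(neighbor, order, True, axis=1)
        k_or_radius = param
    else:
        raise ValueError(f"unknown method {method!r}; use 'adaptive_radius' or 'fixed_k'")

    ii, jj = np.where(neighbor)
    if deduplicate:
        lo = np.minimum(ii, jj)
        hi = np.maximum(ii, jj)
        pairs = np.unique(np.column_stack([lo, hi]), axis=0)
    else:
        pairs = np.column_stack([ii, jj])
    delta_y = (phenotype[pairs[:, 0]] != phenotype[pairs[:, 1]]).astype(float)
    return NeighborPairs(pairs, delta_y, method, k_or_radius, deduplicated=deduplicate)


# -- regression designs -------------------------------------------------------


@njit(cache=True)
def _abs_diff_design(xt: np.ndarray, ii: np.ndarray, jj: np.ndarray) -> np.ndarray:
    # xt: (n_features, n_samples) C-order; returns (n_features, m) whose
    # transpose is the Fortran-ordered (m, n_features) design.
    p, _ = xt.shape
    m = ii.shape[0]
    out = np.empty((p, m))
    for c in range(p):
        row = xt[c]
        for r in range(m):
            v = row[ii[r]] - row[jj[r]]
            out[c, r] = v if v >= 0.0 else -v
    return out


def pair_design(dataset: CorrelationDataset, neighbor_pairs: NeighborPairs) -> ProjectedDesign:
    """One absolute-diff column per ROI pair (n(n-1)/2 columns)."""
    xt = np.ascontiguousarray(dataset.feature_matrix.T)
    mat = _abs_diff_design(xt, neighbor_pairs.pairs[:, 0], neighbor_pairs.pairs[:, 1]).T
    return ProjectedDesign(mat, pair_names(dataset.roi_names), "pair", neighbor_pairs.delta_y)


def corr_diff_design(dataset: CorrelationDataset, neighbor_pairs: NeighborPairs) -> ProjectedDesign:
    """One correlation-diff column per ROI (n columns).

    Column r sums the pair-level absolute diffs of every pair involving r, so
    summing all columns double-counts each pair diff exactly once:
    ``sum_r d^CD(r) = 2 * sum_p d^p``.
    """
    pair = pair_design(dataset, neighbor_pairs)
    pos = dataset.pair_positions
    n_rois = dataset.n_rois
    incidence = np.zeros((dataset.n_pairs, n_rois))
    incidence[np.arange(dataset.n_pairs), pos[:, 0]] = 1.0
    incidence[np.arange(dataset.n_pairs), pos[:, 1]] = 1.0
    mat = np.asfortranarray(pair.values @ incidence)
    return ProjectedDesign(mat, list(dataset.roi_names), "corr_diff", neighbor_pairs.delta_y)
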