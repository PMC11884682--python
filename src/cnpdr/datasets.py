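"""The samples × ROI-pair container and upper-triangle (de)vectorization.

A correlation dataset holds one row per subject whose columns are the
n(n-1)/2 pairwise correlations between n named ROIs — the upper triangle of
each subject's symmetric correlation matrix stretched into a vector, in
row-major order: (1,2), (1,3), ..., (1,n), (2,3), ...
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CorrelationDataset",
    "pair_names",
    "vectorize_upper_triangle",
    "devectorize_upper_triangle",
]

#: separator used in on-disk pair names ("A--B"); ASCII-safe on every filesystem.
PAIR_SEP = "--"


def pair_names(roi_names: list[str]) -> list[str]:
    """Upper-triangle pair labels "A--B" in row-major order, A before B."""
    return [
        f"{roi_names[a]}{PAIR_SEP}{roi_names[b]}"
        for a in range(len(roi_names))
        for b in range(a + 1, len(roi_names))
    ]


def vectorize_upper_triangle(
    matrix: np.ndarray, roi_names: list[str], *, atol: float = 1e-8
) -> tuple[np.ndarray, list[str]]:
    """Stretch a symmetric unit-diagonal correlation matrix into a vector.

    Returns ``(vector, pair_labels)`` with entries in row-major upper-triangle
    order.  Raises ``ValueError`` naming the offending cell if the matrix is
    asymmetric beyond ``atol``.
    """
    m = np.asarray(matrix, dtype=float)
    n = len(roi_names)
    if m.shape != (n, n):
        raise ValueError(f"matrix shape {m.shape} does not match {n} ROI names")
    asym = np.abs(m - m.T)
    if asym.max(initial=0.0) > atol:
        i, j = np.unravel_index(np.argmax(asym), asym.shape)
        raise ValueError(
            f"matrix is asymmetric at ({roi_names[i]}, {roi_names[j]}): "
            f"{m[i, j]!r} vs {m[j, i]!r}"
        )
    iu = np.triu_indices(n, k=1)
    return m[iu].copy(), pair_names(list(roi_names))


def devectorize_upper_triangle(vector: np.ndarray, n_rois: int) -> np.ndarray:
    """Inverse of :func:`vectorize_upper_triangle`: rebuild the symmetric
    unit-diagonal matrix from the upper-triangle vector."""
    vector = np.asarray(vector, dtype=float)
    if vector.shape != (n_rois * (n_rois - 1) // 2,):
        raise ValueError(
            f"expected {n_rois * (n_rois - 1) // 2} entries for {n_rois} ROIs, "
            f"got {vector.shape}"
        )
    m = np.eye(n_rois)
    iu = np.triu_indices(n_rois, k=1)
    m[iu] = vector
    m[(iu[1], iu[0])] = vector
    return m


def _pair_positions(n_rois: int) -> np.ndarray:
    """(n_pairs, 2) array of ROI index pairs in row-major upper-triangle order."""
    iu = np.triu_indices(n_rois, k=1)
    return np.column_stack(iu)


@dataclass
class CorrelationDataset:
    """Samples × ROI-pair feature table with a binary phenotype.

    Attributes
    ----------
    feature_matrix : (n_samples, n_pairs) float array of pairwise correlations.
    roi_names : names of the n ROIs; ``n_pairs == n (n-1) / 2``.
    phenotype : binary vector, case = 1, control = 0.
    sample_ids : optional subject identifiers (generated if omitted).
    """

    feature_matrix: np.ndarray
    roi_names: list[str]
    phenotype: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.feature_matrix = np.asarray(self.feature_matrix, dtype=float)
        self.phenotype = np.asarray(self.phenotype, dtype=int)
        self.roi_names = list(self.roi_names)
        n = self.n_rois
        if self.feature_matrix.ndim != 2:
            raise ValueError("feature_matrix must be 2-D (samples × pairs)")
        if len(set(self.roi_names)) != n:
            raise ValueError("ROI names must be unique")
        if self.feature_matrix.shape[1] != n * (n - 1) // 2:
            raise ValueError(
                f"{self.feature_matrix.shape[1]} feature columns inconsistent "
                f"with {n} ROIs (expected {n * (n - 1) // 2})"
            )
        if self.phenotype.shape != (self.n_samples,):
            raise ValueError("phenotype length must equal the number of samples")
        if not set(np.unique(self.phenotype)) <= {0, 1}:
            raise ValueError("phenotype must be binary (case = 1, control = 0)")
        if not self.sample_ids:
            width = len(str(max(self.n_samples, 1)))
            self.sample_ids = [f"S{i + 1:0{width}d}" for i in range(self.n_samples)]
        elif len(self.sample_ids) != self.n_samples:
            raise ValueError("sample_ids length must equal the number of samples")

    # -- basic geometry ------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.feature_matrix.shape[0]

    @property
    def n_rois(self) -> int:
        return len(self.roi_names)

    @property
    def n_pairs(self) -> int:
        return self.feature_matrix.shape[1]

    @property
    def pair_positions(self) -> np.ndarray:
        """(n_pairs, 2) ROI index pairs aligned with the feature columns."""
        return _pair_positions(self.n_rois)

    @property
    def pair_index(self) -> list[tuple[str, str]]:
        """Ordered (roi_a, roi_b) name pairs aligned with the feature columns."""
        names = self.roi_names
        return [(names[a], names[b]) for a, b in self.pair_positions]

    @property
    def pair_labels(self) -> list[str]:
        return pair_names(self.roi_names)

    def roi_position(self, roi: str) -> int:
        try:
            return self.roi_names.index(roi)
        except ValueError:
            raise KeyError(
                f"unknown ROI {roi!r}; valid names: {', '.join(self.roi_names)}"
            ) from None

    def subject_matrix(self, sample: int) -> np.ndarray:
        """The sample's full symmetric correlation matrix (unit diagonal)."""
        return devectorize_upper_triangle(self.feature_matrix[sample], self.n_rois)
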