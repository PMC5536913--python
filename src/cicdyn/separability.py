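"""Rank-one SVD approximation of space-time matrices.

The central hypothesis is that the spatiotemporal nuclear Cic pattern is
separable: X(x, t) ~ S(x) * a(t).  The best rank-one approximation in the
least-squares sense is sigma_1 * u_1 * v_1^T from the SVD, and the quality
of the approximation is summarised by the accuracy ratio

    r = sigma_1 / sqrt(sum_i sigma_i^2) = ||X||_2 / ||X||_F,

which equals 1 exactly when X has rank one and is below 1 otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .containers import SpaceTimeMatrix


@dataclass
class RankOneDecomposition:
    """Result of a rank-one decomposition.

    spatial_mode is the unit-norm first left singular vector (sign-fixed
    to nonnegative mean); temporal_amplitude = spatial_mode^T X carries
    the physical intensity magnitude.
    """

    singular_values: np.ndarray
    spatial_mode: np.ndarray
    temporal_amplitude: np.ndarray
    accuracy_ratio: float

    @property
    def reconstruction(self) -> np.ndarray:
        return np.outer(self.spatial_mode, self.temporal_amplitude)

    @property
    def plateau_scaled_amplitude(self) -> np.ndarray:
        """Temporal amplitude scaled by the spatial-mode peak: the
        reconstruction's intensity time course at the brightest AP
        position.  This puts amplitudes from different embryos in the
        same (raw kymograph) intensity units, so plateau levels are
        directly comparable across embryos and genotypes."""
        return self.temporal_amplitude * float(self.spatial_mode.max())


class RankOneDecomposer(BaseEstimator):
    """Rank-one separability decomposition, scikit-learn style.

    ``fit`` computes the SVD of a (positions x frames) matrix and stores
    the leading spatial mode, its projected temporal amplitude and the
    accuracy ratio.  No smoothing or detrending is applied.

    Attributes
    ----------
    singular_values_ : ndarray, descending, nonnegative
    spatial_mode_ : ndarray, unit 2-norm, nonnegative-mean sign convention
    temporal_amplitude_ : ndarray, projection of X onto the spatial mode
    accuracy_ratio_ : float in (0, 1]
    """

    def fit(self, X, y=None):
        M = self._validate(X)
        u, s, vt = np.linalg.svd(M, full_matrices=False)
        mode = u[:, 0]
        if mode.mean() < 0:  # Perron-Frobenius sign convention
            mode = -mode
        self.singular_values_ = s
        self.spatial_mode_ = mode
        self.temporal_amplitude_ = mode @ M
        self.accuracy_ratio_ = accuracy_ratio(s)
        self.n_features_in_ = M.shape[0]
        return self

    def transform(self, X):
        """Project a matrix (or a single profile) onto the fitted
        spatial mode, returning the temporal amplitude."""
        if not hasattr(self, "spatial_mode_"):
            raise AttributeError("RankOneDecomposer is not fitted")
        M = np.asarray(X.values if isinstance(X, SpaceTimeMatrix) else X, dtype=float)
        return self.spatial_mode_ @ M

    def fit_transform(self, X, y=None):
        return self.fit(X).temporal_amplitude_

    def reconstruct(self) -> np.ndarray:
        """Rank-one reconstruction sigma_1 u_1 v_1^T of the fitted matrix."""
        if not hasattr(self, "spatial_mode_"):
            raise AttributeError("RankOneDecomposer is not fitted")
        return np.outer(self.spatial_mode_, self.temporal_amplitude_)

    def decomposition_(self) -> RankOneDecomposition:
        return RankOneDecomposition(
            singular_values=self.singular_values_,
            spatial_mode=self.spatial_mode_,
            temporal_amplitude=self.temporal_amplitude_,
            accuracy_ratio=self.accuracy_ratio_,
        )

    @staticmethod
    def _validate(X) -> np.ndarray:
        M = np.asarray(X.values if isinstance(X, SpaceTimeMatrix) else X, dtype=float)
        if M.ndim != 2 or min(M.shape) < 2:
            raise ValueError("need a 2-D matrix with at least 2 rows and columns")
        if not np.all(np.isfinite(M)):
            raise ValueError("matrix contains non-finite entries")
        if not np.any(M):
            raise ValueError("matrix is identically zero")
        return M


def decompose(X) -> RankOneDecomposition:
    """Rank-one decomposition of a space-time matrix (functional form)."""
    return RankOneDecomposer().fit(X).decomposition_()


def accuracy_ratio(singular_values: np.ndarray) -> float:
    """sigma_1 / sqrt(sum sigma_i^2), the rank-one accuracy statistic."""
    s = np.asarray(singular_values, dtype=float)
    if s.size == 0 or s[0] <= 0:
        raise ValueError("leading singular value must be positive")
    return float(s[0] / np.linalg.norm(s))


def reconstruct(decomposition: RankOneDecomposition) -> np.ndarray:
    """Outer product of spatial mode and temporal amplitude."""
    return decomposition.reconstruction
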