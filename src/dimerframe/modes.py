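"""PCA decomposition of collective Cα motions and mode-based analyses.

PCA is performed on the 3N-dimensional flattened Cα coordinates of an
aligned ensemble.  The leading eigenvectors of the covariance matrix are
the collective "essential" modes; for the H2A-H2B dimer the first mode is
the simultaneous bending of the two α2-helices along the pseudosymmetry
axis.  Because the sign of a PCA eigenvector is arbitrary, signed analyses
(the bending-angle correlation) first canonicalize it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .core import ConformationEnsemble

__all__ = [
    "ModeDecomposition",
    "pca_modes",
    "inner_product_matrix",
    "project_trajectory",
    "angle_mode_correlation",
]


@dataclass
class ModeDecomposition:
    """Eigenvectors/eigenvalues of an ensemble's coordinate covariance."""

    mean_conformation: np.ndarray  # (N, 3)
    eigenvectors: np.ndarray  # (3N, K), columns are unit eigenvectors
    eigenvalues: np.ndarray  # (K,), Å², descending
    labels: list

    def __post_init__(self) -> None:
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.eigenvectors = np.asarray(self.eigenvectors, dtype=float)
        if np.any(self.eigenvalues < -1e-9):
            raise ValueError("eigenvalues must be non-negative")
        if np.any(np.diff(self.eigenvalues) > 1e-9):
            raise ValueError("eigenvalues must be sorted descending")

    @property
    def variance_fractions(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        if total <= 0:
            raise ValueError("total variance is zero")
        return self.eigenvalues / total

    @property
    def n_modes(self) -> int:
        return self.eigenvectors.shape[1]


def pca_modes(ensemble: ConformationEnsemble) -> ModeDecomposition:
    """Eigen-decomposition of the 3N×3N coordinate covariance (1/(T−1)).

    Computed via SVD of the centered (T, 3N) data matrix, which is exact
    and avoids forming the covariance.  No mass weighting is applied: the
    selection is Cα-only, so weights would be uniform anyway.
    """
    ensemble.require_aligned("pca_modes")
    T, N, _ = ensemble.frames.shape
    if T < 2:
        raise ValueError("PCA needs at least 2 frames")
    if T <= 3 * N:
        warnings.warn(
            f"T={T} frames <= 3N={3 * N} coordinates: covariance is rank-deficient",
            stacklevel=2,
        )
    flat = ensemble.frames.reshape(T, 3 * N)
    mean = flat.mean(axis=0)
    centered = flat - mean
    _, s, Vt = np.linalg.svd(centered, full_matrices=False)
    eigenvalues = s ** 2 / (T - 1)
    order = np.argsort(eigenvalues)[::-1]
    return ModeDecomposition(
        mean_conformation=mean.reshape(N, 3),
        eigenvectors=Vt[order].T,
        eigenvalues=eigenvalues[order],
        labels=list(ensemble.labels),
    )


def inner_product_matrix(a: ModeDecomposition, b: ModeDecomposition,
                         k: int = 10) -> np.ndarray:
    """|dot products| of the first k eigenvectors of *a* against those of *b*.

    1 for codirectional modes, 0 for orthogonal ones; the absolute value
    removes the arbitrary eigenvector sign.
    """
    if a.labels != b.labels:
        raise ValueError("decompositions use different atom selections")
    ka = min(k, a.n_modes)
    kb = min(k, b.n_modes)
    return np.abs(a.eigenvectors[:, :ka].T @ b.eigenvectors[:, :kb])


def project_trajectory(ensemble: ConformationEnsemble, mode: np.ndarray,
                       mean: np.ndarray) -> np.ndarray:
    """Per-frame projection of an aligned trajectory onto one unit mode.

    The projection of frame t is the dot product of its flattened
    displacement from *mean* with the eigenvector, in Å.
    """
    ensemble.require_aligned("project_trajectory")
    T = ensemble.n_frames
    flat = ensemble.frames.reshape(T, -1)
    v = np.asarray(mode, dtype=float).ravel()
    m = np.asarray(mean, dtype=float).ravel()
    if v.shape != (flat.shape[1],) or m.shape != (flat.shape[1],):
        raise ValueError("mode/mean dimension does not match the ensemble")
    return (flat - m) @ v


def angle_mode_correlation(angles: np.ndarray, projections: np.ndarray):
    """Pearson correlation between the α2-α2 angle and a mode projection.

    The eigenvector sign being arbitrary, projections are first
    canonicalized so that they decrease as the angle increases (bending of
    the helices lowers the angle while the projection grows); the returned
    correlation is therefore ≤ 0 whenever any monotone association exists.
    Returns ``(r, projections_canonical)``.
    """
    theta = np.asarray(angles, dtype=float)
    proj = np.asarray(projections, dtype=float)
    if theta.shape != proj.shape or theta.ndim != 1:
        raise ValueError("angle and projection series must be equal-length 1D")
    if len(theta) < 3:
        raise ValueError("need at least 3 frames")
    if np.std(theta) < 1e-12 or np.std(proj) < 1e-12:
        raise ValueError("zero-variance input")
    r = float(sps.pearsonr(theta, proj).statistic)
    if r > 0:
        proj = -proj
        r = -r
    return r, proj
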