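"""Generalized Procrustes analysis (GPA).

Shape variables are obtained by removing location (centering), size
(scaling to unit centroid size, CS) and orientation (least-squares optimal
rotation) from each landmark configuration, iterating rotation against a
running consensus until the consensus stabilizes.  Reflections are never
allowed: the optimal rotation is a proper rotation (det = +1), with the
conventional SVD sign fix as a deterministic tie-break for degenerate
cross-covariance matrices.

Analyses downstream run directly on the Procrustes-aligned coordinates; no
additional tangent-space projection is applied (a good approximation at the
small shape variation typical of conspecific skeletal data).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateConfigurationError, ValidationError
from .landmark_io import LandmarkDataset

__all__ = [
    "centroid_size",
    "optimal_rotation",
    "gpa",
    "procrustes_distance",
    "ProcrustesResult",
]

_EPS = 1e-12


def centroid_size(config: np.ndarray) -> float:
    """Centroid size: sqrt of summed squared landmark distances to the centroid.

    CS is homogeneous of degree one in scale and is the size variable carried
    through all analyses (log CS as the allometry covariate).
    """
    x = np.asarray(config, dtype=float)
    if x.ndim != 2:
        raise ValidationError(f"expected a k x D matrix, got shape {x.shape}")
    if np.isnan(x).any():
        raise ValidationError("centroid_size: configuration contains missing landmarks")
    centered = x - x.mean(axis=0)
    cs = float(np.sqrt((centered**2).sum()))
    if cs < _EPS:
        raise DegenerateConfigurationError("all landmarks coincide (centroid size is zero)")
    return cs


def optimal_rotation(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Proper rotation R (det = +1) minimizing ||A @ R - B||_F.

    Kabsch solution: SVD of the cross-covariance A'B with the sign of the
    last singular vector flipped when needed to forbid reflections.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValidationError(f"shape mismatch {A.shape} vs {B.shape}")
    H = A.T @ B
    U, s, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    if d == 0:  # fully degenerate; fall back to +1 (deterministic)
        d = 1.0
    D = np.ones(A.shape[1])
    D[-1] = d
    if s[-1] < _EPS * max(s[0], 1.0):
        warnings.warn(
            "rank-deficient cross-covariance: rotation optimum is not unique; "
            "using the SVD sign-fixed solution",
            RuntimeWarning,
            stacklevel=2,
        )
    return U @ np.diag(D) @ Vt


@dataclass
class ProcrustesResult:
    """Aligned shape coordinates in unit-centroid-size shape space."""

    aligned: np.ndarray  # n x k x D
    consensus: np.ndarray  # k x D, unit CS
    centroid_sizes: np.ndarray  # n, in original units (mm)
    n_iterations: int
    converged: bool
    specimen_ids: list[str] | None = None

    @property
    def log_cs(self) -> np.ndarray:
        return np.log(self.centroid_sizes)

    @property
    def n(self) -> int:
        return self.aligned.shape[0]

    def flat(self) -> np.ndarray:
        """Aligned coordinates flattened landmark-major to n x (k*D)."""
        return self.aligned.reshape(self.n, -1)


def gpa(
    data: LandmarkDataset | np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> ProcrustesResult:
    """Iterative generalized Procrustes superimposition.

    All configurations are centered and scaled to unit CS, then repeatedly
    rotated to the running consensus (initialized from the first specimen);
    the consensus is the mean of the rotated set, rescaled to unit CS.
    Iteration stops when the summed squared change of the consensus falls
    below ``tol``.
    """
    specimen_ids = None
    if isinstance(data, LandmarkDataset):
        specimen_ids = data.specimen_ids
        X = data.coords_array()
    else:
        X = np.asarray(data, dtype=float)
        if X.ndim == 2:
            X = X[None]
    if X.ndim != 3:
        raise ValidationError(f"expected n x k x D array, got shape {X.shape}")
    if np.isnan(X).any():
        raise ValidationError("gpa requires complete configurations (run estimate_missing)")
    n = X.shape[0]

    sizes = np.array([centroid_size(x) for x in X])
    scaled = np.stack([(x - x.mean(axis=0)) / s for x, s in zip(X, sizes)])

    consensus = scaled[0].copy()
    aligned = scaled.copy()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        aligned = np.stack([x @ optimal_rotation(x, consensus) for x in scaled])
        new_consensus = aligned.mean(axis=0)
        new_consensus -= new_consensus.mean(axis=0)
        new_consensus /= centroid_size(new_consensus)
        delta = float(((new_consensus - consensus) ** 2).sum())
        consensus = new_consensus
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"GPA did not converge in {max_iter} iterations", RuntimeWarning, stacklevel=2
        )
    return ProcrustesResult(
        aligned=aligned,
        consensus=consensus,
        centroid_sizes=sizes,
        n_iterations=it,
        converged=converged,
        specimen_ids=specimen_ids,
    )


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean norm of the coordinate difference of two aligned shapes.

    Both shapes must already live in a common superimposition frame (the
    partial Procrustes distance of the aligned coordinates).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError(f"shape dimension mismatch {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b))
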