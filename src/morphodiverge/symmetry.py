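"""Object-symmetry decomposition of bilaterally symmetric structures.

A skull bisected by the mid-sagittal plane carries "object symmetry": its
mirror image, with left/right landmark labels swapped, is another valid
configuration of the same structure.  Superimposing the original and the
reflected-relabelled copy of every specimen jointly and averaging the two
aligned copies yields each specimen's *symmetric component*, the response
used in all downstream shape statistics; the residual from the aligned
original is the asymmetric component (fluctuating + directional asymmetry).

The reflection axis is the first coordinate axis by convention; the joint
superimposition absorbs the orientation so the choice is immaterial (tested
as a package property).  The consensus is symmetrized at every iteration,
which makes the symmetric components exactly mirror-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .landmark_io import LandmarkDataset, PairingMap
from .superimposition import centroid_size, optimal_rotation

__all__ = ["reflect_relabel", "symmetry_decomposition", "SymmetryDecomposition"]


def _pair_permutation(labels: list[str], pairing: PairingMap) -> np.ndarray:
    pairing.validate_against(labels)
    index = {l: i for i, l in enumerate(labels)}
    perm = np.arange(len(labels))
    for left, right in pairing.pairs:
        perm[index[left]] = index[right]
        perm[index[right]] = index[left]
    return perm


def reflect_relabel(
    config: np.ndarray,
    labels: list[str],
    pairing: PairingMap,
    axis: int = 0,
) -> np.ndarray:
    """Mirror a configuration across ``axis`` and swap left/right labels.

    Midline landmarks are only reflected.  The operation is an involution:
    applying it twice returns the input exactly.
    """
    X = np.asarray(config, dtype=float)
    if X.ndim != 2:
        raise ValidationError(f"expected k x D coordinates, got shape {X.shape}")
    if not 0 <= axis < X.shape[1]:
        raise ValidationError(f"reflection axis {axis} out of range for D={X.shape[1]}")
    perm = _pair_permutation(labels, pairing)
    out = X.copy()
    out[:, axis] = -out[:, axis]
    return out[perm]


@dataclass
class SymmetryDecomposition:
    """Per-specimen symmetric and asymmetric shape components."""

    symmetric: np.ndarray  # n x k x D
    asymmetric: np.ndarray  # n x k x D, aligned original - symmetric
    consensus: np.ndarray  # k x D, mirror-symmetric
    centroid_sizes: np.ndarray  # n, from the specimens' original scale
    aligned: np.ndarray  # n x k x D aligned originals
    specimen_ids: list[str] | None = None

    @property
    def n(self) -> int:
        return self.symmetric.shape[0]

    def flat_symmetric(self) -> np.ndarray:
        return self.symmetric.reshape(self.n, -1)

    @property
    def log_cs(self) -> np.ndarray:
        return np.log(self.centroid_sizes)


def symmetry_decomposition(
    dataset: LandmarkDataset,
    axis: int = 0,
    tol: float = 1e-12,
    max_iter: int = 200,
) -> SymmetryDecomposition:
    """Extract the bilateral-symmetry component of every specimen.

    The 2n-configuration set {originals} ∪ {reflected-relabelled copies} is
    superimposed jointly; the consensus is symmetrized (averaged with its own
    reflected-relabelled copy) each iteration so that it is exactly
    mirror-invariant.  Each specimen's symmetric component is the mean of
    its two aligned copies; symmetric + asymmetric reconstructs the aligned
    original exactly.
    """
    if dataset.pairing is None:
        raise ValidationError("symmetry decomposition requires a PairingMap")
    X = dataset.coords_array()
    labels = dataset.labels
    pairing = dataset.pairing
    perm = _pair_permutation(labels, pairing)
    n = X.shape[0]

    sizes = np.array([centroid_size(x) for x in X])
    scaled = np.stack([(x - x.mean(axis=0)) / s for x, s in zip(X, sizes)])
    reflected = np.stack([reflect_relabel(x, labels, pairing, axis=axis) for x in scaled])
    both = np.concatenate([scaled, reflected])  # 2n x k x D

    def symmetrize(c: np.ndarray) -> np.ndarray:
        refl = c.copy()
        refl[:, axis] = -refl[:, axis]
        sym = 0.5 * (c + refl[perm])
        sym -= sym.mean(axis=0)
        return sym / centroid_size(sym)

    consensus = symmetrize(both[0])
    aligned = both.copy()
    for _ in range(max_iter):
        aligned = np.stack([x @ optimal_rotation(x, consensus) for x in both])
        new_consensus = symmetrize(aligned.mean(axis=0))
        delta = float(((new_consensus - consensus) ** 2).sum())
        consensus = new_consensus
        if delta < tol:
            break

    aligned_orig = aligned[:n]
    aligned_refl = aligned[n:]
    symmetric = 0.5 * (aligned_orig + aligned_refl)
    asymmetric = aligned_orig - symmetric
    return SymmetryDecomposition(
        symmetric=symmetric,
        asymmetric=asymmetric,
        consensus=consensus,
        centroid_sizes=sizes,
        aligned=aligned_orig,
        specimen_ids=dataset.specimen_ids,
    )
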