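"""Principal component analysis of shape and trait matrices.

Shape PCA runs on the flattened symmetric-component Procrustes coordinates;
trait PCA on the standardized size-corrected matrix.  Two loading
conventions are emitted: unit eigenvectors and eigenvalue-scaled loadings
(eigenvector * sqrt(eigenvalue)); the latter can exceed 1 in magnitude for
strongly structured data.  Eigenvector signs are fixed so the
largest-magnitude element of each component is positive, making output
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .superimposition import procrustes_distance

__all__ = ["PCAResult", "pca", "pc_extreme_shape", "replicate_error_check"]


@dataclass
class PCAResult:
    scores: np.ndarray  # n x r
    eigenvectors: np.ndarray  # p x r (unit length)
    eigenvalues: np.ndarray  # r, non-increasing
    variance_fraction: np.ndarray  # r, sums to 1 over full rank
    loadings: np.ndarray  # p x r, eigenvector * sqrt(eigenvalue)

    @property
    def rank(self) -> int:
        return self.eigenvalues.size


def pca(X: np.ndarray) -> PCAResult:
    """PCA by singular value decomposition of the column-centered matrix.

    Eigenvalues are singular values squared over (n - 1); the retained rank
    is min(n - 1, p).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValidationError(f"need an n x p matrix with n >= 2, got shape {X.shape}")
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    if not np.any(Xc):
        raise ValidationError("constant matrix has no principal components")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    r = min(n - 1, p)
    U, s, Vt = U[:, :r], s[:r], Vt[:r]
    # deterministic sign: largest-|element| of each eigenvector positive
    flip = np.sign(Vt[np.arange(r), np.abs(Vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    U = U * flip[None, :]
    eigenvalues = s**2 / (n - 1)
    total = eigenvalues.sum()
    return PCAResult(
        scores=U * s,
        eigenvectors=Vt.T,
        eigenvalues=eigenvalues,
        variance_fraction=eigenvalues / total,
        loadings=Vt.T * np.sqrt(eigenvalues),
    )


def pc_extreme_shape(
    result: PCAResult, mean_shape: np.ndarray, axis: int, score: float
) -> np.ndarray:
    """Landmark shape at a given score along one PC of flattened coordinates."""
    mean_shape = np.asarray(mean_shape, dtype=float)
    if not 0 <= axis < result.rank:
        raise ValidationError(f"axis {axis} out of range (rank {result.rank})")
    vec = result.eigenvectors[:, axis]
    if vec.size != mean_shape.size:
        raise ValidationError(
            f"eigenvector length {vec.size} does not match shape size {mean_shape.size}"
        )
    return mean_shape + score * vec.reshape(mean_shape.shape)


def replicate_error_check(
    aligned: np.ndarray, metadata: pd.DataFrame
) -> tuple[float, pd.DataFrame]:
    """Landmarking-error check from repeated digitizations.

    Ratio of the mean pairwise Procrustes distance among replicates of the
    same specimen to the mean pairwise distance among distinct conspecific
    specimens.  Replicates that cluster much more tightly than conspecifics
    (ratio well below 1) indicate negligible digitization error.
    """
    aligned = np.asarray(aligned, dtype=float)
    md = metadata.reset_index(drop=True)
    if "replicate_of" not in md.columns:
        raise ValidationError("metadata lacks a replicate_of column")
    base_of = [
        r["replicate_of"] if r.get("replicate_of") not in (None, "", np.nan) else r["specimen_id"]
        for _, r in md.iterrows()
    ]
    groups: dict[str, list[int]] = {}
    for i, b in enumerate(base_of):
        groups.setdefault(str(b), []).append(i)
    rep_sets = {b: idx for b, idx in groups.items() if len(idx) > 1}
    if not rep_sets:
        raise ValidationError("no replicated specimens in the dataset")

    rows = []
    rep_dists: list[float] = []
    for b, idx in rep_sets.items():
        d = [
            procrustes_distance(aligned[i], aligned[j])
            for a, i in enumerate(idx)
            for j in idx[a + 1 :]
        ]
        rows.append({"specimen": b, "n_replicates": len(idx), "mean_replicate_dist": np.mean(d)})
        rep_dists.extend(d)

    # conspecific baseline: one representative (the base) per true specimen
    reps = {b: idx[0] for b, idx in groups.items()}
    species = {b: md.loc[idx[0], "species"] for b, idx in groups.items()}
    con_dists = []
    bases = list(reps)
    for a, b1 in enumerate(bases):
        for b2 in bases[a + 1 :]:
            if species[b1] == species[b2]:
                con_dists.append(procrustes_distance(aligned[reps[b1]], aligned[reps[b2]]))
    if not con_dists:
        raise ValidationError("no distinct conspecific pairs to compare against")
    ratio = float(np.mean(rep_dists) / np.mean(con_dists))
    return ratio, pd.DataFrame(rows)
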