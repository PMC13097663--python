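"""Thin-plate-spline (TPS) estimation of missing landmarks.

An incomplete specimen is repaired by warping a within-group reference shape
(the Procrustes mean of the group's complete specimens) onto the specimen:
a TPS map is fitted from the reference's present-landmark subset to the
specimen's present landmarks, and evaluated at the reference positions of
the missing landmarks.  The specimen is first superimposed on the reference
(center, scale, rotate) using its present landmarks so the spline models
shape difference rather than pose; estimates are transformed back to the
specimen's original frame.

The TPS kernel is U(r) = r for 3D data and U(r) = r^2 log r for 2D data,
with exact interpolation (no smoothing).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import cdist

from .errors import DegenerateConfigurationError, ValidationError
from .landmark_io import LandmarkConfiguration, LandmarkDataset
from .superimposition import centroid_size, gpa, optimal_rotation

__all__ = ["TpsMapping", "tps_fit", "tps_apply", "estimate_missing"]


def _kernel(r: np.ndarray, tag: str) -> np.ndarray:
    if tag == "r":
        return r
    if tag == "r2logr":
        out = np.zeros_like(r)
        nz = r > 0
        out[nz] = r[nz] ** 2 * np.log(r[nz])
        return out
    raise ValidationError(f"unknown TPS kernel tag {tag!r}")


@dataclass
class TpsMapping:
    """Exact thin-plate-spline interpolant between two point sets.

    f(x) = a . (1, x) + sum_j w_j U(||x - s_j||), with side conditions
    sum w = 0 and sum w x = 0 per axis.
    """

    source_points: np.ndarray  # m x D
    weights: np.ndarray  # m x D
    affine: np.ndarray  # (D+1) x D; row 0 is the constant term
    kernel: str  # "r" (3D) or "r2logr" (2D)


def tps_fit(source: np.ndarray, target: np.ndarray) -> TpsMapping:
    """Fit the standard TPS linear system [[K, P], [P', 0]] [w; a] = [target; 0]."""
    S = np.asarray(source, dtype=float)
    T = np.asarray(target, dtype=float)
    if S.ndim != 2 or S.shape != T.shape:
        raise ValidationError(f"source/target must be matching m x D, got {S.shape}, {T.shape}")
    m, D = S.shape
    if D not in (2, 3):
        raise ValidationError(f"TPS supports D in (2, 3), got {D}")
    if m < D + 2:
        raise ValidationError(f"need at least D+2={D + 2} control points, got {m}")
    tag = "r" if D == 3 else "r2logr"
    K = _kernel(cdist(S, S), tag)
    P = np.hstack([np.ones((m, 1)), S])
    L = np.zeros((m + D + 1, m + D + 1))
    L[:m, :m] = K
    L[:m, m:] = P
    L[m:, :m] = P.T
    rhs = np.vstack([T, np.zeros((D + 1, D))])
    try:
        sol = np.linalg.solve(L, rhs)
    except np.linalg.LinAlgError as exc:
        raise DegenerateConfigurationError(
            "TPS system is singular (source points collinear/coplanar or duplicated)"
        ) from exc
    return TpsMapping(source_points=S, weights=sol[:m], affine=sol[m:], kernel=tag)


def tps_apply(mapping: TpsMapping, points: np.ndarray) -> np.ndarray:
    """Evaluate the TPS map at ``points`` (q x D)."""
    X = np.atleast_2d(np.asarray(points, dtype=float))
    D = mapping.source_points.shape[1]
    if X.shape[1] != D:
        raise ValidationError(f"points are {X.shape[1]}-D but mapping is {D}-D")
    U = _kernel(cdist(X, mapping.source_points), mapping.kernel)
    P = np.hstack([np.ones((X.shape[0], 1)), X])
    return P @ mapping.affine + U @ mapping.weights


def estimate_missing(
    dataset: LandmarkDataset,
    group_by: str = "species",
) -> tuple[LandmarkDataset, dict[str, int]]:
    """Estimate all missing landmarks, working within groups of ``group_by``.

    For each group the reference is the Procrustes mean shape of its
    *complete* specimens.  Returns the completed dataset together with a log
    of estimated-landmark counts per specimen.  Idempotent on complete
    datasets (returns the input unchanged).
    """
    if dataset.total_missing == 0:
        return dataset, {}
    factors = dataset.factor_frame()
    if group_by not in factors.columns:
        raise ValidationError(f"unknown grouping factor {group_by!r}")
    groups = factors[group_by].tolist()
    D = dataset.ndim

    new_configs: list[LandmarkConfiguration] = [None] * dataset.n  # type: ignore[list-item]
    log: dict[str, int] = {}
    for level in sorted(set(groups)):
        idx = [i for i, g in enumerate(groups) if g == level]
        complete = [i for i in idx if dataset.configurations[i].n_missing == 0]
        incomplete = [i for i in idx if dataset.configurations[i].n_missing > 0]
        if incomplete and not complete:
            raise ValidationError(
                f"group {level!r} has no complete specimens to build a reference"
            )
        for i in complete:
            new_configs[i] = dataset.configurations[i]
        if not incomplete:
            continue
        ref = gpa(np.stack([dataset.configurations[i].coords for i in complete])).consensus
        for i in incomplete:
            cfg = dataset.configurations[i]
            present = ~cfg.missing_mask
            if present.sum() < D + 2:
                raise ValidationError(
                    f"{cfg.specimen_id}: only {int(present.sum())} present landmarks; "
                    f"need at least {D + 2} to fit a TPS"
                )
            est = _estimate_one(cfg.coords, present, ref)
            coords = cfg.coords.copy()
            coords[cfg.missing_mask] = est
            log[cfg.specimen_id] = int(cfg.missing_mask.sum())
            new_configs[i] = replace(
                cfg, coords=coords, missing_mask=np.zeros(cfg.k, dtype=bool)
            )
    return LandmarkDataset(new_configs, dataset.pairing, dataset.metadata), log


def _estimate_one(coords: np.ndarray, present: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """TPS-estimate the masked rows of one specimen against a reference shape."""
    missing = ~present
    spec_p = coords[present]
    ref_p = ref[present]
    # superimpose the specimen's present landmarks on the reference subset
    c_spec = spec_p.mean(axis=0)
    c_ref = ref_p.mean(axis=0)
    scale = centroid_size(ref_p) / centroid_size(spec_p)
    A = (spec_p - c_spec) * scale
    R = optimal_rotation(A, ref_p - c_ref)
    spec_in_ref = A @ R + c_ref
    mapping = tps_fit(ref_p, spec_in_ref)
    est_ref_frame = tps_apply(mapping, ref[missing])
    # back-transform to the specimen's original frame
    return (est_ref_frame - c_ref) @ R.T / scale + c_spec
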