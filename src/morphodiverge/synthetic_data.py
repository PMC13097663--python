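"""Synthetic data generators with recorded ground truth.

Three generators emulate the statistical structure the analyses assume:

* :func:`simulate_landmarks` — bilaterally symmetric 3D (or 2D) landmark
  configurations with group mean-shape differences, log-size allometry,
  sexual shape dimorphism, small fluctuating asymmetry, digitization noise,
  and similarity-transform nuisance (pose and scale).  Shape effects are
  tangent-space displacement fields applied to a unit-centroid-size
  template, orthogonalized against translation, scaling and infinitesimal
  rotation so that generated Procrustes distances between group means equal
  the Euclidean norms of the effect differences.
* :func:`simulate_traits` — log-log allometric trait tables:
  log Y = log a + b log SVL + group + sex + noise.
* :func:`simulate_phantom` — two-material CT phantoms (ellipsoids/tubes at
  a bone intensity over a background intensity) with Gaussian gray noise
  and a ground-truth mask.

Every generator is bit-reproducible given its seed, and returns a truth
record for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .landmark_io import (
    LandmarkConfiguration,
    LandmarkDataset,
    PairingMap,
    SpecimenMetadata,
)
from .allometry import TRAITS, TraitTable
from .ct_segmentation import BinaryVolume, GreyVolume

import pandas as pd

__all__ = [
    "GroupSpec",
    "LandmarkSimParams",
    "LandmarkTruth",
    "simulate_landmarks",
    "TraitSimParams",
    "TraitTruth",
    "simulate_traits",
    "PhantomParams",
    "simulate_phantom",
    "study_landmark_params",
    "study_trait_params",
]


# ---------------------------------------------------------------------------
# landmark generator


@dataclass
class GroupSpec:
    """One group (e.g. species) in a landmark simulation."""

    name: str
    n: int
    offset_scale: float = 0.0  # norm of the group mean-shape offset
    mean_log_size: float = 0.0  # lognormal location for centroid size (mm)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError(f"group {self.name!r}: n must be >= 1")


@dataclass
class LandmarkSimParams:
    """Study conditions for the landmark generator.

    Defaults emulate a cranium-like template (54 bilateral pairs + 12
    midline landmarks) with three groups.  All shape-effect magnitudes are
    in units of Procrustes (unit-CS) shape distance.
    """

    k_pairs: int = 54
    k_midline: int = 12
    ndim: int = 3
    groups: list[GroupSpec] = field(
        default_factory=lambda: [
            GroupSpec("sey", 17, 0.0, np.log(30.0)),
            GroupSpec("tac", 16, 0.0, np.log(24.0)),
            GroupSpec("tra", 9, 0.0, np.log(40.0)),
        ]
    )
    group_distances: dict[tuple[str, str], float] | None = None
    size_sd: float = 0.15  # lognormal sigma of centroid size
    allometry_scale: float = 0.015  # shape change per unit log-size
    sex_effect_scale: float = 0.015
    asymmetry_sd: float = 0.001  # per-coordinate, independent per side
    noise_sd: float = 0.002  # per-coordinate symmetric individual variation
    digitization_sd: float = 0.0005  # per-coordinate landmark placement error
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("size_sd", "asymmetry_sd", "noise_sd", "digitization_sd",
                     "allometry_scale", "sex_effect_scale"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0 <= self.missing_rate <= 0.2:
            raise ValidationError("missing_rate must be in [0, 0.2]")
        if self.ndim not in (2, 3):
            raise ValidationError("ndim must be 2 or 3")


@dataclass
class LandmarkTruth:
    """Ground truth recorded by the landmark generator."""

    template: np.ndarray  # k x D, unit CS, mirror-symmetric
    group_offsets: dict[str, np.ndarray]  # k x D tangent displacement per group
    sex_effect: np.ndarray  # k x D (applied to males)
    allometry_vector: np.ndarray  # k x D per unit log-size
    sizes: np.ndarray  # n centroid sizes
    sexes: list[str]
    species: list[str]

    def expected_distance(self, a: str, b: str) -> float:
        return float(np.linalg.norm(self.group_offsets[a] - self.group_offsets[b]))


def _symmetric_template(rng, k_pairs: int, k_midline: int, ndim: int) -> np.ndarray:
    """Mirror-symmetric template about the first coordinate axis, unit CS."""
    right = rng.uniform(0.25, 1.0, size=(k_pairs, 1))
    rest = rng.uniform(-1.0, 1.0, size=(k_pairs, ndim - 1))
    right = np.hstack([right, rest])
    left = right.copy()
    left[:, 0] = -left[:, 0]
    mid = np.hstack(
        [np.zeros((k_midline, 1)), rng.uniform(-1.0, 1.0, size=(k_midline, ndim - 1))]
    )
    # interleave pairs so labels L1,R1,...,M1,... match the coordinate order
    coords = np.vstack([np.stack([left, right], axis=1).reshape(-1, ndim), mid])
    coords -= coords.mean(axis=0)
    cs = np.sqrt((coords**2).sum())
    if cs <= 0:
        raise ValidationError("degenerate template")
    return coords / cs


def _pair_labels(k_pairs: int, k_midline: int) -> tuple[list[str], PairingMap]:
    labels: list[str] = []
    pairs: list[tuple[str, str]] = []
    for i in range(k_pairs):
        labels += [f"L{i + 1}", f"R{i + 1}"]
        pairs.append((f"L{i + 1}", f"R{i + 1}"))
    midline = [f"M{i + 1}" for i in range(k_midline)]
    labels += midline
    return labels, PairingMap(pairs, midline)


def _tangent_basis(template: np.ndarray) -> np.ndarray:
    """Orthonormal basis (columns) of the similarity directions to remove:
    translations, scaling, and infinitesimal rotations at the template."""
    k, D = template.shape
    gens = []
    for a in range(D):
        t = np.zeros((k, D))
        t[:, a] = 1.0
        gens.append(t.ravel())
    gens.append(template.ravel())  # scaling direction
    if D == 2:
        rot = np.stack([-template[:, 1], template[:, 0]], axis=1)
        gens.append(rot.ravel())
    else:
        for a, b in ((0, 1), (0, 2), (1, 2)):
            rot = np.zeros((k, D))
            rot[:, a] = -template[:, b]
            rot[:, b] = template[:, a]
            gens.append(rot.ravel())
    Q, _ = np.linalg.qr(np.stack(gens, axis=1))
    return Q


def _symmetric_field(rng, k_pairs, k_midline, ndim) -> np.ndarray:
    """Random mirror-symmetric displacement field (unnormalized)."""
    right = rng.standard_normal((k_pairs, ndim))
    left = right.copy()
    left[:, 0] = -left[:, 0]
    mid = rng.standard_normal((k_midline, ndim))
    mid[:, 0] = 0.0
    return np.vstack([np.stack([left, right], axis=1).reshape(-1, ndim), mid])


def _project_tangent(field: np.ndarray, basis: np.ndarray) -> np.ndarray:
    v = field.ravel()
    v = v - basis @ (basis.T @ v)
    return v.reshape(field.shape)


def _random_rotation(rng, ndim: int) -> np.ndarray:
    A = rng.standard_normal((ndim, ndim))
    Q, R = np.linalg.qr(A)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def _group_offset_fields(
    rng, groups, distances, basis, k_pairs, k_midline, ndim
) -> dict[str, np.ndarray]:
    """Mirror-symmetric tangent offsets with prescribed pairwise distances.

    When explicit pairwise distances are given (three groups), the offsets
    are placed in a 2-plane spanned by two orthonormal symmetric tangent
    fields so the realized distances equal the prescription; otherwise each
    group gets an independent offset of its ``offset_scale`` norm.
    """
    def unit_field():
        f = _project_tangent(_symmetric_field(rng, k_pairs, k_midline, ndim), basis)
        return f / np.linalg.norm(f)

    names = [g.name for g in groups]
    if distances:
        if len(names) != 3:
            raise ValidationError("prescribed pairwise distances require exactly 3 groups")
        a, b, c = names
        d_ab = distances[(a, b)]
        d_ac = distances[(a, c)]
        d_bc = distances[(b, c)]
        u = unit_field()
        v = unit_field()
        v = v - u * np.sum(u * v)
        v /= np.linalg.norm(v)
        # triangle embedding: A at origin, B on u, C from the law of cosines
        x_c = (d_ab**2 + d_ac**2 - d_bc**2) / (2 * d_ab) if d_ab > 0 else 0.0
        y_c = np.sqrt(max(d_ac**2 - x_c**2, 0.0))
        pts = {a: (0.0, 0.0), b: (d_ab, 0.0), c: (x_c, y_c)}
        centroid = np.mean(list(pts.values()), axis=0)
        return {
            name: (xy[0] - centroid[0]) * u + (xy[1] - centroid[1]) * v
            for name, xy in pts.items()
        }
    out = {}
    for g in groups:
        out[g.name] = g.offset_scale * unit_field() if g.offset_scale > 0 else np.zeros(
            ((2 * k_pairs + k_midline), ndim)
        )
    return out


def simulate_landmarks(
    params: LandmarkSimParams,
) -> tuple[LandmarkDataset, LandmarkTruth]:
    """Generate a landmark dataset with known shape effects.

    Each specimen's shape is template + group offset + sex effect (males)
    + allometry_vector * (log s - mean log s) + symmetric noise, plus
    independent asymmetric and digitization noise; the configuration is
    then randomly rotated, scaled to its centroid size s and translated.
    Missing landmarks are masked completely at random at ``missing_rate``
    (never more than 20% of a specimen, and the first specimen of each
    group stays complete so a reference always exists).
    """
    rng = np.random.default_rng(params.seed)
    k_pairs, k_midline, ndim = params.k_pairs, params.k_midline, params.ndim
    k = 2 * k_pairs + k_midline
    labels, pairing = _pair_labels(k_pairs, k_midline)
    template = _symmetric_template(rng, k_pairs, k_midline, ndim)
    basis = _tangent_basis(template)

    def sym_unit():
        f = _project_tangent(_symmetric_field(rng, k_pairs, k_midline, ndim), basis)
        return f / np.linalg.norm(f)

    offsets = _group_offset_fields(
        rng, params.groups, params.group_distances, basis, k_pairs, k_midline, ndim
    )
    sex_effect = params.sex_effect_scale * sym_unit()
    allometry_vector = params.allometry_scale * sym_unit()

    configs: list[LandmarkConfiguration] = []
    metadata: dict[str, SpecimenMetadata] = {}
    sizes, sexes, species = [], [], []
    mean_log_size = float(
        np.mean([g.mean_log_size for g in params.groups for _ in range(g.n)])
    )
    for g in params.groups:
        for i in range(g.n):
            sid = f"{g.name}_{i + 1:03d}"
            sex = "M" if i % 2 == 0 else "F"
            s = float(np.exp(rng.normal(g.mean_log_size, params.size_sd)))
            shape = template + offsets[g.name]
            if sex == "M":
                shape = shape + sex_effect
            shape = shape + allometry_vector * (np.log(s) - mean_log_size)
            shape = shape + params.noise_sd * _project_tangent(
                _symmetric_field(rng, k_pairs, k_midline, ndim), basis
            )
            shape = shape + params.asymmetry_sd * rng.standard_normal((k, ndim))
            shape = shape + params.digitization_sd * rng.standard_normal((k, ndim))
            R = _random_rotation(rng, ndim)
            coords = (shape @ R) * s + rng.uniform(-50, 50, size=ndim)
            mask = np.zeros(k, dtype=bool)
            if params.missing_rate > 0 and i > 0:
                draw = rng.random(k) < params.missing_rate
                if draw.sum() > 0.2 * k:
                    draw[np.flatnonzero(draw)[int(0.2 * k) :]] = False
                mask = draw
            configs.append(
                LandmarkConfiguration(sid, coords, list(labels), missing_mask=mask)
            )
            region = "northern" if i % 3 else "southern"
            metadata[sid] = SpecimenMetadata(
                specimen_id=sid,
                species=g.name,
                region=region,
                island=f"{region[:1]}{i % 4}",
                sex=sex,
            )
            sizes.append(s)
            sexes.append(sex)
            species.append(g.name)

    dataset = LandmarkDataset(configs, pairing, metadata)
    truth = LandmarkTruth(
        template=template,
        group_offsets=offsets,
        sex_effect=sex_effect,
        allometry_vector=allometry_vector,
        sizes=np.array(sizes),
        sexes=sexes,
        species=species,
    )
    return dataset, truth


def study_landmark_params(
    structure: str = "cranium", seed: int = 0, missing_rate: float = 0.0028
) -> LandmarkSimParams:
    """Study-like landmark conditions: cranium (54 pairs + 12 midline) or
    mandible (24 pairs) templates, three species with n = 17/16/9, and
    between-species mean-shape distances matching the magnitudes reported
    for the real material."""
    if structure == "cranium":
        k_pairs, k_midline = 54, 12
        dists = {("sey", "tac"): 0.066, ("sey", "tra"): 0.107, ("tac", "tra"): 0.159}
    elif structure == "mandible":
        k_pairs, k_midline = 24, 0
        dists = {("sey", "tac"): 0.083, ("sey", "tra"): 0.142, ("tac", "tra"): 0.213}
    else:
        raise ValidationError(f"unknown structure {structure!r}")
    return LandmarkSimParams(
        k_pairs=k_pairs,
        k_midline=k_midline,
        group_distances=dists,
        missing_rate=missing_rate,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# trait generator


@dataclass
class TraitSimParams:
    """Log-log allometric trait simulation.

    Defaults emulate the study's 2D dataset: three species with
    n = 246/206/115, ten traits following log Y = log a + b log SVL +
    species effect + sex effect + N(0, noise_sd^2), with near-isometric
    slopes for linear head/limb traits and a cubic-order slope for mass.
    """

    traits: list[str] = field(default_factory=lambda: list(TRAITS))
    log_intercepts: dict[str, float] | None = None
    slopes: dict[str, float] | None = None
    groups: dict[str, int] = field(
        default_factory=lambda: {"sey": 246, "tac": 206, "tra": 115}
    )
    mean_svl: dict[str, float] | None = None  # per-group mean SVL (mm)
    svl_sd_log: float = 0.08
    group_effects: dict[str, dict[str, float]] | None = None  # log-scale shifts
    slope_effects: dict[str, dict[str, float]] | None = None  # per-species slope deviations
    sex_effects: dict[str, float] | None = None  # applied to males, log scale
    island_effects: dict[str, float] | None = None  # common log-scale shift per island
    islands_per_group: int = 4
    noise_sd: float = 0.05
    seed: int = 0


_DEFAULT_SLOPES = {
    "ED": 0.85, "EED": 0.95, "FTL": 1.0, "HH": 1.0, "HL": 0.95,
    "HW": 1.0, "IND": 0.9, "IOD": 0.95, "SED": 0.95, "Weight": 3.0,
}
# intercepts chosen so traits have realistic proportions at SVL ~ 100 mm
_DEFAULT_LOG_A = {
    "ED": np.log(4.5) - 0.85 * np.log(100),
    "EED": np.log(9.0) - 0.95 * np.log(100),
    "FTL": np.log(10.0) - 1.0 * np.log(100),
    "HH": np.log(11.0) - 1.0 * np.log(100),
    "HL": np.log(27.0) - 0.95 * np.log(100),
    "HW": np.log(18.0) - 1.0 * np.log(100),
    "IND": np.log(3.5) - 0.9 * np.log(100),
    "IOD": np.log(8.0) - 0.95 * np.log(100),
    "SED": np.log(11.0) - 0.95 * np.log(100),
    "Weight": np.log(25.0) - 3.0 * np.log(100),
}
# species shape effects (log scale): tra heavier/wider, tac longer-snouted
_DEFAULT_GROUP_EFFECTS = {
    "sey": {},
    "tac": {"ED": 0.06, "HL": 0.05, "SED": 0.06, "Weight": -0.10, "HW": -0.04,
            "FTL": -0.05, "EED": -0.04, "IND": -0.04, "IOD": -0.05},
    "tra": {"Weight": 0.18, "FTL": 0.08, "HW": 0.08, "HH": 0.05, "EED": 0.07,
            "IND": 0.07, "IOD": 0.07, "ED": -0.04, "SED": -0.04, "HL": -0.03},
}
# species-specific allometric trajectories (slope deviations); these carry
# most of the size-corrected species separation, since purely additive
# species shifts are largely absorbed by the pooled allometric slope
_DEFAULT_SLOPE_EFFECTS = {
    "sey": {},
    "tac": {"ED": 0.055, "HL": 0.045, "SED": 0.050, "Weight": -0.085, "HW": -0.055,
            "FTL": -0.060, "EED": -0.050, "IND": -0.050, "IOD": -0.055, "HH": -0.030},
    "tra": {"Weight": 0.085, "FTL": 0.060, "HW": 0.060, "HH": 0.035, "EED": 0.055,
            "IND": 0.050, "IOD": 0.055, "ED": -0.040, "SED": -0.040, "HL": -0.030},
}
# shared island pool: most islands host more than one species, so island
# terms are (partially) crossed with species rather than nested in them
_ISLAND_POOL = [
    ("Praslin", "northern"), ("Curieuse", "northern"),
    ("LaDigue", "northern"), ("Aride", "northern"),
    ("Mahe", "southern"), ("Silhouette", "southern"),
    ("Therese", "southern"), ("SainteAnne", "southern"),
]
_DEFAULT_SEX_EFFECTS = {"HL": 0.02, "SED": 0.02, "HH": 0.015, "Weight": -0.04}
_DEFAULT_MEAN_SVL = {"sey": 90.0, "tac": 65.0, "tra": 120.0}


@dataclass
class TraitTruth:
    slopes: dict[str, float]
    log_intercepts: dict[str, float]
    group_effects: dict[str, dict[str, float]]
    sex_effects: dict[str, float]
    island_effects: dict[str, dict[str, float]]


def simulate_traits(params: TraitSimParams) -> tuple[TraitTable, TraitTruth]:
    """Generate a trait table under the log-log allometric model."""
    rng = np.random.default_rng(params.seed)
    slopes = dict(_DEFAULT_SLOPES if params.slopes is None else params.slopes)
    log_a = dict(_DEFAULT_LOG_A if params.log_intercepts is None else params.log_intercepts)
    geff = dict(_DEFAULT_GROUP_EFFECTS if params.group_effects is None else params.group_effects)
    sleff = dict(_DEFAULT_SLOPE_EFFECTS if params.slope_effects is None else params.slope_effects)
    seff = dict(_DEFAULT_SEX_EFFECTS if params.sex_effects is None else params.sex_effects)
    mean_svl = dict(_DEFAULT_MEAN_SVL if params.mean_svl is None else params.mean_svl)

    pool = _ISLAND_POOL[: max(2, min(params.islands_per_group * 2, len(_ISLAND_POOL)))]
    rows = []
    island_truth: dict[str, dict[str, float]] = {}
    for isl, _region in pool:
        shift = (params.island_effects or {}).get(isl, 0.0)
        island_truth[isl] = {t: shift for t in params.traits}
    for g, n in params.groups.items():
        for i in range(n):
            sex = "M" if rng.random() < 0.5 else "F"
            isl, region = pool[i % len(pool)]
            svl = float(
                np.exp(rng.normal(np.log(mean_svl.get(g, 100.0)), params.svl_sd_log))
            )
            row = {
                "specimen_id": f"{g}_{i + 1:04d}",
                "species": g,
                "region": region,
                "island": isl,
                "sex": sex,
                "SVL": round(svl),
            }
            for t in params.traits:
                mu = log_a[t] + slopes[t] * np.log(svl)
                mu += geff.get(g, {}).get(t, 0.0)
                mu += sleff.get(g, {}).get(t, 0.0) * np.log(svl)
                if sex == "M":
                    mu += seff.get(t, 0.0)
                mu += island_truth[isl][t]
                val = float(np.exp(mu + rng.normal(0.0, params.noise_sd)))
                row[t] = round(val, 2) if t != "Weight" else round(val * 2) / 2
                if row[t] <= 0:
                    row[t] = 0.01
            rows.append(row)
    table = TraitTable(pd.DataFrame(rows), list(params.traits))
    truth = TraitTruth(
        slopes=slopes,
        log_intercepts=log_a,
        group_effects=geff,
        sex_effects=seff,
        island_effects=island_truth,
    )
    return table, truth


def study_trait_params(seed: int = 0) -> TraitSimParams:
    """The study's 2D conditions: n = 567 (246 / 206 / 115)."""
    return TraitSimParams(seed=seed)


# ---------------------------------------------------------------------------
# CT phantom generator


@dataclass
class PhantomParams:
    """Two-material CT phantom: ellipsoids/tubes at bone intensity over background."""

    shape: tuple[int, int, int] = (64, 64, 64)
    ellipsoids: list[tuple] = field(default_factory=list)  # (center, semiaxes)
    tubes: list[tuple] = field(default_factory=list)  # (axis, center2d, radius)
    mean_bone: float = 180.0
    mean_background: float = 60.0
    noise_sd: float = 10.0
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.mean_bone > self.mean_background:
            raise ValidationError("mean_bone must exceed mean_background")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


def default_phantom_params(shape=(64, 64, 64), seed: int = 0, **kw) -> PhantomParams:
    """A centred ellipsoid plus a tube, filling a realistic bone fraction."""
    nz, ny, nx = shape
    return PhantomParams(
        shape=shape,
        ellipsoids=[((nz / 2, ny / 2, nx / 2), (nz / 3.2, ny / 4.0, nx / 3.0))],
        tubes=[(0, (ny / 4.0, nx / 4.0), min(ny, nx) / 10.0)],
        seed=seed,
        **kw,
    )


def simulate_phantom(params: PhantomParams) -> tuple[GreyVolume, BinaryVolume]:
    """Voxelize the geometry, add Gaussian noise, and return volume + truth mask."""
    nz, ny, nx = params.shape
    zz, yy, xx = np.meshgrid(
        np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij"
    )
    truth = np.zeros(params.shape, dtype=bool)
    for center, semi in params.ellipsoids:
        cz, cy, cx = center
        az, ay, ax = semi
        if min(az, ay, ax) <= 0:
            raise ValidationError("ellipsoid semiaxes must be positive")
        if cz - az < -0.5 or cz + az > nz - 0.5 or cy - ay < -0.5 or cy + ay > ny - 0.5 \
                or cx - ax < -0.5 or cx + ax > nx - 0.5:
            raise ValidationError("ellipsoid exceeds the grid")
        truth |= (
            ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2
        ) <= 1.0
    for axis, center2d, radius in params.tubes:
        if radius <= 0:
            raise ValidationError("tube radius must be positive")
        planes = [zz, yy, xx]
        others = [p for i, p in enumerate(planes) if i != axis]
        c1, c2 = center2d
        truth |= ((others[0] - c1) ** 2 + (others[1] - c2) ** 2) <= radius**2
    rng = np.random.default_rng(params.seed)
    vox = np.where(truth, params.mean_bone, params.mean_background).astype(float)
    if params.noise_sd > 0:
        vox = vox + rng.normal(0.0, params.noise_sd, size=params.shape)
    return GreyVolume(vox, params.spacing), BinaryVolume(truth, params.spacing)
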