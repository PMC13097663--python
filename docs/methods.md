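# Methods

`morphodiverge` implements a complete landmark-based and linear-measurement
morphometrics workflow of the kind used to test species boundaries and
within-species geographic structure in skeletal and external-body data, plus
the micro-CT thresholding protocol used to produce the skeletal volumes the
landmarks are digitized on. This note records the models, the parameters
that matter, the numerical choices, and the limits of what the synthetic
data can show.

## Shape variables

A specimen is a configuration of k labelled landmarks in D = 2 or 3
dimensions (mm). Size is measured by centroid size,
CS = sqrt(Σ_j ‖x_j − x̄‖²), which is homogeneous of degree one in scale and
enters all downstream models as log(CS).

**Generalized Procrustes analysis** (`superimposition.gpa`) removes
location (centering), size (scaling to unit CS) and orientation
(least-squares rotation against a running consensus, initialized from the
first specimen). The rotation is the Kabsch SVD solution with the sign of
the last singular vector corrected so that reflections are impossible
(det R = +1); mirror symmetry is handled explicitly by relabelling, never
by improper rotations. Iteration stops when the summed squared change of
the consensus falls below 1e-10 (typically 2–3 iterations). Analyses run
directly on the Procrustes-aligned coordinates with no tangent-space
projection; at the within-genus shape variation the package targets
(Procrustes distances ≲ 0.2) the curvature correction is far below the
other error terms, and we document this as an approximation rather than an
option.

**Object symmetry** (`symmetry.symmetry_decomposition`). A bilaterally
symmetric structure and its mirror image with left/right labels swapped are
two observations of the same shape. The 2n-configuration set
{originals} ∪ {reflected-relabelled copies} is superimposed jointly; the
consensus is symmetrized every iteration (averaged with its own
reflected-relabelled copy), which keeps it exactly mirror-invariant and
makes each specimen's symmetric component — the mean of its two aligned
copies — exactly invariant under reflection-relabelling (the residual is
machine precision, not just < 1e-8). The asymmetric component is the
aligned original minus the symmetric component, so the decomposition is
exact by construction. The reflection axis is the first coordinate axis by
convention; because the joint superimposition absorbs orientation, the
choice is immaterial (tested as a property, agreement within 1e-6 after
matching). All downstream shape statistics consume the symmetric
component; the asymmetric component is computed and returned but not used
by the pipeline presets.

**Missing landmarks** (`missing_landmarks.estimate_missing`). Within each
group (species), the reference is the Procrustes mean shape of the group's
*complete* specimens; groups whose specimens are all incomplete are an
error rather than a guess. An incomplete specimen is first superimposed on
the reference using its present landmarks (center, scale by the CS ratio,
rotate), a thin-plate spline is fitted from the reference's
present-landmark subset to the specimen (exact interpolation, kernel
U(r) = r in 3D and r² log r in 2D, solved from the standard
[[K, P], [Pᵀ, 0]] system), and the spline is evaluated at the reference
positions of the missing landmarks; estimates are transformed back to the
specimen's original frame. Superimposing first means the spline models
shape difference, not pose. TPS reproduces affine maps exactly, so
affinely deformed copies are recovered to numerical precision; under
landmark noise of σ (fraction of CS) the RMS estimation error is ≈ σ
(empirically < 3σ at σ = 0.5 % CS). Estimation is single-pass and
idempotent on complete data.

## Permutational linear models (RRPP)

`rrpp_stats.fit_rrpp` fits ordered linear models to multivariate responses
with sequential (type I) sums of squares: the null model for each term is
all preceding terms. Factors are encoded as one-hot blocks; interactions
and nesting (e.g. `region:island` for islands within regions) are products
of one-hot blocks with aliased columns dropped by incremental rank checks,
so the island-within-region term automatically gets (islands − regions)
degrees of freedom. The statistic per term is
F = (SS_term/df_term)/(RSS_full/df_residual), with the residual taken from
the complete model, so the observed univariate single-factor F equals the
classical ANOVA F exactly.

Significance is by randomized residual permutation: residuals of the
reduced model are row-permuted and added back to its fitted values, the
statistic is recomputed, and the observed arrangement counts as one
permutation, so p ≥ 1/(iterations + 1) — with the conventional 9999
permutations the floor is 1e-4, which is why very strong effects report
p = 0.0001 (formatted "< 0.001"). One permutation schedule, drawn once
from the seed, is shared across terms, making results bit-reproducible and
giving all terms identical resamples. An explicit permutation matrix can
be supplied for exhaustive enumeration on tiny samples. The effect size Z
is the standard deviate of the observed statistic within its permutation
distribution, computed on log F for F-type statistics (floored at 1e-12
before the log) and on raw values for distances; degenerate distributions
(sd = 0) return Z = 0 with a warning.

**Pairwise group distances** (`pairwise_groups`). The observed statistic
per group pair is the Euclidean distance between covariate-adjusted group
means (for shape responses this is the Procrustes distance between
adjusted mean shapes). Group means are least-squares means from the full
model: each group's observed design rows with covariates replaced by grand
means and genuinely crossed factors (e.g. sex) balanced explicitly;
factors nested in the group (e.g. islands within species) stay at the
group's observed composition, so the prediction never extrapolates to
factor combinations that cannot occur. The permutation scheme resamples
*null-model* residuals (the null model omits the group terms), so
covariate effects are excluded from the test; each pair reports d, the
95th percentile of the permuted distances (UCL95), Z (identity transform)
and p.

A useful conservatism falls out of this construction: when testing a
coarse factor (region) in the presence of genuine finer-scale structure
(islands), the permuted residuals still contain the island variance, so
the coarse term's null distribution is widened and the test under-rejects
rather than over-rejects. This is why the island-level pattern — region
non-significant, island-within-region significant — is detected reliably
(≥ 95/100 seeded runs in the acceptance suite).

## Allometric size correction of linear traits

For each trait Y the allometric slope b is the OLS slope of log Y on
log SVL (natural logs; b is base-invariant) over the analysis subset —
pooled across species for interspecific analyses, within species for
intraspecific ones. Each measurement is standardized to the subset's mean
size with Z_i = Y_i (SVL̄/SVL_i)^b, which is exact (Z = Y) at
SVL_i = SVL̄ and removes the fitted size trend (residual log-log slope
|b̂| < 0.02 at n = 500, σ = 0.05). Mass is corrected with the same formula;
its fitted b (≈ 3) absorbs the cubic expectation. SVL itself is excluded
from the corrected response set. Corrected traits are z-scored per column
(ddof = 1) before entering multivariate models; "loadings" are emitted in
both conventions (unit eigenvectors, and eigenvector × √eigenvalue, which
can exceed 1).

A structural property of this correction worth knowing: the pooled slope
is an OLS fit, so any between-species mean pattern that is collinear with
species mean size is largely absorbed by it — the fraction surviving is
the within/(within+between) share of log-SVL variance. Under a *purely*
additive log-linear generating model the surviving species pattern is a
fixed quadratic contrast across the three species. Realistic species
separation after correction therefore requires species-specific allometric
trajectories, which is how the trait generator produces its effects (and
is the biological reason intraspecific analyses re-estimate b within
species).

## PCA and digitization-error check

PCA is by SVD of the column-centered matrix; eigenvalues are singular
values squared over (n − 1), retained rank min(n − 1, p), and each
eigenvector's sign is fixed so its largest-magnitude element is positive
(deterministic output). Shape PCA runs on the flattened symmetric-
component coordinates; `pc_extreme_shape` reconstructs the landmark shape
at any score along an axis. `replicate_error_check` compares the mean
pairwise Procrustes distance among digitization replicates of the same
specimen with the mean distance among distinct conspecifics; ratios well
below 1 indicate negligible landmarking error.

## Micro-CT thresholding protocol

Volumes are float intensity grids with per-axis spacing; multipage TIFF is
the supported on-disk format (no NRRD reader in this environment's stack).

**Half-maximum-height** (`global_halfmax_threshold`): rough bone and
background seed masks are shrunk by Euclidean-ball erosion (10 and 30
voxels by default, implemented as distance-transform > radius so the seeds
contain only pure material), the mean gray value of each eroded seed gives
a (bone) and b (background), and the volume is thresholded at
(a − b)/2 + b. Empty eroded seeds are an error naming the offending radius.

**Local Otsu with reslicing and 2-of-3 voting** (`otsu_vote_segmentation`):
per-slice local Otsu thresholds (square neighborhoods of half-width 5,
256-bin histograms over the slice range) are applied to the original stack
and two axis-permuted ("resliced") stacks, mapped back, and combined by a
voxel-wise 2-of-3 majority vote. Two stabilizations make the per-pixel
Otsu rule usable on whole volumes:

1. *Bimodality guard.* Otsu's criterion degrades in windows that do not
   genuinely contain two materials — it splits pure noise, and in windows
   barely grazing the minority material the threshold can sit anywhere on
   the empty-intensity-gap plateau. A window uses its local threshold only
   if its variance exceeds what a ~20 % minority mixture at the
   volume-level class separation would produce (plus 4× the median window
   variance, a robust noise estimate); all other windows fall back to a
   volume-level threshold, the midpoint of the two class means of a global
   256-bin Otsu split — i.e. a half-maximum-height style global value.
   Constant slices and volumes classify entirely as background.
2. *Plateau centering.* Within accepted windows the local threshold is
   polished by three class-mean-midpoint (isodata-style) iterations, which
   centers it in the intensity gap instead of at an arbitrary plateau
   point.

With these choices the two protocols agree to within 0–1 voxels on
two-material phantoms at the default noise level (class separation
120, σ = 10, SNR 12): disagreement ≪ 1 % of voxels and confined to ≤ 2
voxels of the true boundary, matching what one observes comparing the two
protocols on real scans. At substantially lower SNR (≈ 6) the noise tails
of the two materials overlap the threshold region and scattered
disagreements away from the boundary become physically unavoidable for any
pair of slightly different thresholds; the protocol comparison is
meaningful at the SNR of practical bone µCT.

`segmentation_compare` reports disagreement voxel count, Dice coefficient,
and the symmetric maximum surface-to-surface voxel distance (directed both
ways over voxelized surfaces).

## Synthetic data: what it emulates and what it does not

`synthetic_data` generates the three data types with recorded ground truth;
every generator is bit-reproducible from its seed.

**Landmarks.** A mirror-symmetric template (pairs interleaved left/right
plus midline points on the reflection plane, unit CS) is perturbed by
group, sex and allometric displacement fields and by symmetric individual
variation, all of which are mirror-symmetric tangent-space fields:
orthogonalized against translations, the scaling direction and
infinitesimal rotations, so that the norm of an effect difference *is* the
expected Procrustes distance between group mean shapes. Fluctuating
asymmetry and digitization error are independent per-landmark noise. Each
configuration is then randomly rotated, scaled to a lognormal centroid
size and translated; missingness is completely at random, capped at 20 %
per specimen, with the first specimen per group kept complete.
Defaults mirror a three-species cranial study: 54 pairs + 12 midline
landmarks (mandible preset: 24 pairs), group sizes 17/16/9, prescribed
between-species mean-shape distances of 0.066/0.107/0.159 (cranium) and
0.083/0.142/0.213 (mandible) embedded exactly via a triangle construction
in a 2-plane of symmetric tangent fields, per-coordinate symmetric noise
0.002, asymmetry 0.001 and digitization noise 0.0005 (units of CS),
allometry 0.015 per unit log-size, sex effect 0.015, size spread 0.15
(log). Not emulated: realistic skull geometry, correlated (non-isotropic)
landmark covariance, ontogeny, and phylogenetic structure — so passing
recovery tests demonstrates correctness of the estimators under the
model's assumptions, not robustness to their violation.

**Traits.** log Y = log a + b log SVL + species trajectory deviation ×
log SVL + sex effect + island effect + N(0, 0.05²), with near-isometric
slopes for the nine linear traits and b = 3 for mass, species mean SVL
65–120 mm, and measurements rounded as with calipers/ruler/scale (0.01 mm
/ 1 mm / 0.5 g). Three species at n = 246/206/115 (567 total) across a
shared island pool (most islands host more than one species, so island
terms are crossed with species, not nested). Species separation is carried
mainly by trajectory (slope) deviations for the structural reason given
above.

**CT phantoms.** Voxelized ellipsoids/tubes at a bone intensity over a
background intensity with additive Gaussian noise (defaults 180/60,
σ = 10) and the exact truth mask. No partial-volume blur, beam hardening
or ring artifacts — the protocol comparison on phantoms is therefore a
best case for both methods equally.

## Pipelines, presets and reporting

`run_3d_analysis`: estimate_missing (within species) → GPA → symmetry
decomposition → RRPP on the flattened symmetric components with terms
logCS + sex + species + sex:species (species preset) or
logCS + sex + region (intraspecific preset) → pairwise against the null
model without the group terms → PCA with PC-extreme shapes.
`run_2d_analysis`: drop incomplete rows → allometric slopes (within the
analysis subset) → size correction → z-scoring → RRPP
(sex + species + sex:species + island interspecific;
sex + region + region:island intraspecific; sex + locality for the
within-island preset) → pairwise → PCA with both loading conventions.
Term order is configurable (sequential SS depend on it); the presets put
covariates first, grouping factors next, interactions last. Each run
writes anova.csv, pairwise.csv (d, UCL95, Z, p, formatted p), PCA scores
and variance tables, a stage log accounting for every specimen, and a
PC1–PC2 SVG. Defaults use 9999 permutations and one master seed; reports
are bit-reproducible from (input, seed).

## Known limitations

- Procrustes-aligned coordinates are analysed without tangent-space
  projection (negligible at small shape variation, documented above).
- Only object symmetry (midline-bisected structures) is implemented, and
  the measurement-error / sides ANOVA of fluctuating-asymmetry studies is
  out of scope.
- Sequential SS means non-final terms' SS depend on term order; the order
  is part of the model specification and is logged.
- The local-Otsu guard assumes most windows are single-material when
  estimating noise variance (true for skeletal µCT; not for dense
  textures).
- Trait and landmark generators draw effects from fixed directions per
  seed; they are study-condition emulators, not fitted models of any real
  dataset.
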