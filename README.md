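# morphodiverge

Geometric and multivariate morphometrics for testing inter- and
intraspecific divergence — built for the kind of question that comes up
with cryptic species on archipelagos: are the named species
morphologically distinct, and does within-species variation follow broad
geographic regions or individual islands?

The package covers the full workflow from raw data to inference:

- **Landmark I/O** — 3D Slicer markups (`.mrk.json`), FCSV fiducials and
  TPS files, with homology by label, validated bilateral pairing
  (left/right pairs + midline), and missing landmarks carried as masks.
- **Superimposition** — generalized Procrustes analysis (GPA): centroid
  size CS = √Σ‖xⱼ − x̄‖², scaling to unit CS, centering, and
  reflection-free Kabsch rotations against an iterated consensus.
- **Bilateral symmetry** — object-symmetry decomposition: each specimen
  and its mirrored, pair-relabelled copy are superimposed jointly; the
  symmetric component (the average of the two aligned copies) is the
  response for all shape statistics, and the asymmetric remainder is
  returned alongside.
- **Missing landmarks** — exact thin-plate-spline interpolation from the
  within-species Procrustes mean shape onto each incomplete specimen.
- **RRPP statistics** — permutational (multivariate) ANOVA by randomized
  residual permutation: sequential SS over an ordered term list
  (covariates such as log CS and sex first), F statistics, permutation
  p-values with the observed arrangement included (floor 1/(iter+1)),
  effect sizes Z as standard deviates of log F, and post-hoc pairwise
  distances d between covariate-adjusted group means with permutation
  UCL95 and p. Nesting (`region:island`) is supported in the formulas.
- **Allometry** — size correction of linear traits by
  Z = Y·(SVL̄/SVL)ᵇ with b the log–log OLS slope per trait, then
  per-column standardization for multivariate analysis.
- **Ordination** — PCA (SVD-based, deterministic signs), PC-extreme
  landmark shapes, and a digitization-replicate error check.
- **µCT segmentation thresholds** — the half-maximum-height global
  threshold (a−b)/2 + b from eroded bone/background seeds, slice-wise
  local Otsu thresholding with reslicing in three directions combined by a
  2-of-3 voxel vote, and segmentation comparison (Dice, boundary
  distances).
- **Synthetic data** — generators for bilaterally symmetric landmark
  datasets, log-log allometric trait tables and two-material CT phantoms,
  each with recorded ground truth, used throughout the test suite for
  parameter-recovery checks.

## Worked example

Simulate a study-like cranial dataset (three species, n = 17/16/9,
120 landmarks = 54 bilateral pairs + 12 midline, a few landmarks missing)
and run the full 3D pipeline — missing-landmark estimation, GPA, symmetry
decomposition, permutational MANOVA with 999 permutations, pairwise shape
distances, PCA:

```python
from morphodiverge import run_3d_analysis
from morphodiverge.synthetic_data import simulate_landmarks, study_landmark_params

dataset, truth = simulate_landmarks(study_landmark_params(seed=1))
bundle = run_3d_analysis(dataset, iter=999, seed=42)
print(bundle.anova.round(4))
print(bundle.pairwise.round(4))
```

```
             df      SS      MS     Rsq        F       Z      p
logCS         1  0.0920  0.0920  0.4182  58.1351  6.0459  0.001
sex           1  0.0053  0.0053  0.0240   3.3294  2.8580  0.006
species       2  0.0642  0.0321  0.2919  20.2859  7.5018  0.001
sex:species   2  0.0031  0.0016  0.0141   0.9812 -0.1120  0.546
Residuals    35  0.0554  0.0016  0.2518     NaN     NaN    NaN
Total        41  0.2200     NaN  1.0000     NaN     NaN    NaN

              d   UCL95        Z      p p_formatted
sey:tac  0.0671  0.0369   6.5593  0.001      < 0.01
sey:tra  0.1086  0.0449  10.1865  0.001      < 0.01
tac:tra  0.1597  0.0615  10.7947  0.001      < 0.01
```

Reading this: shape covaries with size (logCS, R² = 0.42) and differs
between the sexes, and after adjusting for both, species explain 29 % of
shape variance (p at the permutation floor). The pairwise rows are
Procrustes distances between covariate-adjusted species mean shapes; each
observed d sits far above its permutation 95 % upper confidence limit, so
all three species pairs are distinct. The generator placed the species
mean shapes at distances 0.066/0.107/0.159 — the pipeline recovers
0.067/0.109/0.160. The first two PCs carry 71 % of the symmetric shape
variation (`bundle.pca_variance`).

The same object exposes the run log (`bundle.log_lines` — e.g.
"estimate_missing: estimated 17 landmarks in 15 specimens"), PCA scores,
and PC-extreme shapes. `run_2d_analysis` is the trait-table counterpart
(size correction → standardization → MANOVA → pairwise → PCA), with
intraspecific presets that test region with islands nested inside it.

There is also a thin CLI:

```bash
morphodiverge simulate landmarks --seed 1 --out sim/
morphodiverge run --config run.yaml        # analysis preset, iter, seed, paths
morphodiverge sizecorrect --in traits.csv --out corrected.csv --scope global
```

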