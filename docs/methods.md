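# Methods

This note records the scientific model behind `fatomics`, the numerical
conventions it fixes, the choices made where the design was genuinely open,
and what the synthetic oracles do and do not establish.

## Imaging model and conventions

Volumes are HU-calibrated 3D grids with physical spacing `(dz, dy, dx)` in
mm, axis order `(slice, row, col)`; the top of the heart is the highest
slice index. Coordinates are voxel-center based: position = origin +
index·spacing. Typical calcium-score geometry is strongly anisotropic
(2.5 mm slices, 0.5 mm pixels), so every geometric operator — erosion,
thickness rays, principal axes — works in physical millimeters, never in
voxel counts.

The pericardial-sac mask is an input. Automatic pericardium segmentation is
out of scope; any segmentation source works as long as mask and volume
share geometry.

## EAT derivation

Noise is reduced with a 2D 3×3 median filter applied per axial slice
(slice-wise because the slice spacing is five times the pixel pitch;
a 3D kernel would smear across 2.5 mm). EAT is then the sac voxels with
attenuation in the fat window **[−190, −30] HU inclusive** on the filtered
volume. The window bounds are the conventional CT adipose range and match
the span of the histogram-bin features exactly; widening the window can
only add voxels (monotonicity is asserted in tests).

## Subregions

*Axial slabs.* The occupied slice range of the sac is split into four
consecutive blocks `PQ1` (bottom) … `PQ4` (top). When the count is not
divisible by 4, remainder slices go to the bottom-most slabs first, so
block sizes differ by at most one. Using the sac's occupied range (not the
scan extent) makes `PQ4` track the top of the heart regardless of scan
coverage.

*Radial shells.* With `L` the sac's major principal axis length, shells of
width `w = L/8` are peeled from the outside in: `Shellᵢ =
erode₍ᵢ₋₁₎·w(sac) \ erodeᵢ·w(sac)` for i = 1..3, and `Shell4` is the
remaining core. Erosion thresholds the anisotropy-aware Euclidean distance
transform, so shell widths are true millimeters. `w = L/8` is one
consistent reading of "equidistant shells scaled by the major axis"; with
it, four shells of width `w` reach roughly halfway to the centroid of a
convex sac, and `Shell4` absorbs the remainder. `Shell4` may come out
empty for flat sacs; this is flagged, not fatal. Both subdivisions exactly
partition the sac voxelwise, and the partitions are asserted, not assumed.

## Feature catalog (148)

The catalog is a fixed, ordered registry: 7 morphology + 7 HU statistics +
24 HU histogram + 14 thickness = 52 global features, plus 12 features ×
8 subregions = 96. Per subregion: EAT volume, HU mean/SD/skewness, and the
8 fat-window bin volumes. This composition reproduces the published total
and contains every individually named feature (`vol_50_30`,
`Negative_skewness`, `Vol_PQ4`, `Thickness_Kurtosis`, axis lengths, …);
where the full enumeration was not published, the registry makes this
package's reconstruction explicit and machine-readable
(`FeatureCatalog.to_records()`).

Statistical conventions, fixed for determinism: population moments
(ddof = 0), Fisher skewness g₁, **non-excess** kurtosis (Gaussian → 3).
Principal axis lengths use the `4·√λ` convention on the covariance of sac
voxel centers (for a uniform ellipsoid with semi-axis a, λ = a²/5, so the
reported length is ≈1.789a — an axis-length *scale*, not the diameter).
Subregions whose EAT contains fewer than 3 voxels report 0 for the
undefined HU statistics; globally, fewer than 3 EAT voxels is an error.

## Thickness mapping

Rays leave the sac's physical center of mass in all 64,800 directions of
the 1° grid (polar φ ∈ {0..179}°, azimuth θ ∈ {0..359}°), marching in
steps of `min(spacing)/2` until past the sac's bounding sphere. Thickness
is the Euclidean distance between the first and last in-fat samples; rays
that never meet fat contribute 0, so every study yields exactly 64,800
measurements.

Membership is decided by trilinear interpolation of the binary EAT mask
with a 0.5 threshold rather than a nearest-voxel lookup. A nearest-voxel
test leaves the fat boundary on jagged voxel faces and its worst-case
boundary error approaches a full voxel diagonal — measured against the
spherical-shell oracle it misses the ray_step + half-diagonal accuracy
budget on ~2% of rays. The interpolated boundary sits midway between voxel
centers; the same oracle then shows a worst-case error of one voxel
(within budget everywhere). Map statistics use all 64,800 values including
zeros; the fixed bins are [0,8), [8,16), [16,24), [24,32] mm, reported as
both counts and fractions of 64,800.

## Survival modeling

*mRMR.* Greedy selection with relevance = |z| of the univariable Cox fit
(Breslow ties, Newton–Raphson, z-scored feature), scaled to [0,1] by the
largest |z| so that relevance and redundancy (mean |Pearson r| with the
already-selected set) are commensurate in the difference criterion
`relevance − redundancy`. With raw |z| the difference form fails its own
sanity property — an exact duplicate of a strong feature would beat weaker
informative candidates; scaling restores it while keeping the difference
form (more stable than a quotient near zero redundancy). Constant columns
get relevance and redundancy 0 and are selected last. Selection is
deterministic (index-order tie-break).

*Cox elastic net.* Penalty λ·Σ(α|β| + (1−α)β²/2) with α = 0.8, fit on
internally standardized columns (coefficients reported on the original
scale) over a log-spaced λ path via coordinate descent (scikit-survival's
glmnet-family backend, Breslow ties). λ is chosen to minimize 10-fold
cross-validated partial-likelihood deviance (the "λ.min" convention; folds
stratified by event, seeded). If the optimum admits more than
`max_features` (default 15) nonzero coefficients, the penalty is
re-tightened along the already-computed path until the active set fits the
cap — the sparsity target is a modeling constraint, not a re-fit.

*Evaluation.* Harrell's C uses the exact pairwise definition (comparable
iff tᵢ < tⱼ and eventᵢ = 1; score ties count ½) and is verified against a
brute-force O(n²) enumeration. The 2-year AUC is the IPCW
cumulative/dynamic estimator. AIC refits the active set unpenalized
(−2·logPL + 2k). KM stratification splits at the median risk; the group HR
comes from a univariable Cox fit on the indicator. Bootstrap validation
resamples subjects with replacement, refits the fixed-feature model (λ by
CV each time) and scores the out-of-bag subjects — the less optimistic
convention, chosen deliberately. Categorical NRI uses two categories at
each model's median; subjects censored before the horizon are handled by
inverse-probability-of-censoring weights (1/G(T⁻) for cases, 1/G(t) for
horizon survivors) rather than exclusion.

The pipeline splits 80/20 stratified by event, selects and fits on the
training split only, and writes an audit log of the study ids each stage
touched; a leakage check asserts no test id was available to selection or
fitting.

## Synthetic oracles

*Phantoms.* Ellipsoidal sacs voxelized on (by default) a scaled-down
128×128×40 grid at (2.5, 2, 2) mm — the clinical 512² × 0.5 mm geometry is
a preset. The EAT shell contains the sac voxels whose radial distance to
the boundary (along the ray from the sac center; analytic for an
ellipsoid) is at most a controllable thickness field t(φ,θ): constant,
top-bottom gradient, or lobed t₀ + a·cosθ·sinφ. The radial construction is
exact — an earlier distance-transform construction biased the shell thin
by ~half a voxel because voxel-to-background-voxel distances overestimate
distances to the continuous surface — and coincides with the normal-depth
reading for spheres. HU is drawn per region (background −900, core +40,
EAT from a Gaussian or skew-normal; the skew-normal exists to give
`Negative_skewness` and `Pro_50_30` analytic targets). Phantoms do not
model cardiac anatomy, motion, beam hardening, or partial-volume blur, so
passing geometry tests demonstrates correctness of the measurement
machinery, not segmentation robustness on real CT.

*Cohorts.* Event times invert a Weibull proportional-hazards model
(default shape 1.2, scale 1000 days) with a known coefficient vector on
z-scored features; administrative uniform censoring C ~ U(0, w) has w
calibrated by bisection to the target event fraction (default 56%, the
enriched-event design; maximum follow-up 6 years). The feature-table
simulator draws 148 catalog-named columns from a low-rank latent-factor
model with per-category scale transforms — it reproduces the block
correlation of real fat-omics tables for modeling-scale experiments where
extracting hundreds of phantoms would be wasteful, but its columns are not
physically consistent with any single phantom (e.g. bin volumes need not
sum to the total); conclusions drawn from it concern the modeling stack
only.

## Problem sizes and defaults

Unit and acceptance tests use phantoms of ~10⁵–10⁶ voxels, simulated
cohorts of 200–5,000 subjects, 100-seed recovery sweeps, and reduced
bootstrap iteration counts (the production default remains 1,000); these
sizes give stable assertions at interactive runtimes. Default pipeline
settings: fat window [−190, −30] HU, mRMR k = 50, α = 0.8, 10 folds,
15-feature cap, 2-year AUC horizon, 80/20 event-stratified split, minimum
follow-up 10 days.

## Known limitations

- The exact identity of a clinically selected 15-feature set depends on
  the cohort; this package treats the *procedure* as the contract.
- Radial shells interpret "equidistant" as w = L/8; other widths are
  possible readings.
- Thickness rays assume the sac centroid lies inside the sac (true for
  convex and mildly concave sacs); strongly concave shapes would need a
  surface-normal formulation.
- No competing risks, time-varying covariates, or calibration analysis.
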