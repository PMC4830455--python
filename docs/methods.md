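# Methods

## The measurement model

A carbonate block is scanned twice — before and after a field deployment —
producing two 3D intensity volumes on isotropic voxel grids. The block is
rigid, so the only geometric difference between the scans is a 6-parameter
rigid transform (scanner placement) plus the biological change of interest:
voxels of CaCO₃ removed by borers and grazers, and voxels added by
encrusting calcifiers. The analysis is deliberately **binary**: a voxel
either holds CaCO₃ or it does not. Density change below whole-voxel loss is
invisible by construction — this is the most conservative reading of the
scans, and it avoids mistaking partial-volume intensity shifts for real
change. Consequently the method cannot see microborers whose scars are
smaller than the working voxel (100 µm), nor chemical dissolution that
thins but does not remove skeletal elements.

Pipeline stages and their contracts:

1. **Block averaging** (`preprocess.downsample_mean`). Each output voxel is
   the arithmetic mean of a `factor³` input block; total intensity over the
   cropped region is conserved to 1e-9 relative. The voxel edge scales by
   the factor (50 µm native → 100 µm working).
2. **Global threshold** (`preprocess.apply_threshold`). Solid where
   intensity ≥ 200 CT units (boundary inclusive, configurable). The
   threshold is applied *after* averaging and *after* registration
   resampling, so pre and post masks derive from the same rule.
3. **Rigid registration** (`registration.register`). Estimated on the raw
   working-resolution intensities (not the binary masks), pre scan fixed,
   post scan moving. The transform maps fixed-frame physical points x to
   moving-frame points y = R(x−c) + c + t, with R an Euler z-y-x rotation
   about the fixed volume's centre c and t a translation in µm.
4. **Subtraction** (`differencing.subtract_binary`). post − pre on {0,1}
   gives the trinary change map; `summarize` counts each sign and converts
   to m³ with the voxel volume. Two exact identities hold for every input
   and are enforced by tests: |post| − |pre| = |accreted| − |eroded|, and
   swapping pre/post swaps the two counts.
5. **Rates** (`rates`). Bioerosion in kg m⁻² yr⁻¹, secondary accretion in
   mm yr⁻¹, net change in % yr⁻¹, using the block's bulk skeletal density
   (default 1570 kg m⁻³, the mean of buoyant-weight measurements on dead
   massive *Porites* blocks), the pre-deployment surface area, and the
   deployment time in decimal years (days/365.25 — a 376-day deployment is
   1.0294 yr). Surface area always comes from the **pre**-deployment mask.

## Registration details

- **Metric**: mutual information of the 50×50 joint intensity histogram,
  intensities binned linearly over each image's range, moving image
  linearly interpolated. `mattes_mi` on identical images equals the
  Shannon entropy of the binned histogram (a test oracle); against a
  constant image it is 0.
- **Optimizer**: (1+1) evolution strategy. Parameters are normalized so one
  unit of rotation (1 rad) and one unit of translation (the volume's
  half-diagonal) displace the block edge comparably. Proposals are
  parent + radius·N(0, I); improvements are accepted and grow the radius
  (×1.05), failures shrink it (×0.98); termination at radius ≤ 1.5e-6 or
  200 iterations per pyramid level (×4, ×2, ×1 mean-downsampling levels,
  each seeded with the previous solution). All settings are exposed in
  `RegistrationConfig`; a fixed seed makes the result bit-identical.
- **Polish**: after the ES, a deterministic Powell refinement of the metric
  (default on, `refine=False` for the bare ES). The ES reliably reaches the
  right basin but stalls at ~0.1 voxel; the polish brings the residual to
  ~0.01–0.03 voxel, which matters because every 0.1 voxel of residual
  misalignment flips boundary voxels in the subtraction.
- **Metric smoothing**: both volumes are Gaussian-smoothed (σ = 1 voxel,
  `metric_smoothing_sigma`) before metric evaluation — for the metric only.
  Without it, interpolation of the moving image smooths its *noise* at
  fractional offsets, inflating MI there and biasing the optimum by
  ~0.15 voxel away from integer-voxel alignments (the classic MI
  interpolation artifact). Smoothing both images suppresses the differential
  and leaves the optimum within ~0.04 voxel of truth on noisy phantoms.
- Registration direction and the resample-then-rethreshold order follow the
  stage contracts above; out-of-field voxels fill with air (0). An optional
  centre-of-mass pre-alignment exists (`center_of_mass_init`, off by
  default).

## The phantom: a stated world

`phantom.make_phantom_pair` generates a pre/post scan pair with exact
ground truth. Defaults describe a desk-scale version of the field
experiment:

- grid 64×128×128 voxels at 100 µm with a 16-voxel air margin; the margin
  must absorb the misalignment sweep of the block corners (rendering raises
  if the block clips the grid);
- porosity: a white-noise field smoothed with an isotropic Gaussian
  (correlation length 500 µm ≈ the trabecular/pore scale of massive
  *Porites* skeleton) and thresholded at the quantile giving solid
  fraction 0.5 — a texture proxy, not a microstructure model;
- intensities: solid 400, air 0, noise sd 20 (5% of contrast). The solid
  intensity is chosen so the pipeline's 200-unit threshold sits at **half
  the contrast**: binarization after interpolation is then the
  median-unbiased voxelization, with a ~0.25-voxel robustness margin
  against residual misalignment on flat interfaces;
- bioerosion: 6 capsule-shaped borings (radius 2–3, length 15–30 voxels)
  entering from the outer surface toward the block interior, plus 2 shallow
  grazing scars (spherical caps, 2 voxels deep) — together ~1–2% of the
  solid; accretion: 3 crust patches grown by 26-connected constrained
  dilation (1–2 voxels thick) on the outer envelope, ~1% of the solid.
  Erosion and accretion are restricted to the block's outer envelope
  (morphological closing), where organisms actually act;
- one seeded RNG drives every stage in fixed order, so a spec+seed pair is
  fully reproducible; the recorded truth masks are the *net* changes
  (pre\post and post\pre), which satisfy the set identities exactly.

What a green phantom test establishes: the pipeline recovers a known rigid
misalignment to ~0.03 voxel and known change volumes to a few percent under
realistic noise. What it does not establish: performance on real scanner
physics (beam hardening, ring artifacts, spatially varying PSF), real
*Porites* microstructure (sub-voxel porosity), or partial dissolution —
all outside the stated world.

## Driver statistics

Environmental drivers along a reef transect co-vary with position, so each
variable is replaced by its residuals from an OLS regression on depth and
distance from shore before model fitting; right-skewed predictors (mean
chlorophyll *a*, mean DIN:DIP) are natural-log transformed first (the
log-then-residualize order is configurable). Responses are square-root
transformed; net change, which can be negative, uses the signed square
root sign(x)·√|x| — an explicit package choice, flagged in the output,
since a plain square root is undefined there.

Model ranking uses AICc = −2 logL + 2m + 2m(m+1)/(n−m−1) with logL the
maximized Gaussian likelihood (ML variance RSS/n, the standard convention
for AIC) and m the number of regression coefficients including the
intercept. Ranking tables conventionally print k = m + 1, counting the
residual variance; both counts are reported, and `penalty="all_params"`
switches the penalty to k for users who prefer that convention. Ties rank
the smaller model first. Effect sizes are |β| from a refit on z-scored
predictors and response: for a single predictor this equals |Pearson r|
exactly; for multi-predictor models they are partial standardized
coefficients with standard errors.

The synthetic transect world (`simulate_block_environment`,
`simulate_rates`) places 20 blocks along a 32-m transect (depth 0.5–4.5 m)
with position-correlated pH, nutrients, chlorophyll and temperature
anomalies. Bioerosion-like rates are generated on the square-root scale
from the pH residuals with slope −22.29 and intercept 0.55; the residual
noise sd (0.129) is the ML estimate implied by a Gaussian log-likelihood
of 12.54 at n = 20, and the pH residual spread (sd 0.0058) then makes the
driver explain half the variance, matching the reported fit quality. With
those values the correct driver wins the AICc ranking in roughly 92–94% of
replicates — an honest property of a true R² of 0.50 at n = 20 against
five competitor models, two of which cost only one coefficient.

## Numerical choices

- Threshold boundary rule is ≥ (includes the threshold value); raising the
  threshold never increases the solid count.
- `downsample_mean` crops trailing voxels of non-divisible dimensions and
  logs the crop.
- `largest_component` (optional, off by default) breaks size ties by the
  component whose first voxel comes earliest in (z, y, x) raster order.
- Mesh surface area anti-aliases the binary mask (Gaussian σ = 1 voxel)
  before marching cubes at level 0.5; the raw staircase isosurface
  overestimates a sphere's area by ~9%, the anti-aliased one is within
  0.5%. `voxel_face` (exact face counting) is the documented alternative
  and an upper bound for convex solids.
- NIfTI-1 headers store voxel size as float32; the writer records the exact
  edge length in the header's `descrip` field, which the reader prefers,
  so round trips through our own files preserve the voxel edge exactly.
  Files from other writers are read to float32 precision.
- Change maps are written as signed 8-bit with a JSON legend sidecar.

## Known limitations

- Rigid-only alignment (an affine option exists for calibration drift, but
  deformation is out of scope — blocks are rigid).
- No morphological cleanup of the change map by default; an optional
  minimum-cluster-size filter (26-connectivity) is available.
- The phantom's porosity proxy is not calibrated to real coral
  microstructure; bulk density is matched, micro-scale porosity is not.
- Scanner-side steps (projection averaging, reconstruction) are upstream of
  this package; input is a reconstructed intensity volume.
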