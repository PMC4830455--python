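# coralct

Volumetric differencing of before/after microCT scans of experimental
carbonate blocks, for coral-reef carbonate-budget studies.

Reef growth is a balance between accretion and destruction. Besides coral
growth itself, two processes act on every exposed carbonate surface:
**bioerosion** (removal of CaCO₃ by boring bivalves, sponges, worms, and
grazing parrotfish and urchins) and **secondary accretion** (new CaCO₃ laid
down by crustose coralline algae and encrusting invertebrates). Traditional
field methods — buoyant weight, casts, 2D image analysis — either confound
the two processes or cannot attach a rate to them. Scanning the same
experimental block before and after deployment, aligning the two 3D scans,
and digitally subtracting them separates the processes voxel by voxel on
the same substrate and time scale.

`coralct` implements that pipeline and its surrounding analysis:

1. **Preprocess** — block-average the scans to the working resolution
   (50 → 100 µm) and binarize with a single global threshold (200 CT units)
   that separates CaCO₃ from air.
2. **Register** — estimate the 6-parameter rigid transform aligning the
   post-deployment scan onto the pre-deployment scan by maximizing Mattes
   mutual information with a (1+1) evolution strategy over a
   coarse-to-fine pyramid.
3. **Difference** — re-threshold the resampled post scan and subtract the
   binary volumes, giving a trinary change map: +1 new CaCO₃ (accretion),
   −1 lost CaCO₃ (bioerosion), 0 unchanged.
4. **Rates** — sum each sign, multiply by the voxel volume, and convert
   with per-block constants:

   - bioerosion rate (kg m⁻² yr⁻¹) = (Vol_eroded × ρ) / (SA × Time)
   - secondary accretion rate (mm yr⁻¹) = 1000 × Vol_accreted / (SA × Time)
   - net change (% yr⁻¹) = 100 × (V_post − V_pre) / (V_pre × Time)

   with ρ the block's bulk skeletal density, SA the pre-deployment surface
   area and Time the deployment interval in decimal years.
5. **Driver statistics** — residualize environmental variables against
   depth and distance from shore, square-root transform the rates, fit the
   candidate driver models (pH, resource availability, temperature, depth,
   distance, full) and rank them by the small-sample corrected Akaike
   criterion AICc = −2 logL + 2m + 2m(m+1)/(n−m−1); compare effect sizes by
   standardized (z-scored) coefficients.

Because raw scan pairs of this kind are rarely shareable, the `phantom`
module generates synthetic porous-block scan pairs with known borings,
grazing scars, crusts, rigid misalignment and noise, so the whole pipeline
can be validated against exact ground truth.

## Worked example

```python
import numpy as np
from coralct.phantom import PhantomSpec, make_phantom_pair
from coralct.pipeline import PipelineConfig, run_pipeline_volumes
from coralct.preprocess import PreprocessConfig
from coralct.rates import BlockMeta
from coralct.registration import RigidTransform

# synthetic block pair: 5 deg rotation + (3, -2, 5)-voxel shift, 5% noise
spec = PhantomSpec(seed=42)
spec.transform_truth = RigidTransform(
    np.zeros(3), np.array([5.0, 0.0, 0.0]),
    np.array([3.0, -2.0, 5.0]) * spec.voxel_edge)
pre, post, truth = make_phantom_pair(spec)

meta = BlockMeta("demo", density_rho=1570.0, surface_area=7.0e-3,
                 deployment_days=376)
cfg = PipelineConfig(preprocess=PreprocessConfig(downsample_factor=1), seed=42)
report = run_pipeline_volumes(pre, post, meta, cfg)
print(report["transform"]["euler_zyx_deg"])
print(report["summary"], report["rates"])
```

prints (abridged):

```
euler_zyx_deg  [4.9966, -0.0058, -0.0013]        # truth: [5, 0, 0]
translation_um [301.1, -777.1, 1030.7]           # truth: [300.0, -777.6, 1029.3]
n_eroded   3405   (truth 3300, +3.2%)
n_accreted 2680   (truth 2645, +1.3%)
bioerosion_kg_m2_yr   0.000742
accretion_mm_yr       0.000372
net_change_pct_yr    -0.478
```

The recovered transform is accurate to ~0.01 voxel / 0.005° and the eroded
and accreted volumes land within a few percent of the phantom's exact
ground truth. (The rates are small because the desk-scale phantom carves
only ~3 mm³; a real 5×5×2 cm block carries ~1000× the volume.)

The same pipeline is available from the shell:

```sh
coralct phantom --out-dir ph --seed 42 --rotation-deg 5 --shift-voxels 3 -2 5
coralct run --pre ph/pre.nii.gz --post ph/post.nii.gz \
            --meta meta.csv --out-dir results/
coralct modelselect --data blocks.csv --response-column bioerosion_rate \
            --out-table selection.csv --out-coefs coefs.csv
```

Subcommands: `phantom`, `register`, `diff`, `rates`, `modelselect`, `run`.
Volumes are read/written as multipage TIFF, NIfTI-1, or raw binary with a
JSON sidecar; all grids are (z, y, x) with isotropic voxels in µm.

## Acceptance script

`scripts/acceptance.py` recomputes the published small-sample AICc
quantities of the reference study's model-selection table from scratch —
taking each row's printed log-likelihood and parameter count (n = 20
blocks) and evaluating the corrected Akaike formula through
`coralct.driver_stats.aicc`, including the ΔAICc differences between
competing models:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Documentation

See `docs/methods.md` for the model and procedure details, the phantom's
design and its limitations, numerical choices (threshold placement, metric
smoothing, optimizer polish), and known limitations of the method.
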