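# petseg

Comparative delineation of the biological tumour volume (BTV) on
FDG-PET-like images.  The package implements nine segmentation methods from
four families, the image-restoration chain applied before segmentation, the
overlap/error statistics used to score them, and a synthetic 3-D phantom
cohort with exact ground truth on which the whole comparison can be
reproduced end to end.

## Who this is for

Delineating tumours on PET is hard: partial-volume blur (~4-7 mm FWHM),
high noise, and heterogeneous uptake mean that no single algorithm wins
under all conditions, and adaptive thresholds must be recalibrated per
scanner.  `petseg` gives researchers a controlled benchmark: every method
behind one estimator interface, scored against a known truth, with every
parameter logged.

## The nine methods

Thresholding (a threshold `T` in SUV separates lesion from background):

| method     | rule                                                           |
| ---------- | -------------------------------------------------------------- |
| `suvmax40` | T = 40% of SUV_max                                             |
| `biehl`    | %T = 59.1 − 18.5·log10(V [cm³]), solved as a fixed point       |
| `black`    | T = 0.307·(mean target SUV) + 0.588, solved as a fixed point   |
| `nestle`   | T = β·I_mean(70% isocontour) + I_bkg, β = 0.15                 |
| `schaefer` | T/SUV_max = (a·SUV_mean(70%) + b·BKG)/SUV_max, size-dependent a, b |

`biehl` and `black` define `T` through statistics of the region that `T`
itself selects; the circular dependence is solved by Picard iteration from
the 40% SUV_max mask with an oscillation guard.

Variational: `levelset` — a geometric level set ∂φ/∂t = −g(|∇I|)(ν − εκ)|∇φ|
with the geodesic edge-stopping function g(s) = 1/(1+(s/λ)²); the front
(zero crossing of the signed distance φ) shrinks from the 40% initialisation
and freezes on strong image edges.

Stochastic: `em` — a K-class Gaussian mixture fit to the intensity
histogram by expectation-maximisation; the tumour is the highest-mean class
under maximum-responsibility labelling.

Learning: `fcm` and `fcm_sw` — fuzzy c-means minimising
Σᵢₖ u_ik^b‖xᵢ − c_k‖² with memberships u_ik from the inverse-distance
update and u^b-weighted centroids, run with an oversized cluster count
followed by nearest-centroid merging.  `fcm_sw` augments the distance with
two spatially regularising channels compared against the same class
centroid: the anisotropic-diffusion-smoothed image and the coarse-scale
à trous wavelet context, the latter weighted per class by
β_k = β₀(c_k/max c_k)^γ so that spatial context dominates in high-uptake
tissue.  That is what lets it pull a colder necrotic core — invisible to
pure intensity clustering — into the tumour class.

Preprocessing (applied before every method): a 3-D bilateral filter
(spatial kernel 6 mm FWHM, two iterations) followed by Landweber
deconvolution (Gaussian PSF 6 mm FWHM, 30 iterations, nonnegativity
projection).

Scoring: the spatial overlap index SOI = 2|A∩B|/(|A|+|B|) (a Dice-type
score), the voxel classification error CE = (PCE+NCE)/VoIL·100% (can exceed
100%), the relative volume error, and a two-tailed paired t-test of
measured vs reference volumes.

## Worked example

Run the full comparison on a two-case synthetic cohort (heterogeneous
rim/core lesions, 6 mm blur, 0.2 SUV noise, 48³ grid at 2 mm):

```
petseg bench --out demo --n-cases 2 --seed 7 --grid 48 --no-masks
```

which prints the per-method summary table (and writes `results.csv`,
`summary.csv` and `run_config.json` under `demo/`):

```
          n_cases  soi_mean  soi_sd  soi_min  soi_max  rel_vol_err_mean  rel_vol_err_sd  ce_mean  ce_sd  seg_volume_mean_cm3  ref_volume_mean_cm3  volume_p_value
method
biehl           2     0.926   0.010    0.919    0.934             9.860           2.085   15.457  2.276               19.460               17.700           0.128
black           2     0.872   0.012    0.864    0.881            25.424           3.957   28.786  3.268               22.172               17.700           0.034
em              2     0.908   0.005    0.905    0.911            15.401           0.842   19.819  1.127               20.432               17.700           0.060
fcm             2     0.961   0.002    0.960    0.962            -6.021           0.316    7.583  0.321               16.632               17.700           0.059
fcm_sw          2     0.940   0.004    0.937    0.943           -10.695           0.420   11.357  0.815               15.804               17.700           0.054
levelset        2     0.952   0.002    0.951    0.954             3.027           0.530    9.724  0.402               18.232               17.700           0.043
nestle          2     0.911   0.003    0.908    0.913            14.563           0.334   19.157  0.732               20.280               17.700           0.046
schaefer        2     0.961   0.001    0.960    0.962            -5.973           0.384    7.536  0.253               16.640               17.700           0.065
suvmax40        2     0.948   0.004    0.946    0.951             3.889           0.056   10.501  0.756               18.388               17.700           0.030
```

Reading the table: each row is one method scored against the ground-truth
masks of the two phantoms (mean reference volume 17.7 cm³).  `black`
over-segments (+25% volume, CE 29%) because its affine rule was calibrated
for another scanner; the clustering methods and `schaefer` land within a
few percent of the true volume with overlap indices above 0.94.  On
heterogeneous cohorts with a pronounced necrotic core, `fcm_sw`'s CE drops
well below the thresholding methods' (see the cohort acceptance test).

The same pipeline is available as a library:

```python
from petseg import PhantomSpec, make_cohort, preprocess, FCMSWSegmenter
from petseg.benchmark import case_context

(img, truth), = make_cohort(1, PhantomSpec(grid_shape=(64,)*3), master_seed=7)
seed, region, bkg = case_context(truth)
est = FCMSWSegmenter().fit(preprocess(img), seed_point=seed,
                           search_region=region, background_mask=bkg)
print(est.mask_.volume_cm3, truth.volume_cm3)
```

Every segmenter is a scikit-learn style estimator (`get_params`,
`set_params`, `clone`-compatible) whose fitted attributes (`mask_`,
`threshold_`, `state_`, ...) expose the result and diagnostics.

## Layout

- `petseg.volume` — `ImageVolume`/`BinaryMask` containers, NIfTI I/O
- `petseg.phantom` — synthetic phantom specs, blur/noise model, SUV
  conversion, cohort generation
- `petseg.preprocess` — bilateral filter, Landweber deconvolution
- `petseg.thresholding`, `petseg.levelset`, `petseg.clustering` — the nine
  segmenters
- `petseg.metrics` — SOI, CE, volume errors, paired t-test, cohort summary
- `petseg.benchmark`, `petseg.cli` — orchestration and the `petseg` CLI

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
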