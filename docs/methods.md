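# Methods

`ctvi` implements direct CT-to-ventilation translation: a 3-D
encoder–decoder network maps a masked, rescaled free-breathing CT volume
to a SPECT-like ventilation map, with Monte-Carlo dropout (MCD) giving a
per-voxel epistemic-uncertainty estimate. This note records the model,
the assumptions behind the synthetic phantom used to exercise it, and
every numerical choice a maintainer might want to revisit.

## The translation model

**Architecture.** A U-Net with `depth` down-sampling steps. Each encoder
level applies two 3×3×3 convolutions (stride 1, padding 1), each followed
by a leaky ReLU (α = 0.30) and a dropout layer, then a 2×2×2 max-pool;
feature maps double per level (`base_filters · 2^k` at level *k*). Each
decoder level applies a 2×2×2 stride-2 transposed convolution that halves
the feature maps, concatenates the matching encoder features, and repeats
the double-convolution block. A final 1×1×1 convolution with a ReLU
yields the single-channel non-negative output. L2 regularization
(1.0 × 10⁻⁴) is attached to every convolution kernel (not to biases). No
normalization layers are used.

Dropout is placed after *each* convolution's activation. It is standard
element-wise (Bernoulli) dropout, inverted (masks scaled by 1/(1−p) at
sampling time), so evaluation-mode passes need no rescaling and MCD
sampling simply re-enables the training-time masks.

The engine is written directly in NumPy: convolutions are lowered to BLAS
GEMMs via an im2col patch matrix, gradients are hand-derived per layer,
and every layer is verified in the test suite against brute-force loop
oracles and central finite differences in double precision. Weights are
initialized with Glorot-uniform draws from a seeded generator.

**Sizes are configuration, not constants.** Full-scale work uses 128³
inputs at 2.5 mm spacing with depth 4 and 16 base filters; the desk-scale
reference experiment uses 32³ inputs, depth 2, 8 base filters. The code
path is identical.

**Training.** Adam (default lr 5.0 × 10⁻⁵, β₁ 0.90, β₂ 0.999,
ε 1.0 × 10⁻⁷), mean-squared-error loss over the *full* output volume,
batch size 2, up to 1000 epochs with early stopping (patience 50) on the
validation loss, restoring the best-validation weights. The loss includes
the zeroed background deliberately: inputs and targets are masked to the
lung, and a full-volume MSE also teaches the network to output zero
outside it. Cross-validation is five-fold and *group-aware*: all scans of
one patient share a `group_id` and always land in the same fold, and
never straddle the pool/test boundary.

**Inference routes.**

- *standard*: one deterministic pass, dropout off.
- *bagged*: voxel-wise mean of the five fold models' standard passes
  (accumulated in float64, so bagging identical checkpoints is exactly
  the identity).
- *MCD*: `n` stochastic passes with dropout on (default n = 200);
  per-voxel sample mean (the prediction), sample SD with ddof = 1 (the
  uncertainty), and CV = SD/mean (the scaled uncertainty). Only running
  first and second moments are kept (Welford update), so memory is
  independent of `n`; the result matches a naive two-pass computation to
  ~1e−10.
- *bagged MCD*: all `5 × n` samples pooled; the mean map is computed as
  the average of per-fold means (identical by algebra, exact in
  floating point) and the SD is the pooled-sample SD via the standard
  M2-merge formula.

CV guard: voxels with |mean| < 1e−6 in normalized ventilation units get
CV = 0 and are excluded from region-wise CV averages — SD/mean is
meaningless on the zeroed background.

## Preprocessing

Order: optional externally computed rigid transform (default identity) →
resample to the target spacing (trilinear for images, nearest for masks)
→ crop/pad to the target shape about the lung-mask centroid → intensity
transforms → masking.

- **CT rescale**: affine map with −999 HU → 0 and −250 HU → 1, clipped
  below at 0 but *not* above 1. In-lung vessels exceed −250 HU, and the
  point of using raw HU is to preserve the ordering of attenuation
  values; an upper clip would destroy it.
- **Ventilation normalization**: division by the in-lung *median*
  (robust to SPECT count outliers), computed over the CT-derived lung
  mask — the same mask that defines the model's input/output region.
  Post-condition: in-mask median exactly 1.
- **SPECT-derived mask**: threshold at 15 % of the image maximum; used
  only for the registration-quality Dice check, never for training.
- Median/percentile convention throughout: linear interpolation between
  order statistics (NumPy default); even-count medians are midpoints.
- Crop centering: mask centroid rounded to the nearest voxel, half-voxel
  ties toward the lower index; the window is shifted minimally to cover
  the lung bounding box whenever it fits, and a truncation warning with
  the lost-voxel count is raised when it does not. All volumes of a case
  share the identical window.
- Resampling delegates to `scipy.ndimage.zoom` (grid-aligned,
  edge-replicating); output shape is `round(shape · spacing / target)`.

Rigid registration itself is out of scope: the pipeline accepts an
externally computed transform (e.g. from Elastix) as a callable and
defaults to the identity, which is exact for the synthetic phantoms.

## The synthetic phantom

The generator emulates the statistical structure that CT-to-ventilation
translation relies on, at desk scale and with no data download:

- **Anatomy**: two ellipsoidal lungs (default semi-axes 30 × 16 × 11 mm,
  ±10 % per-case jitter) in a 32³ grid at 2.5 mm spacing; soft-tissue
  background at 0 HU.
- **Parenchyma**: Gaussian random field, mean −820 HU, SD 40 HU,
  correlation length 5 mm.
- **Defects**: `defect_count` (default 4, jittered per case) spheres of
  radius 4–9 mm shifted by −90 HU with a smooth halo — emphysema-like
  low-attenuation lesions.
- **Ventilation link**: a sigmoid of HU, increasing over the parenchymal
  range (midpoint −860 HU, width 22 HU): ≈ 0.86 at −820 HU, 0.5 at
  −860 HU, ≈ 0.14 at −900 HU. Tissue below the −856 HU emphysema
  threshold therefore always ventilates below the in-lung median. The
  `coupling` parameter interpolates between this link (1) and a
  HU-independent field (0).
- **Gravity**: a linear ventral-to-dorsal multiplier, default ±10 %
  (slope 0.2), approximating the posture-dependent gradient of real
  ventilation.
- **SPECT degradation**: mask-normalized Gaussian blur (FWHM 2.5 voxels)
  plus multiplicative log-normal noise (σ = 0.3, mean-one). The blur is
  normalized by the blurred mask rather than applied raw: a raw blur
  bleeds counts into the zero background, and at desk scale the boundary
  shell is ~half of all lung voxels, which would swamp the
  HU–ventilation signal. Real partial-volume count loss at the pleural
  boundary is therefore *not* emulated.

Defaults were chosen once for realism at desk scale; with them the
cohort's non-defect ventilation fraction (50 %-of-P90 rule) comes out
near 68 % with a few percent SD, i.e. a predominantly-ventilated cohort
with clear defect burden. A single seeded generator drives everything:
identical parameters and seed give bit-identical volumes.

**What the phantom does not model**: airway trees, tomographic
reconstruction artifacts, attenuation-correction bias, respiratory
motion, true pleural partial-volume loss, and inter-scanner HU
calibration drift. Passing the phantom study shows the pipeline recovers
a monotone attenuation–ventilation relationship with spatial defect
structure under noise — not that it reaches clinical accuracy on real
SPECT/CT pairs.

## Evaluation suite

All indices are computed within the lung mask.

- **Spearman r_s**: average ranks substituted into the product-moment
  correlation form; on tie-free data this equals 1 − 6Σd²/(n(n²−1))
  (asserted to 1e−10 in the tests).
- **Functional regions**: tertiles at the 33.3rd/66.7th in-lung
  percentiles; `low` is strict `<`, `high` is `≥`, `moderate` the rest —
  a deterministic partition; ties may unbalance the thirds slightly.
  Dice 2|a∩b|/(|a|+|b|) per corresponding region; Dice of two empty
  regions is an error, not 1.
- **MSE** over the in-lung voxel series.
- **Non-defect fraction**: percent of lung voxels ≥ 50 % of the in-lung
  90th-percentile intensity.
- **Low-attenuation area**: lung voxels < −856 HU; for matched-volume
  comparison the same number of lowest-intensity voxels is segmented
  from each functional image (ties broken by voxel index).
- **Region CV**: mean of the MCD CV map per tertile, excluding
  guard-zeroed voxels.
- Registration quality: Dice between the CT lung mask and the
  15 %-of-max SPECT mask. Paired significance testing between prediction
  sets is a `scipy.stats.wilcoxon` call on the per-case columns of the
  evaluation CSV; it is not re-implemented.

## The reference desk-scale experiment

`ctvi.experiments.run_phantom_study` (also behind
`scripts/acceptance.py`): 56 phantom cases; a group-aware split of 40
pool / 8 test cases (the surplus mirrors a cohort larger than the
analysed subset and is left unused); five-fold CV of the depth-2 /
8-filter network on 32³ grids; bagged standard predictions and pooled
bagged MCD (20 samples per fold) on the test cases; evaluation against
the phantom's noise-free ventilation truth (median-normalized), with MSE
reported on the same scale. A chance baseline for the low-attenuation
overlap is computed by shuffling each predicted map's in-lung values and
re-deriving the low tertile.

Desk-scale training uses Adam at 1 × 10⁻³ with dropout 0.2, batch 2, at
most 12 epochs with patience 4 — an aggressive-but-standard schedule for
a small network on an easy surrogate task; the full-scale defaults
(5 × 10⁻⁵, dropout 0.5, 1000 epochs, patience 50) remain the documented
defaults of `TrainConfig`/`NetConfig`. Problem sizes (32³, 56 cases, 12
epochs, 20 MCD samples) are the package's desk-scale reference
conditions, chosen so the whole study runs in minutes on one CPU core.

## Numerical choices and degenerate inputs

- Engine precision float32 (switchable to float64; the gradient tests do).
- Max-pool gradient routes to the first maximum on ties.
- Seeds: every entry point takes one seed; internal streams are derived
  via `numpy.random.SeedSequence` spawning, all below 2³¹.
- Degenerate inputs fail loudly: empty masks, non-positive ventilation
  medians, all-tied tertiles, constant series for Spearman, both-empty
  Dice, p1 = p99 display ranges.

## Known limitations

- CPU-only engine; full-scale 128³ training is architecturally supported
  but impractical without an accelerator.
- Single-channel input; no 4DCT phases.
- Uncertainty is epistemic-only and uncalibrated (SD/CV of MCD samples);
  no aleatoric term.
- The phantom's ventilation is, by construction, a function of HU and
  position — real ventilation has physiology CT cannot see, so phantom
  scores are an upper bound on what this architecture could do clinically.
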