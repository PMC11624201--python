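# Methods

`ischclock` implements an imaging "tissue clock" for acute ischemic stroke
on non-contrast CT (NCCT), together with the two biological-age validation
pipelines (CT perfusion mismatch, infarct growth) and a synthetic phantom
family that provides ground truth for every stage. This note records the
models, the tunable parameters that matter, the numerical choices, and what
the phantom experiments do and do not establish.

## 1. Problem and pipeline

Treatment decisions in acute stroke hinge on lesion age: chronometric age
(onset-to-scan time, OTS) gates thrombolysis windows, and biological age
(where the tissue lies between reversible ischemia and infarction) governs
the benefit of revascularisation. The pipeline estimates OTS from the NCCT
appearance of a segmented lesion:

1. **Segmentation** — a 2.5D U-Net maps a stack of adjacent axial slices to
   a per-pixel lesion probability for the central slice; connected
   components of the p > 0.5 field are ranked by peak probability and at
   most the top three are considered (an overlap rule against the reference
   lesion stands in for the clinical expert-adjudication step).
2. **Comparator (RI/NWU)** — relative intensity,
   `RI = (mean HU_mirror − mean HU_lesion) / mean HU_mirror`, over voxels in
   the 20–80 HU window, regressed against log OTS linearly or by Gaussian
   process regression (GPR).
3. **Radiomics** — a bank of ~175 features of the lesion and of its
   normalized difference against the mirrored contralateral region: plain
   and depth-weighted intensity statistics, GLCM and NGTDM texture,
   shape/lacunarity, and the volume below the mirror's 5th HU percentile.
   Training-phase reduction: variance filter, Spearman cross-correlation
   filter (|rho| ≥ 0.9, keeping the most age-correlated member of each
   cluster), then stepwise forward selection by out-of-bag GPR R² over
   bootstrap resamples.
4. **CNN** — a K-fold (default 5) ensemble of small residual 3D networks
   regresses log OTS from cubes sampled uniformly from lesion voxels of the
   clipped/z-scored volume; test-time prediction averages over folds and
   freshly sampled cubes.
5. **Fusion (CNN-R)** — one GPR of log OTS on the CNN estimate plus the
   selected radiomic features.
6. **Evaluation** — the held-out set is repeatedly split in half;
   each half calibrates the model and is scored on the other (both
   directions pooled), metrics averaged over splits (default 20). Reported:
   R² on log-hours, RMSE in minutes, one-vs-rest F1/accuracy for the
   ≤4.5 / 4.5–9 / 9–24 / ≥24 h windows with prevalence-weighted means,
   AUROC for the 4.5 h and 24 h thresholds, error-vs-time slopes.
   "Calibration" here means refitting the output-layer GPR only; CNN
   weights and the feature list stay frozen — the cheapest defensible
   reading of test-site calibration, isolated behind one interface.

OTS is always modelled as its natural log (the base only rescales
coefficients). All models emit positive hours via the exponential
back-transform.

## 2. The NCCT phantom

`PhantomSpec` defaults (64×64×32 voxels at 1 mm) define the study
conditions used throughout the tests:

| parameter | default | meaning |
|---|---|---|
| `gm_hu`, `wm_hu` | 38, 30 HU | two-tissue background inside an ellipsoidal brain; mirror-symmetric by construction |
| `drift_amp` | 1.5 HU | smooth symmetric spatial drift |
| `uptake_rate` | 0.045 | fractional HU deficit per unit aging response |
| `texture_amp` | 2.5 HU | lesion texture amplitude at 24 h |
| `noise_sd` | 1.0 HU | acquisition noise |
| `csf_hu` | 8 HU | clamp floor for hypoattenuation |
| `profile_gamma` | age-dependent | radial deficit concentration (below) |
| `wm_lesion_load` | 0 | optional leukoaraiosis-like confound blobs |

**Aging law.** Lesion voxels lose
`delta = base_HU · uptake_rate · A(t)` with the saturating response
`A(t) = 5.2·x/(x+2)`, `x = log(1+t)`. A is monotone, approximately
log-linear early, and plateaus beyond 1–2 days — water uptake cannot exceed
tissue capacity. It is calibrated so `A(24 h) = log(25)`; the default
uptake rate then yields RI ≈ 0.145 at 24 h, the magnitude scale of the
net-water-uptake literature. No quantitative HU-vs-time curve exists to
validate against; the law is a configurable stand-in and every test that
depends on it is a parameter-recovery test, not a claim about human tissue.

**Radial profile.** Young lesions concentrate the deficit at the lesion
core (`profile_gamma` up to 0.9, decaying with log-age), old lesions are
uniformly hypodense. This gives depth-weighted statistics and the CNN a
spatial age cue that the plain mean does not carry.

**Cohort variability.** Per-subject lognormal noise: sd 0.35 on the uptake
rate — collateral supply and tissue vulnerability make relative intensity a
weak clock clinically, which is the premise of the whole method; this sd
places the RI comparator's explanatory power at the R² ≈ 0.2–0.3 scale
reported for clinical net-water-uptake clocks — plus sd 0.12 on texture
amplitude and sd 0.15 on the profile exponent.
Lesions are spheres of radius 6–11 mm placed uniformly in either
hemisphere; OTS is sampled log-uniformly on 1–48 h (a bimodal option with
peaks near 3 and 25 h mimics consecutive clinical series). Segmentation
experiments use the subacute range (6–48 h): the two-model acute/subacute
design trains each network on its own age class, and sub-3 h lesions are
near-invisible by construction of the aging law, exactly as on real NCCT.
Everything about subject *i* derives from `seed + i`, so cohort prefixes
reproduce exactly.

**Thick slices** are emulated by axial block-averaging (factor 4 in the
tests: 1 mm → 4 mm) with majority-vote masks. On these phantoms the
first-order casualty is voxel-scale texture — the radiomic clock's main
channel — so the thick-vs-thin direction is asserted on the radiomics
family. Relative intensity, being a region mean, is nearly
dilution-invariant here (dilution rescales RI, and regression absorbs a
rescaling); the strong thick-slice RI degradation seen clinically rides on
noise and partial-volume structure the phantom does not model, a limitation
noted below.

## 3. The CTP phantom and deconvolution

Tissue curves follow the indicator-dilution forward model
`C(t) = k · CBF · (AIF ⊛ R)(t − delay)` with `R(t) = exp(−t/MTT)`, a
gamma-variate arterial input (peak 200 HU), a 35 HU anatomic baseline, a
bone shell around the brain support, and
`k = ρ/(k_H·6000)` (ρ = 1.04 g/mL, haematocrit ratio k_H = 0.73) so that
`CBV = 100·k_H/ρ · AUC_tissue/AUC_AIF` in mL/100g and `MTT = 60·CBV/CBF`.
The forward integral is evaluated on a 0.05 s grid and sampled at the
native frame rate — deliberately not the discrete operator the
deconvolution inverts. The standard mismatch phantom (32³ voxels at 2 mm,
60 s at 1 Hz) embeds a penumbral ball (CBF 35, Tmax 8 s) with an ischemic
core (CBF 15, Tmax 10 s) in one hemisphere; healthy tissue is CBF 60,
MTT 4 s, delay 1 s. Delays are integer seconds so the 1 Hz grid can
represent the residue peak exactly.

The deconvolution embeds the AIF in a block-circulant matrix (zero-padded
to twice the series length, hence time-shift insensitive) with Simpson-type
elements `a_i = Δt(c_{i−1} + 4c_i + c_{i+1})/6`; a plain rectangle rule
biases peak (CBF) estimates by O(Δt/MTT). Singular values below a fraction
of the maximum are zeroed. **The truncation fraction is a bias/variance
dial and must match the noise level**: the package default (0.10) follows
common clinical practice for noisy acquisitions; the recovery experiments
use 0.001 on noise-free series (the inverse problem is then well posed) and
0.005 after denoising series with tissue SNR ≈ 20. Maps: CBF = residue
peak, Tmax = its lag, CBV from curve areas, MTT = 60·CBV/CBF (undefined at
zero flow). Core = CBF < 30% of the contralateral hemispheric mean,
penumbra = Tmax > 6 s excluding core, CPR = core/penumbra volume.

Anisotropic diffusion (Perona–Malik, conduction threshold 30 HU,
integration constant 0.1, up to 50 iterations) is the spatial denoiser;
AIF/VOF curves are always taken from the unfiltered series, because a
single-voxel artery would be smeared by any spatial filter. The AIF is
rescaled so its area matches the venous outflow curve's (partial-volume
correction).

## 4. The growth cohort

Percent lesion growth between two scans is generated from a linear model
(intercept 80; −1.2 per mL baseline volume; +0.8 per hour of inter-scan
interval; +1.5 per NIHSS point; 0 for age/sex/thrombolysis; −18 per unit
log biological age; Gaussian noise sd 25) driven by a *latent biological
age* `b`, log-uniform over 1–48 h. Chronometric onset time is a noisy
readout `cots = b·exp(ε)`, sd 0.6 — the dissociation that collateral supply
introduces — and the imaging biomarker is a low-noise readout
`b·exp(ε′)`, sd 0.1. With this (classical measurement error) structure the
chronometric regression coefficient is attenuated relative to the
biomarker's, which is the added-value contrast the growth analyses test.
Generating noise on top of `ots` instead (so that ε is independent of
`cots`) would leave the chronometric coefficient unattenuated and make the
contrast undetectable in principle; the adopted direction is the one under
which an imaging biomarker can outperform the clock, as observed clinically.
Edema correction of follow-up volumes is an identity hook by default (a
multiplicative factor or arbitrary callable can be plugged in); conclusions
on the synthetic cohort do not depend on it.

## 5. Neural networks without a deep-learning framework

Both networks run on `ischclock.nn`, a small numpy layer library
(channels-last tensors, im2col + one BLAS GEMM per convolution, manual
backpropagation, Adam). Training is bitwise deterministic for a fixed seed.
Desk-scale defaults — U-Net: 5-slice 64² stacks, 3 levels, 8 base channels,
single conv per block, 12 epochs, batch 16, lr 1e-3, lesion-pixel
cross-entropy weight 3 (class imbalance), 12 lesion + 4 background slices
per volume; CNN: 16³ cubes, 5 folds, one residual block, 16 epochs, 6
training cubes per subject, 32 prediction cubes. The full-scale
configurations (15-slice 256² four-level U-Net, 100 epochs; 48³ cubes,
3000 epochs) remain expressible in the same config objects but are not
exercised. Gradient correctness is verified against central differences in
float64 down to ~1e-9.

## 6. Numerical and statistical conventions

* Weighted quantiles: zero-weight points dropped; position of the i-th
  sorted point is `p_i = cum_{i−1}/(W − w_i)`, which reduces exactly to
  numpy's linear-interpolation quantile under uniform weights and is
  monotone. Weighted moments are population-type; kurtosis is non-excess.
* GLCM: 3D masked co-occurrence over the 13 unit directions, symmetric,
  quantized to 16/32 levels over the windowed-mask HU range. NGTDM uses the
  26-neighbourhood clipped to the mask. Both match brute-force loop
  implementations to 1e-10 on small toys; constant regions raise.
* Depth weights are `depth/max_depth` with Euclidean distance in mm; the
  depth map comes from the unwindowed lesion shape, sampled at HU-windowed
  voxels.
* Normalized difference features use `(f_lesion − f_mirror)/f_mirror` for
  scale-carrying features and the raw difference for dimensionless ones
  (skew, kurtosis, texture), avoiding near-zero denominators.
* "Volume of thresholded minimum" — the lesion volume below the mirror's
  5th HU percentile — is a stand-in definition; the quantity has no
  published formula.
* The partial F test compares nested models from their R² with an explicit
  degrees-of-freedom convention (predictor counts excluding intercept);
  comparing the 1-predictor RI model with the fused model treats the
  former as nested in the latter's span. DeLong AUC comparisons use the
  fast midrank algorithm; McNemar is continuity-corrected; correlations
  compare via Fisher Z; regression slopes via a coefficient Z test.
* GPRs are sklearn RBF + white-noise kernels on standardized inputs with
  `normalize_y`; during forward feature selection the kernel is held fixed
  (thousands of refits), with marginal-likelihood optimization reserved for
  final models. Undefined per-window metrics are reported as missing, never
  imputed.
* Segmentation component ties (equal peak probability) break toward the
  larger component, then the lower label index.

## 7. Study sizes

The canned studies in `ischclock.experiments` use: 400 phantoms (200
train / 200 test, 20 calibration splits) for the model comparison; 30
train / 10 held-out subacute phantoms for segmentation; the 32³×60-frame
mismatch phantom for perfusion recovery; n = 500 for growth. These sizes
are the package's desk-scale design points: large enough for the orderings
and recovery tolerances they assert, small enough to run on one CPU in
minutes.

## 8. What the phantoms do and do not show

The phantoms share the geometry of the inference problem (hemispheric
mirroring, HU windowing, lesion-restricted sampling, tracer kinetics) but
none of the anatomy: no skull/bone in NCCT, no gyral or ventricular
structure, spherical lesions, Gaussian noise without beam hardening or
motion, and an aging law that is *assumed*, not measured. Passing tests
therefore establish that the implementation recovers what its generators
program — parameter recovery, invariances, and the relative ordering of
model families under a controlled information structure — not that any
model reaches a particular accuracy on clinical NCCT. Orderings
(fusion > radiomics > RI-GPR > RI-linear; biomarker > chronometric time for
growth) replicate direction, never magnitude.

## 9. Known limitations

* The U-Net and CNN are far smaller than clinical-scale networks; their
  absolute scores have no clinical meaning.
* The cSVD truncation default suits clinical noise, not noise-free
  phantoms; callers must match it to their data (section 3).
* Mirroring assumes the midplane is a coordinate plane (exact on phantoms);
  for real data a rigid pre-alignment hook must be supplied — template
  normalization is out of scope.
* The expert-adjudication step is approximated by a ground-truth overlap
  rule; inter-rater behaviour is not modelled.
* DICOM ingestion and skull stripping are out of scope; inputs are
  NIfTI volumes that are already brain-extracted.
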