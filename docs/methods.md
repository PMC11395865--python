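# Methods

## The quantity being mapped

Both acquisitions are post-contrast T1-weighted volumes of the same patient.
Between the early scan (~5 min after injection, near the enhancement peak of
actively perfused tumor tissue) and the late scan (~20 min), tumor and vessel
signal declines while scar/necrosis signal keeps rising.  The map is the
voxelwise signed difference `d = early − late` after the two series have been
made comparable; `d > 0` is wash-out (rendered red), `d < 0` wash-in
(rendered green).  Everything else in the pipeline exists to make that
subtraction valid: multiplicative inhomogeneity must be removed per series
(it does not cancel in a difference of independently acquired volumes), the
global intensity scale must be equalized, and the patient moves between the
two acquisitions, so the late series must be rigidly resampled onto the
early grid.

## Geometry conventions

All volumes live in a right-handed RAS world in mm; DICOM (LPS) and NIfTI
affines are converted at the I/O boundary.  Voxel indexing is 0-based with
axis order (i, j, k) and `world = origin + orientation · (spacing ⊙ index)`.
DICOM slice order is resolved by position along the slice normal, never by
file name; slice-spacing inconsistency beyond 1% is rejected.  Rigid
transforms map fixed-space (early) world points into moving (late) space —
the resampling direction — and serialize as a plain-text 4×4 matrix.

## Preprocessing

* **Bias correction** is N4 (SimpleITK), estimated on a grid downsampled by
  the `bias.shrink` factor (default 3) with the log-field evaluated at full
  resolution.  It runs independently per series, before normalization.
  A constant input returns an identity field with a flag: N4's histogram
  machinery is undefined without intensity spread.
* **Foreground masking** thresholds with Otsu and keeps the class with the
  larger mean gradient magnitude (air is uniform; tissue is structured — the
  policy survives inverted contrast), then takes the largest 26-connected
  component and fills holes.
* **Mean normalization**: each series is scaled linearly so its foreground
  mean equals the arithmetic mean of the two original foreground means.  The
  mask is used, not the whole grid, because background air would otherwise
  dominate the means; the symmetric target avoids privileging either
  acquisition.  Both scale factors are logged in the manifest so any other
  convention is recoverable.

## Registration

Late → early, 6-DOF, multi-resolution (shrink 4/2/1, smoothing σ 2/1/0
voxels), Mattes mutual information on dense samples (no stochastic sampling,
so results are bit-reproducible), optimized by regular-step gradient descent
with parameter scales from physical shift.  Before optimization a fixed grid
of 13 coarse starts (identity ± 6° per axis, ± 6 mm per axis) is evaluated
at the coarsest level and the best one seeds the pyramid.  The metric is
restricted to the union of the two foreground masks.  If the final metric is
worse than the metric at identity, the identity transform is returned with a
failure flag rather than a degraded alignment.  Mutual information was
preferred over plain correlation as the default because it tolerates
residual bias field; both are exposed.

## Encoding

The display clip range is C = (max − min)/2 of the valid difference values
(a percentile-based range is available for robustness).  Grayscale:
`g = round_half_up(127 + 255·d/(2C))`, clipped to [0, 255].  This pins the
three anchors exactly — d = 0 → 127, d = +C → 255, d = −C → 0 — and bounds
the decode∘encode error by half a quantization step, C/255, at every voxel.
An exactly symmetric 8-bit mapping around 127 does not exist (128 levels
above, 127 below); the uniform-step/round-half-up construction is the one
that satisfies both the midpoint anchor and the half-step bound, at the cost
of `decode(255) = C·(128/127.5)` rather than exactly C (still within the
bound).  RGB uses the magnitude `m = min(|d|/C, 1)`: the active channel
(red for d > 0, green for d < 0) ramps from the neutral level to 255, the
other channels fade to 0; negating the difference therefore swaps the red
and green channels exactly.  By default the neutral level is a dimmed
grayscale rendering of the early series so the color coding sits on visible
anatomy; a flat mid-gray mode exists and is what the antisymmetry and
round-trip guarantees are stated for.

## Volumetry

Compartments are `d > +T` (wash-out) and `d < −T` (wash-in), each filtered
by 26-connected component size ≥ `min_component_mm3` (default 50 mm³) and
optionally restricted to an ROI.  The default threshold is `T = k·σ_bg`
(k = 3) with σ_bg = 1.4826·MAD of the difference over valid foreground — a
robust noise scale, since lesions occupy a small foreground fraction.  The
interactive slice-by-slice tracing this replaces is not reproducible; the
deterministic threshold is the package's own choice and is recorded in the
manifest.  The pipeline adds a threshold floor of 2% of the normalization
target mean: in a degenerate noise-free case σ_bg → 0 and a pure k·σ rule
would threshold at zero.  The pipeline's default ROI erodes the foreground
by 4 mm to keep subvoxel-registration rim artifacts at the scalp edge out of
the statistics (mimicking raters who only trace lesion neighbourhoods).
Volumes are exactly voxel count × voxel volume; the wash-out ratio is
WO/(WO+WI), flagged undefined when both compartments are empty.

Hyperperfusion volumetry thresholds a supplied relative-CBV map at 1.2 and
removes components whose *largest in-plane (axial) cross-section* is not
greater than 0.25 cm² — the criterion is two-dimensional by design, matching
how minimum enhancing areas are assessed slice-wise.  The per-lesion rCBV
summary is the maximum rCBV inside the retained mask.

## Statistics

ICC(2,k) — two-way random effects, absolute agreement, average measures — is
computed from the explicit ANOVA decomposition
`ICC = (MSR − MSE) / (MSR + (MSC − MSE)/n)`, with 95% bounds from the
F-distribution construction for the single-measure coefficient followed by
the Spearman–Brown step, and Koo–Li interpretation bands attached.  Pearson
r (with R² and two-sided p), Tukey's HSD (scipy's studentized-range
implementation), paired/two-sample t-tests per subgroup, and Likert 0–10
summaries on the 0–100% scale (sample SD by default, population SD
available; single-observation groups report SD 0 with a flag) complete the
layer.  p-values are descriptive only; nothing in the pipeline branches on
them.  Note that Tukey-adjusted p-values dominate the *matched* unadjusted
pairwise test — the one sharing the pooled ANOVA variance (Fisher LSD) —
not an arbitrary two-sample t-test with different pooling.

## Phantom

Tissue classes (normal brain, vessel, enhancing tumor, scar/necrosis, edema)
follow `intensity(t) = baseline + A·f(t)` with `f(0) = 0`:
gamma-variate-like `f = ((t/tp)·e^{1−t/tp})^s` for fast-enhancing classes
(tumor peak tp = 5 min, glioblastoma-like; vessels tp = 2 min) and
saturating-exponential `f = 1 − e^{−t/τ}` (τ = 10 min) for scar.  These
families are a modelling choice anchored only to the published time-to-peak
ranges (≈3–8 min for glioblastoma, ≈10–15 min for metastases); what the
tests rely on is the sign and magnitude of the early-vs-late difference,
which the anchors force.  Geometry is parametric (head ellipsoid; sphere,
spherical-shell "ring" and cylinder lesions) so truth volumes are analytic.
Acquisition times default to 5 and 20 min (≈15 min inter-scan delay).  The
late series is resampled through a known rigid transform; each series gets
an independent smooth multiplicative bias field (range 1 ± 0.2 by default)
and Gaussian noise at SNR 20 (Rician optional — at these SNRs the Gaussian
approximation is adequate).  The synthetic rCBV map assigns class-typical
ratios (vessel 3.5, tumor 2.5, brain 0.8, scar 0.4) plus mild noise.
Everything is seeded; equal seeds give bit-identical volumes.

What the phantom does *not* model: anatomical texture, partial-volume
blending at tissue borders (labels are hard), pharmacokinetic realism
(no Tofts-type modelling), susceptibility/motion artifacts, and
scanner-dependent sequence contrast.  Passing the phantom harnesses
therefore demonstrates the correctness of the geometry, normalization,
encoding and measurement chain under controlled kinetics — not clinical
performance on patient data.

## Evaluation problem sizes and defaults

The built-in harnesses (`rapidwashout.benchmarks`) use a 72×72×60 grid at
2 mm for the null-case, registration and determinism studies, and an
80×80×72 grid at 1.25 mm for volume recovery, where sphere-voxelization
error must stay near 1% so the volume comparison tests the pipeline rather
than the discretization.  Transform recovery draws 20 random rigid
perturbations (≤5°, ≤5 mm) at SNR 20 with the bias field disabled —
bias-robustness is exercised separately in the volume-recovery and
preprocessing tests.  Volume recovery runs spheres of 1, 2 and 8 cm³ over
10 seeds each, pre-aligned (registration stage disabled) so that
segmentation accuracy is measured independently of registration accuracy.

## Known limitations

* Registration assumes rigid intra-patient motion; severe movement artifact
  is out of scope (clinically such cases are excluded, not corrected).
* The subtraction threshold is a stand-in for the interactive tracing of the
  original workflow; absolute compartment volumes depend on it, though the
  wash-out *ratio* is less sensitive.
* Vessels are not explicitly excluded from the wash-out compartment (they
  share its kinetics); the ROI mechanism is the provided mitigation.
* The rCBV map is consumed as given; computing CBV from raw DSC time series
  is out of scope.
* Only two time points are used; no multi-point kinetic model is fitted.
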