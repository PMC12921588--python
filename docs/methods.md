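# Methods

This note documents the measurement model behind `haquant`, the numerical
choices made where the design was genuinely open, what the phantom generator
does and does not emulate, and the known limitations.

## Measurement model

A stained thin section emits fluorescence `SAI = AF + g·c + noise`, where
`AF` is tissue autofluorescence, `c` the local analyte concentration
(mg/mL) and `g` an unknown probe/optics gain (AU per mg/mL). The pre-probe
frame `PAI = AF + noise` shares the autofluorescence but not the signal, so
`FI = max(SAI − PAI, 0)` isolates the analyte term up to noise. The gain
`g` is never measured directly; it is eliminated by calibrating summed,
volume-normalized FI against bulk biochemical values from adjacent thick
sections of the same block. The model assumes:

* autofluorescence is stable between the two acquisitions (same section,
  same optics; only the stage moves, which registration corrects);
* the probe signal is proportional to local analyte concentration within
  the imaged range (optionally mildly nonlinear — hence the quadratic
  calibration option);
* serial sections a few hundred µm apart share composition, so the thick
  section's bulk value represents its flanking thin sections;
* section volume is area × thickness (flat, even sections).

### Units

Per-pixel fluorescence is in arbitrary units (AU). All volume bookkeeping
stays in px²·µm (areas in pixels, thicknesses in µm): FI concentrations are
AU per px²·µm, and a pixel's own FI concentration divides its AU by the
voxel volume `1 px² × h_C`. Keeping the section-level and pixel-level
quantities on the same per-volume scale is what makes a curve fitted on
whole sections applicable pixel by pixel: a pixel carrying the
section-average intensity maps exactly to the section's bulk value.

### The two conversion modes

**Ratio mode** normalizes a section's summed FI by the thick-section volume
`V_D = ((A_before + A_after)/2)·h_D` and converts as
`c(x) = Tk · [HA]_total · (FI(x)/h_C) / (ΣFI/V_D)`. By construction
`Σ c(x) · (1 px²·h_C) = Tk · [HA]_total · V_D` — total analyte mass is
conserved to machine precision. This is the right tool when only one
block's bulk value is available.

**Curve mode** (default) applies the fitted calibration polynomial to each
pixel's per-volume FI, then multiplies by `Tk`. Negative predictions
(possible under extrapolation) clamp to 0 with a logged count, and FI
values outside the fitted abscissa range trigger an extrapolation warning
but are still converted.

### Thickness factor

`Tk = h_ref / h_C`, with `h_ref` defaulting to the thin-section thickness
used during calibration, so `Tk = 1` whenever mapping sections of the
calibration thickness itself. Rationale: a section twice as thick collects
twice the fluorescence per pixel at equal concentration, so its per-pixel
FI must be rescaled to the calibration's reference before applying the
curve. This is the only dimensionally consistent reading and is stated here
as an explicit assumption of the implementation.

### Calibration residual

The fit's residuals (observed − predicted bulk values) are reported as a
scatter descriptor of the calibration and are never added to predictions.

## Pipeline order and numerical choices

* **Registration.** Landmarks fit a similarity by default (serial sections
  deform minimally; fewer parameters are stabler with few landmarks); an
  affine is available. The similarity uses the closed-form scaled-Procrustes
  solution; the affine is the exact geometric least squares (plain linear
  regression of fixed on moving coordinates). The PAI is warped onto the SAI
  with bilinear interpolation, fill 0, because the FI image must live in
  the frame all downstream mapping uses. Degenerate inputs (identical
  points, collinear points for an affine) are rejected.
* **Coverage masking.** Pixels the warped PAI cannot supply (outside the
  moving frame) carry no evidence; the pipeline zeroes FI there so
  uncovered border strips cannot contaminate the background estimate.
* **Subtraction and background.** Negative differences clamp to 0 —
  intensities are physical, and a negative excess over autofluorescence is
  noise; clamp counts are logged as a quality signal. Background is
  estimated *after* subtraction as the mean FI over the complement of a
  provisional Otsu mask, subtracted everywhere, and the tissue is then
  re-segmented on the corrected image. At least 1% of pixels must lie
  outside the mask for the estimate to be accepted.
* **Otsu thresholding.** Computed on bit-depth-native unit bins for integer
  images and 256 min–max bins for float images (reproducible across
  dtypes). The between-class-variance sweep runs in exact rational
  arithmetic, so near-tied splits cannot flip on float rounding and ties
  are true ties, broken toward the lowest threshold. Pixels strictly above
  the threshold are foreground. Single-valued images are rejected. No
  morphological cleanup by default (`min_object_px = 0`).
* **Model selection.** Linear and quadratic calibrations are compared by
  AIC (Gaussian likelihood, degree + 2 parameters; the residual sum of
  squares is floored at 1e-30 per point so exact fits tie rather than
  produce unbounded likelihoods). The quadratic is accepted only when it
  beats the linear by more than 4 AIC units — on the standard
  AIC-difference support scale a gap of 4+ means the simpler model has
  considerably less support. A plain lowest-AIC rule would flip to the
  spurious quadratic on noise alone in roughly one seed set in six; with
  the margin the generating degree is recovered in ≥97% of simulated
  200-replicate studies in both directions. Ties prefer the linear model.
  Residual-vs-fitted values for both models are reported so the choice can
  be inspected.
* **Regions and profiles.** "Concentric depth" partitions tissue into k
  equal-width bands of Euclidean distance-to-boundary (band 1 = surface),
  the coordinate along which outside-in gradients are expressed;
  "concentric centroid" bands distance from the mask centroid (band 1 =
  periphery). Pixel membership uses pixel centers; a pixel exactly on an
  internal edge joins the outer band. Manual label images (e.g. hand-drawn
  skin layers) are consumed as-is; no automatic layer detection. Profile
  positions are µm along the sampling direction; a line profile stops at
  the first step whose band contains no tissue pixels.
* **Reproducibility.** CV uses the sample (n−1) SD. The ICC is fixed to
  ICC(2,1) — two-way random effects, absolute agreement, single measure —
  computed from the ANOVA mean squares, with the McGraw–Wong F-based 95%
  interval (Satterthwaite degrees of freedom). Absolute agreement is the
  conservative form for repeated measurements of the same sections across
  slides, since a constant inter-slide offset counts against it; the
  consistency form ICC(3,1) is available as a diagnostic for localizing
  such offsets. Rows with missing cells are removed listwise with a
  warning; zero-total-variance tables are rejected as undefined.

## The phantom generator

`generate_phantom` builds one synthetic block: a tissue geometry (disk,
layered slab, or annulus), a concentration law over depth (constant, linear
or exponential), a smooth autofluorescence field (mean level plus a few
broad Gaussians), gain `g` linking concentration to fluorescence with
optional quadratic curvature, additive Gaussian (optionally Poisson) noise,
a similarity misalignment between the PAI and SAI acquisitions, and assay
noise on the bulk value. All fields are analytic functions of continuous
coordinates, and the misaligned SAI is produced by evaluating the scene at
the inverse-transformed grid — not by resampling a raster — so noiseless
phantoms are exact to machine precision and the stored truth map lives in
the very frame the pipeline's FI image ends up in. The emitted landmarks
map PAI to SAI coordinates exactly; the bulk value equals the mean truth
over the tissue support before assay noise. A single seeded random stream
drives all stochastic elements in a fixed order (autofluorescence shape,
per-section noise, assay noise), so datasets are bit-reproducible.

Defaults describe a realistic small acquisition: 192×192 px at 1 µm/px,
~1 mg/mL of analyte (soft-tissue HA scale), autofluorescence around 200 AU,
gain 1200 AU per mg/mL (signal ≈ 5× autofluorescence), read noise of a few
AU, a (3, 2) px / 0.4° stage shift between the paired frames, 5/400 µm
thin/thick sections, and a 5% CV on the bulk assay.

What the phantom does **not** emulate: optics (PSF, vignetting), mosaic
tile seams and shading residue, probe-affinity variation with analyte size,
section-to-section deformation (both flanking sections share one geometry),
and intensity quantization. Passing phantom tests therefore demonstrates
the correctness of the computational pipeline — registration, subtraction,
segmentation, calibration algebra, statistics — not robustness to every
artifact of real acquisitions.

## Validation problem sizes

The shipped validation suite uses 96–128 px square phantoms, 8-level
calibration series, 200-replicate model-selection studies, and 50–100
random tables for the statistical oracles; these sizes keep the full suite
fast while leaving every estimate's sampling error far inside the asserted
tolerances. The noisy end-to-end scenario sets the Gaussian σ to 5% of the
series' mean fluorescence signal (one shared acquisition noise level across
levels) and judges the reconstruction by relative RMSE pooled over all
tissue pixels of the series, normalized by the mean truth.

## Known limitations

* The calibration assumes the thick section is compositionally represented
  by its flanking thin sections; abrupt morphology changes violate the
  mean-flanking-area volume estimate.
* Per-pixel uncertainty is not propagated; the residual SD of the
  calibration is reported globally only.
* Mosaic stitching, proprietary microscope formats and pyramidal
  whole-slide formats are out of scope; inputs are plain grayscale TIFFs.
* Automatic (intensity-based) registration and nonrigid warping are not
  provided; alignment quality is bounded by the supplied landmarks.
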