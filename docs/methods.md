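# Methods

## Measurement model

The AAPM performance phantom's slice-thickness module images three thin
aluminum plates inclined through the slice plane. With the plates'
45°-equivalent geometry, the in-plane width of a bar equals the slice
thickness, so the slice sensitivity profile is read off as the 1-D pixel
profile across the bar and its FWHM — in pixels, converted to mm with the
DICOM PixelSpacing — is the measured slice thickness. The package assumes
this equivalence (a `ramp_factor` scales it for other inclinations) and
applies no further deconvolution: the reported value is the profile FWHM,
which for thin slices therefore includes in-plane blurring of the bar
edges.

## Pipeline stages and numerical choices

**Thresholding.** `"auto"` applies Otsu's method to HU values above
−200 HU (air excluded) clipped at +1200 HU. Air must be excluded: with
roughly half the field of view at −1000 HU, Otsu otherwise separates
air from water and the entire water disc becomes foreground. A guard
rejects thresholds whose foreground/background class means are separated
by less than 100 HU, so pure-noise images fail with "no stair objects
found" instead of yielding speckle. A fixed HU threshold (e.g. +200) can
be supplied instead; aluminum/water contrast is large enough that any
reasonable value works.

**Bar filters.** Components must have an area in [20, 2000] px (scaled by
(0.508 mm / spacing)²) and major/minor axis ratio ≥ 3. This keeps the
thin, long bars and rejects the water disc, speckle, and blobs. The
foundation strip is rendered at low contrast (below threshold), mirroring
its faint appearance; the 30×30 re-crop is what guarantees it cannot
touch the profile. Components are 8-connected: thin rotated bars fragment
under 4-connectivity.

**Middle-bar selection.** Centroids of the detected bars are projected
onto their own principal axis and ranked; the median rank is the middle
bar. For an upright phantom this is simply column order, but it is
invariant to any in-plane rotation.

**Orientation.** A straight-line Hough accumulator is built from the
binarized 65×65 crop over θ ∈ [−90°, 90°) in 0.5° steps, θ measured so a
bar parallel to the column axis scores 0°. Votes are split linearly
between adjacent ρ bins (bin width 0.5 px) and the accumulator is
smoothed along ρ with a 1 px Gaussian before being collapsed to the 1-D
response Σ_ρ Â(ρ,θ)² (normalized to max 1). The vote *concentration* is
what peaks at the bar angle — the plain sum over ρ is the same for every
θ (each pixel votes once per θ), and integer ρ binning without smoothing
biases the argmax by up to ~1° through pixel-lattice aliasing. With these
choices the estimator is accurate to ≤ 0.3° for bar widths from 2 to
10 px, including off-grid angles, which is far below anything that
matters for the FWHM (a residual angle ε inflates the width by a factor
1/cos ε ≈ 1 + ε²/2, under 0.01% at 1°). Ties in the response are broken
toward the smallest |θ|. The 0.5° grid is kept as the estimate's
resolution; no sub-grid refinement is attempted.

**Rotation.** The crop is rotated upright with bilinear interpolation;
the constant fill is the median HU of the crop's border ring, preserving
the water baseline. A zero estimate skips resampling entirely.

**Profile.** After rotation the bar centroid is re-found and a 30×30 px
window (≈ 15 mm at default spacing) is cut: small enough to exclude the
foundation (≥ 28 px from the bar center) and the neighbouring bars
(≥ 18 px edge distance at the 12 mm pitch), large enough to hold the bar
cross-section plus water on both sides. Pixel values are averaged along
the bar's long axis; the direction is auto-detected as the one whose mean
profile has the larger excursion, so the convention cannot flip with the
bar orientation. Averaging ~30 samples suppresses the noise on each
profile point by √30 (σ 10 HU → ≈ 1.8 HU).

**Half level and FWHM.** The baseline is the mean of the lowest quartile
of profile samples (surrounding water); the half level is
baseline + (peak − baseline)/2, which makes the measurement invariant to
a global HU offset. `half_mode="raw"` gives the literal peak/2 — with
water ≈ 0 HU the two nearly coincide. Crossings are found scanning
outward from the peak and interpolated linearly between the bracketing
samples; with multiple crossings (residual structure in the window) the
pair nearest the peak wins. A peak at the window edge raises an error
advising a larger window rather than returning a truncated width.

**Aggregation and comparison.** Series results are mean ± sample SD
(n−1) over frames, printed to one decimal; full precision is kept
internally and display rounding never feeds back. Percent difference
from a manual value is 100·|manual − automated|/automated, computed in
decimal arithmetic and rounded half-up to one decimal — the convention
and denominator choice are those of standard QC comparison tables (a
manual-value denominator yields visibly different numbers, e.g. 10.5%
instead of 11.8% for 5.1 vs 5.7 mm).

## Synthetic phantom

The generator emulates the acquisition this method is used with: 512×512
matrix over a 260 mm FOV (0.5078 mm/px), water cylinder (radius 100 mm,
0 HU) in air (−1000 HU), three bars of +900 HU contrast, 25.4 mm long, at
12 mm pitch, on a +120 HU foundation strip (3 mm thick) joined to the bar
ends; in-plane bar width = nominal thickness (45° ramp equivalence). The
assembly can be rotated and offset (the study design this mirrors used
±2 and ±4 cm); the image is convolved with a Gaussian PSF (default σ
0.6 px) and i.i.d. Gaussian noise is added (default σ 10 HU). The same
seed always reproduces the identical frame.

Bars are rasterized by exact pixel-box coverage (area-weighted
anti-aliasing). This matters: hard rasterization quantizes the measured
FWHM by ±0.5 px (≈ 0.25 mm), swamping the method's real error. The box
coverage acts as the physical integration of a detector pixel, and the
ground truth accounts for it: `ground_truth_fwhm` is the FWHM of
rect(width) ⊗ box(spacing) ⊗ Gaussian(psf·spacing), evaluated by dense
numeric convolution (grid step ≤ width/2000). With zero PSF it equals the
nominal width exactly (for widths ≥ one pixel). At the default PSF the
truth is essentially the nominal for 2–5 mm and ≈ 1.12 mm for a 1 mm
nominal — the expected partial-volume broadening of a sub-PSF bar.

Reconstruction-filter variation is emulated by the presets smooth /
standard / sharp = PSF σ {1.0, 0.6, 0.35} px with noise σ {6, 10, 18} HU:
a soft kernel blurs more and denoises, a sharp kernel the opposite. The
generator does *not* simulate filtered backprojection, streaks, helical
pitch or non-Gaussian noise texture; passing the closed-loop tests shows
the algorithm recovers known bar widths under realistic blur and noise,
not that any particular scanner meets tolerance.

## Validation and problem sizes

The closed-loop suite generates phantoms at nominal 1–5 mm (five seeds
each, default parameters) and requires the measured mean per nominal to
sit within 1.0 mm of the nominal and within max(0.1 mm, 2%) of the
analytic ground truth; position sweeps (0, ±20, ±40 mm) must agree within
0.3 mm and the filter presets within 0.1 mm. The FWHM routine is checked
against a 1000×-upsampled counting oracle on random unimodal profiles
(0.02 px) and the Gaussian closed form 2√(2 ln 2)σ; the Hough stage must
recover angles in ±10° within the 0.5° grid step with an equally small
residual after correction. Five seeds per condition keep the whole suite
under a minute of compute while the per-frame noise contribution to the
mean (≲ 0.01 mm) is negligible against the tolerances; observed margins
are typically an order of magnitude inside the bands.

`scripts/acceptance.py` re-runs the 1–5 mm × 5-seed loop (25 frames) and
reports the maximum |measured − nominal| in mm.

## Known limitations

- Exactly three stair bars are assumed; other layouts need new geometry
  constants and a different middle-object rule.
- The angle estimate is grid-limited to 0.5°; irrelevant for FWHM but not
  suitable as a precision goniometer.
- Anisotropic pixel spacing is handled (the spacing along the profile
  axis is used, with a warning) but untested against real anisotropic
  reconstructions.
- Slice thicknesses below one pixel spacing are outside the validated
  range (the profile becomes PSF-dominated).
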