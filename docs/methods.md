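# Methods

This note records the models behind each measurement, the defaults and why,
what the synthetic phantoms do and do not emulate, and the numerical choices
made where the method family leaves freedom.

## Imaging model of the synthetic phantoms

The generator treats the scanner as a linear, shift-invariant in-plane system
with an isotropic Gaussian PSF of width `psf_sigma` (mm).  Objects (wire
cross-sections, rods, HU inserts, low-contrast discs) are rendered as discs on
a grid oversampled 8× (4× for the large modules), convolved with the PSF
there, and area-averaged down to the pixel grid; the downsampling *is* the
pixel-aperture integration.  Disc boundaries use linear edge coverage over one
subpixel rather than hard thresholding, keeping flux and centroids accurate to
O(h²).  The resulting in-plane MTF is

    MTF(f) = exp(-2 π² σ² f²) · A_obj(f) · A_pix(f),

where `A_obj` is the object's own aperture (for a wire of diameter d the jinc
`|2J₁(πfd)/(πfd)|`) and `A_pix` the pixel aperture.  Closed-form recovery
targets follow, e.g. f50 = √(ln 2 / 2π²σ²).  Fixtures keep the pixel pitch
small against 1/f50 so that `A_pix` contributes ≲2% at the 50% point; the
tolerance of the recovery tests (3%) covers it.

Noise is filtered white Gaussian: per slice an i.i.d. standard-normal field of
SD `noise_sigma_white` is circularly convolved with a small kernel `h`, so

    NPS(fx, fy) = noise_sigma_white² · Δx Δy · |H(fx, fy)|²,
    pixel variance = noise_sigma_white² · Σ h²,

with `H` the kernel's discrete-space Fourier transform.  The circular
convolution makes the analytic spectrum exact at DFT frequencies.  A
difference-of-Gaussians kernel (`dog_kernel`) mimics the band-shaped texture
of filtered-backprojection/hybrid-IR CT noise.  Slices are generated
independently; there is no longitudinal noise correlation, no dose/attenuation
dependence across the field, no structured artifacts (rings, streaks, beam
hardening), and no non-linear reconstruction behaviour.  A green recovery test
therefore establishes that the *measurement chain* is correct on a stationary
linear world — not that any particular scanner meets a number.

Defaults state the emulated world: wire diameter 0.05 mm; default PSF
σ = 0.1874 mm (f50 = 1.00 lp/mm, a normal-resolution abdominal kernel);
insert nominal HUs air −1000, LDPE −95, water 0, acrylic 120, Teflon 990;
low-contrast layout of three contrast levels 1.0/0.5/0.3% (10/5/3 HU) × nine
diameters 15–2 mm on a 80-mm ring.  The wire amplitude (20 000 HU) reflects
tungsten's extreme attenuation and gives a blurred wire peak of ~180 HU over
background at the default PSF, comfortably above the 5-SD detection margin at
clinically plausible noise.  The Teflon nominal (990 HU) sits *above* the
expected measured range (850–970 HU): real scans read Teflon lower because of
spectral (beam-hardening) effects the generator deliberately omits, so a
default-world accuracy check honestly flags Teflon while all spectrally
benign materials pass.

## Wire (point-method) MTF

Pipeline: centroid localisation → square crop (default 32 px) → background
subtraction from a surrounding annulus (default radii 8–12 px) → zero-padding
(default 256) → |DFT₂| → radial average in bins of one padded-DFT step →
normalisation at f = 0 → optional finite-wire correction.  Choices:

* **Annulus**: the background ring must sit at ≥4 PSF sigma from the wire or
  it clips the PSF tails and corrupts the DC normalisation; the defaults suit
  σ ≈ 2 px and are exposed (`annulus_inner/outer`) because fine-pitch
  reconstructions need wider rings (the tests use 24–30 px at 0.1 mm pitch).
* **Wire correction** default on: ~5% at 4 lp/mm for a 50-µm wire, material
  at super-high-resolution frequencies.  Correction is applied before the
  final normalisation; since the aperture MTF is 1 at f = 0 the order is
  immaterial and the correction is exactly invertible (tested to 1e-12).
* **Radial average** uses bin-centre assignment with empty bins dropped — no
  interpolation artifacts, deterministic.
* Detection demands a peak ≥5 robust SDs (MAD-based) above the median.

## Circular-edge MTF

Centre estimation: thresholded centroid, then an iterated circle fit to the
half-maximum contour sampled along 360 rays (linear interpolation along each
ray); fits with RMS residual >0.5 px are rejected.  All pixels within
`window_mm/2 + 1 mm` of the fitted radius are binned by their exact radial
distance into bins of `pitch/oversample` (default 8×), giving the oversampled
ESF; the LSF is its central difference; a Hann window of width `window_mm`
centred on the LSF peak precedes the DFT.

The window trades noise robustness against spectral smoothing: the windowed
spectrum is the true MTF convolved with the window transform, which *raises*
apparent frequencies when the window is narrow relative to the LSF.  With the
default 8 mm window the bias at the 50% point is +2.3% at σ = 0.4 mm and
negligible below σ ≈ 0.25 mm; tests use 12 mm (≈30 σ) where large blurs are
measured.  The circular geometry itself is benign for radius ≫ σ (a 6-mm rod
against σ ≤ 0.4 mm contributes <0.1%).

Percent-frequency lookup takes the *first* downward crossing with linear
interpolation — noisy curves may be non-monotone, and the first crossing is
the conservative, deterministic choice.

## Slice sensitivity profile

Per-slice mean over a 23-voxel-diameter ROI inside the foil-disc footprint vs
slice position; background is the mean of the outer 10% of slices at each end
(the stack must span ≥4 FWHM so the tails are signal-free); peak normalised.
FWHM walks outward from the peak to the first half-maximum crossing on each
side (robust against noisy tail re-crossings), interpolating linearly.
Recovery on noisy stacks (ROI-mean noise 2% of peak) is well within one slice
increment; noiseless recovery carries a ≈ +1% bias from tail truncation in the
background estimate — far below the increment and left uncorrected for
simplicity.  Foil-thickness deconvolution is out of scope (a 25-µm foil is
≤6% of the narrowest slice width of interest).

## Noise power spectrum and noise SD

Averaged windowless periodograms over a grid of square ROIs (default 128 px,
half-overlap): `NPS = (ΔxΔy)/(NxNy)·⟨|DFT₂(ROI − trend)|²⟩`.

* **Unsubtracted** mode removes a per-ROI 2-D polynomial of order 2 — enough
  to absorb the bowl/cupping trends of water phantoms (a planar ramp of
  0.1 HU/px changes the spectrum by <2% in tests).
* **Subtracted** mode differences same-position slices of two repeated
  volumes and halves the accumulated power (variance of a difference of
  i.i.d. fields); on stationary synthetic noise both variants agree within
  estimator noise, which is itself a test.
* `slice_gap` (default 15) enforces the slice separation used to decorrelate
  longitudinal noise when harvesting several slices per scan; synthetic
  slices are i.i.d. by construction, so fixtures set it to 0 and say so.
* The radial average bins |f| into rings one DFT step wide, excluding the
  zero-frequency sample; peak frequency is the argmax bin with ties going to
  the lowest frequency.
* Noise SD is the n−1 sample SD of a detrended ROI.  For ROIs with fewer
  than 10 pixels per polynomial coefficient the trend fit would eat the
  noise itself, so only the mean is removed there.

Parseval (∑NPS·Δf² = detrended variance) holds by construction and is
asserted within 5% on synthetic noise.

## Uniformity and CT-number accuracy

Five 32-mm ROIs on the central slice: centre plus 12/3/6/9 o'clock, the
peripheral centres at `phantom_radius − edge_margin − roi_radius` with
`edge_margin` 10 mm (the QA protocols leave the margin to the operator; it is
a parameter).  Pass ⇔ every |peripheral − centre| ≤ 5 HU.  Material ranges
are closed intervals, bounds inclusive; the insert measurement averages a
1-cm ROI across a configurable z-slab (emulating a thick-slice
reconstruction) and refuses layouts whose ROI would touch a neighbouring
insert.  Insert positions are supplied, never auto-detected.

## Low-contrast visibility and dose matching

A human reader's count is replaced by a deterministic rule: per object,
CNR = (mean of a disc ROI at 0.8× object diameter − annulus mean) / annulus
SD, with the annulus at 1.5–2.1× the object radius; visible ⇔
CNR·√(area in pixels) ≥ threshold (default 4, the classical Rose constant).
The score is the total count across contrast levels.  No claim is made that
this reproduces any particular human reading — only that it is reproducible
and monotone in dose, which the tests verify on modules whose noise scales as
1/√dose.  Dose matching takes the smallest dose whose score reaches the
reference and refines it by linear interpolation on the score axis; results
carry an explicit not-reached flag when the series never gets there.
Sub-slice (short-z) objects are handled by restricting the reader's slab
thickness relative to the object extent.

## Report and determinism

`run_report` executes any subset of metrics from a config mapping and writes
`report.json` (pydantic model; shipped JSON Schema) plus per-curve CSVs.  No
timestamps enter the outputs; all randomness derives from the single `seed`
via fixed per-metric offsets, so identical configs reproduce outputs
byte-identically — asserted by test.  The `ctiq` CLI exposes each metric as a
subcommand over the same functions.

## Known limitations

* No projection/reconstruction physics: images are generated in image space;
  non-linear reconstruction effects (the reason the edge method exists for
  iterative reconstructions) are not emulated, only tolerated by the API.
* Gaussian PSF only; real CT kernels have structured MTFs with negative
  lobes that the recovery tests do not exercise.
* The low-contrast reader is a model observer of the simplest kind (CNR +
  Rose); channelized or anthropomorphic observers are out of scope.
* DICOM support is read-only and requires the optional `pydicom`; spacing
  metadata must be complete (no gantry tilt, no non-axial reformats).
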