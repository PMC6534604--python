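# Methods

`acuitysim` predicts the monocular visual acuity of an individual eye from
two measured inputs — the ocular wavefront (a tenth-order OSA/ANSI Zernike
expansion over the aberrometer pupil, in units of the 555 nm reference
wavelength) and the pupil diameter during the acuity test — by simulating
the entire visual chain: polychromatic image formation, neural transfer,
cone noise, template-matching recognition, correlation-based scoring and
psychometric thresholding.  This note records the model, its parameters,
and the design decisions taken where the construction was genuinely open.

## Optical stage

**Schematic eye.** The Gullstrand Exact (No. I) unaccommodated eye (six
spherical surfaces, lens split into cortex and high-index core; radii
7.70/6.80/10.00/7.911/−5.76/−6.00 mm, thicknesses 0.50/3.10/0.546/2.419/
0.635 mm, anatomical vitreous 16.80 mm) supplies the chromatic skeleton of
the model.  Its fixed indices are replaced by Sellmeier-1 fits to the
Atchison–Smith ocular dispersion data; at 555 nm these reproduce the
classical indices (cornea 1.376, aqueous/vitreous 1.336, cortex 1.386,
core 1.406) to better than 1e-3, and the paraxial effective focal length
is 17.04 mm, matching the textbook 17.1 mm average eye.  The eye is used
*paraxially only*: because letter size, pupil and wavefront are all
expressed in object space, the personal focal length cannot influence
image quality, and all individual aberrations enter through the measured
wavefront.  The retina is placed at the 555 nm paraxial focus; the
object-space vergence of the retina conjugate at each wavelength then
defines the longitudinal chromatic defocus ΔD(λ) (−1.65 D at 400 nm to
+0.59 D at 700 nm, a 2.24 D span).

**Polychromatic PSF.** 24 wavelengths equally spaced over 400–700 nm are
weighted by the CIE 1924 photopic luminosity function, using the standard
Gaussian approximation V(λ) ≈ 1.019·exp(−285.4(λ_µm − 0.559)²),
renormalized to unit sum.  Per wavelength the generalized pupil function
is O = T·exp(−i2π·OPD·λ₀/λ) with OPD in λ₀ units (the phase-advance sign
convention makes the PSF the squared modulus of the *forward* FFT of O).
ΔD(λ) is injected as an orthonormal Zernike defocus coefficient
c₂⁰ = ΔD·(d/2)²/(4√3) (length units, then divided by λ₀); higher-order
aberrations are treated as wavelength-independent in length units.  The
pupil plane is sampled with pitch λ/(N·Δx) so that every monochromatic
PSF lands on the common angular grid (N = 1024, Δx = 5.724 arcsec,
Δf = 1/(N·Δx) = 0.6142 cycles/degree) without interpolation; FFT
wrap-around is accepted since the 1.63° field dwarfs the letters.

**Stiles–Crawford apodization.** Cone directionality is modeled as a
Gaussian amplitude transmission T(r) = exp(−(r/2.9 mm)²): T = 1/e at the
published 2.9 mm radius.  This is the literal reading of the source
description; it is stronger than the classical directionality parameter
ρ ≈ 0.05 mm⁻² (which would put the *amplitude* 1/e radius near 4.1 mm),
and it makes the effective aperture saturate above roughly 5 mm.  The
softer physiological reading was evaluated and rejected: it degrades the
calibration-group reproduction markedly (the high-blur myopic subject
most of all) while the literal convention reproduces it.

**Best focus.** The retina-position optimization is emulated by a scan of
an added defocus coefficient (±0.5 D, 15 samples, parabolic refinement)
maximizing the mean radially-averaged polychromatic MTF at 14.85 and
22.28 cycles/degree (50 and 75 cycles/mm on the 17.1 mm retina).  The
scan runs on a reduced 768-sample grid with the same 0.6142 cpd frequency
step.  For myopic records (stored negative Z₂⁰) the scan is performed on
the spectacle-corrected wavefront (Z₂⁰ removed) and only the resulting
correction-independent offset is kept, after which the stored Z₂⁰ is
restored — uncorrected acuity is what is simulated.

**Pupil rescaling.** The Zernike expansion is a fixed surface normalized
to the measurement radius d_w/2; when the test pupil differs, the same
polynomials are evaluated over the new disc (native extrapolation beyond
ρ = 1, with a warning — relevant to one calibration subject whose test
pupil exceeds the wavefront pupil).

## Neural stage

**Neural transfer function.** NTF = CSF/MOTF, built once from population
models at a fixed reference pupil and normalized to NTF(0) = 1 (the unit
background of filtered images is preserved).  The CSF default is the
difference-of-hyperbolic-secants standard-observer form
S(f) = sech((f/f₀)^p) − a·sech(f/f₁) with f₀ = 4.173 cpd, f₁ = 1.362 cpd,
a = 0.8493, p = 0.7786 (absolute gain cancels in the normalization).  The
MOTF default is the diffraction-limited MTF of a 4 mm photopic reference
pupil times an exponential-plus-constant aberration factor,
(1−C)·exp(−f/u₁) + C with u₁(d) = 21.95 − 5.512d + 0.3922d² cpd.  The
high-frequency weight C is not recoverable from the cited source at the
printed precision; it is anchored at C = 0.10 so that the resulting
neural filter, applied to a nearly aberration-free eye, produces an
acuity in the best-normal range (≈ −0.3 logMAR).  Both models are
pluggable and all parameters are exposed.  The resulting NTF is an
edge-enhancement filter (peak gain ≈ 8 near 5 cpd) and is masked to zero
beyond the MOTF diffraction cutoff.  The filter is passed through a
DFT → inverse-FFT round trip so that the forward/backward transform pair
matches the one used for the OTF; with a single FFT implementation this
is the identity, and it is retained as a numerical-convention guard.

**Cone-lattice noise.** Neural noise is additive Gaussian white noise per
cone: one i.i.d. zero-mean deviate of standard deviation σ per cell of a
hexagonal lattice at 120 cycles/degree (nearest-neighbor pitch 1/120°,
one lattice axis horizontal, phase anchored at the image center), added
uniformly to every pixel of the cell.  σ is relative to the unit
background, i.e. a reciprocal signal-to-noise ratio.  Noise is redrawn
independently for every presented letter; templates are noiseless.

## Recognition and scoring

**Templates.** Per letter size, all 26 letters are rendered, filtered by
OTF·NTF, and cropped to a square window centered on the centroid of
|1 − PI| with half-side twice its RMS radius (clipped to a side of 199
pixels; within one size all letters share the common, largest window so
the correlation can be batched).

**Correlation.** Similarity is the peak over all integer lags of the
normalized cross-correlation surface (full correlation, linear size equal
to the sum of the input sizes minus one).  At each lag the value is
Pearson's correlation between the template and the template-sized window
of the zero-padded stimulus, both as deviations from the unit background
— the classical template-normalized NCC.  Normalizing instead over the
bare overlap region at every lag is degenerate under per-cone noise (any
two-pixel overlap of noisy data reaches |ρ| = 1), which is why the
template-window convention is used.  Lags whose window carries
(numerically) no variance are excluded.  The peak makes recognition
translation-invariant.  The stimulus crop window is derived from the
noiseless expected image, not the noisy one, to avoid noise-driven
centroid jitter.

**Guess sets and OC scoring.** All templates within the discrimination
range [ρ_max − δρ, ρ_max] form the guess set (δρ = 0 reduces to the pure
maximum-correlation decision).  Each guess is scored by the Optotype
Correlation matrix — Pearson peaks between the undistorted letter images
(at a 0.3 logMAR reference size; normalized correlation makes this choice
weakly influential), linearly transformed so the diagonal is exactly 1
and the grand mean over ordered letter pairs (identical pairs included,
matching uniform independent draws; a distinct-pairs variant is a flag)
is exactly 1/26.  The per-presentation score is the mean OC over the
guess set; the Rate of Recognition RR at one size is the mean score over
the 26 letters.

**Psychometric function and acuity.** RR(s) over the 14 letter sizes
(0.3 to −0.35 logMAR in 0.05 steps) is fitted with the transformed
logistic L(s) = 1/26 + (25/26)/(1 + exp(−4k(s − s_mp))), i.e. increasing
with letter size; the printed form of this curve carries a +4k exponent,
which with positive k would make recognition degrade with larger letters,
so the increasing orientation is implemented.  Initialization: s_mp at
the tested size with RR nearest the threshold, k = 4 /logMAR, k bounded
to (0.1, 50).  Acuity is the closed-form inversion V = L⁻¹(RR₀) at the
calibrated threshold RR₀ = 0.68.

## Optotypes

Sloan letters on the 5×5 design grid (letter height = 5 stroke widths;
letter size s = log₁₀ of the stroke width in arcmin).  The ten canonical
letters follow the published construction (annuli, arcs and unit-width
strokes); the remaining sixteen of the extended set use the same design
rules with built-in vector outlines — their exact published outlines are
not reprinted anywhere accessible, which is one reason recognition-level
checks carry tolerances.  Glyphs are rasterized with 4×4 supersampling
and a 0.5 coverage threshold into binary images (background 1, strokes
0), centered on the grid.  Ink area follows the expected 10^(2s) scaling
with a regression slope within 1.5% over the trial sizes.

## Trials, calibration, sensitivity

A virtual trial presents all 26 letters once per size with fresh noise
(presentation order: sizes large to small, letters A–Z), deterministic
given a seed.  The fitting error against a reference RR curve is
ΔRR = √Σᵢ(RR_s(sᵢ) − RR_m(sᵢ))² over the 14 sizes — the plain sum, not
divided by 14; a `mean` flag provides the averaged variant for
comparisons.  Calibration grid-searches σ ∈ [0, 0.15] (step 0.025) and
δρ ∈ [0, 0.005] (step 0.0005) against reference curves, averaging ΔRR
over seeds; pooled mode minimizes the subject-average error (the pooled
objective equals the mean of the individual objectives at every cell).
The pooled optimum of the original calibration, σ = 0.10 and δρ = 0.0025,
is the package's fixed "average neural model".

Ablation variants: M0 full model; M1 δρ = 0; M2 monochromatic 555 nm PSF;
M3 additionally a fixed 6 mm pupil.

The inverse-sensitivity analysis perturbs one construction parameter
(pupil diameter, artificial refractive error added after best focus,
σ, or δρ) symmetrically around baseline, averages |ΔV| over subjects,
seeds and signs, and interpolates the perturbation at which |ΔV| crosses
0.05 logMAR on the piecewise-linear curve anchored at the origin.

## Numerical choices

* Heavy inner loops (pupil assembly, image filtering, batched NCC) run in
  single precision; the resulting correlation error (~1e-5) is far below
  the smallest discrimination range of interest (5e-4), and all
  statistics and fits run in double precision.  The reference
  `pearson_peak` path is float64 and matches a brute-force lag-loop
  oracle to 1e-10.
* The best-focus scan tie-breaks toward the first (most negative) of
  exactly equal merits on a symmetric grid; merit ties are measure-zero.
* Degenerate inputs raise typed errors: Sellmeier poles and out-of-band
  wavelengths, zero-power eyes, non-positive pupils, constant correlation
  inputs, empty guess sets, empty calibration grids.
* All randomness flows from integer seeds through `numpy` `SeedSequence`
  streams; per-cell noise deviates are drawn in sorted-cell order so a
  trial is bit-reproducible.

## Synthetic subjects

`generate_synthetic_subject` draws zero-mean Gaussian coefficients per
mode with a per-order RMS budget (orders 2–6: 0.35, 0.30, 0.12, 0.04,
0.015 λ₀ at severity 1, split evenly across the modes of each order,
defocus excluded) and pupils d_w ∈ [4, 6.5] mm, d_m ≤ d_w.  At severity 1
the higher-order RMS distribution overlaps the calibration group's range
(0.03–0.51 λ₀).  The generator emulates the *magnitude structure* of
measured wavefronts, not their mode-to-mode correlations; it exists so
that calibration and recognition mechanics can be exercised on eyes that
are not part of the calibration group.

## Known limitations

* The calibration subjects' published coefficients stop at fourth order;
  the original measurements used 64 terms.  The missing high-order tail
  (which grows steeply with pupil dilation) makes the simulated acuity of
  dilated pupils slightly optimistic, and correspondingly biases the
  pupil-sensitivity estimate upward.
* The exact extended-Sloan outlines and the exact CSF/mean-OTF parameter
  sets behind the neural filter are cited but not printed in the source
  material; the defaults here are standard published forms with one
  anchored constant (see above).  Absolute acuity levels shift by a few
  hundredths of logMAR under reasonable alternatives.
* Light scattering, transverse chromatic aberration, cone-mosaic low-pass
  sampling and accommodation are intentionally outside the model.
* The heavily myopic, strongly astigmatic calibration subject is
  reproduced ~0.1 logMAR worse than the original model — heavily blurred
  templates make the δρ discrimination range the binding mechanism and
  its effect depends sensitively on glyph microstructure.
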