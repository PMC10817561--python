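# Methods

## Model

Monochromatic light of wavelength λ crossing a stack of homogeneous
tissue layers attenuates exponentially: `T_λ = exp(-Σ_k μ_kλ d_k)`,
where `μ_kλ` (cm⁻¹) is tissue k's attenuation coefficient — absorption
plus scattering loss — and `d_k` (cm) its path length. The model
assumes layers attenuate independently (no inter-layer scattering or
point-spread blur), illumination is monochromatic with a planar-enough
wavefront, and the camera responds linearly below saturation.

Per pixel, `ln T⁻¹(x, y)` at k wavelengths equals the k×k attenuation
matrix times the k tissue thicknesses. Decomposition is therefore a
single matrix factorization (LU) reused at every valid pixel — identical
mathematics to applying the explicit inverse, with better numerics.
Rectangular (over-determined) systems are out of the default path; the
square-exact solve is the method.

## Units and conventions

Thickness is always cm, coefficients cm⁻¹; matrix rows are indexed by
wavelength and columns by tissue, both carried as explicit labels and
validated on every pairing — order mismatches raise rather than reorder
silently, because the row/column semantics are the method's most
error-prone convention. Image arrays are row-major, origin top-left,
x = column, y = row, 0-based.

## Validity masking and clamping

A pixel is usable only if, at every wavelength, the reference is above
the dark floor (default 1% of the saturation level, configurable) and
neither frame is saturated — saturated counts carry no attenuation
information. Valid ratios above 1 (noise can make the object brighter
than the reference) clamp to 1; ratios at or below ε = 1e-6 clamp to ε
so `ln(1/T)` stays finite and nonnegative. Both clamp events are
counted and reported so the amount of correction is auditable. Invalid
pixels propagate as NaN through every stage and render at a sentinel
gray. How dark current should be handled before the ratio is left open
deliberately: the package exposes the dark floor rather than guessing a
background subtraction.

## Coefficient characterization

For a homogeneous slab of known thickness d the per-pixel plane
`-ln T(x, y)/d` should be flat; its masked mean is the coefficient and
its standard deviation the reported ± spread (the choice of spread
statistic was open; the per-pixel standard deviation is the simplest
auditable one). The default mask is the central 50% × 50% crop, where
the Gaussian beam is bright; edges sit near the dark floor.

Thin slabs read high because the specimen case reflects light. The
package models the apparent coefficient as `μ(d) = β₀ + β₁ d⁻³` and
reports the asymptote β₀. The model is linear in (β₀, β₁), so the fit
is exact linear least squares on the regressor d⁻³ — no optimizer, no
starting values; standard errors come from the OLS covariance. The
exponent 3 is an empirical choice and is exposed as a parameter.
Noise-free data from the model are recovered to machine precision, and
the tests check β₀ is unbiased under zero-mean noise and converges to
the generating asymptote as the thickness window moves outward even
when the true bias decays with a different power.

## Matrix diagnostics

The inversion is only as good as the matrix's conditioning. Diagnostics
report the determinant (cm⁻³ for k=3), the 2-norm condition number, an
invertibility verdict (|det| above a 1e-10 tolerance), and a warning
above a condition number of 1e3; both thresholds are configurable since
no principled universal cutoff exists. The built-in chicken reference
matrix has det ≈ 0.087 cm⁻³ and condition number ≈ 365: invertible, but
noise in `ln T⁻¹` is amplified by two orders of magnitude, which is why
the accuracy studies below degrade quickly with speckle. A property
test verifies that, under fixed measurement noise, mean thickness error
rises monotonically as the matrix is interpolated toward one with
proportional rows.

## Synthetic phantom

The generator emulates the acquisition end to end so the inverse can be
validated against known ground truth:

- **Beam**: isotropic Gaussian, default amplitude 52 000 counts
  (≈ 0.8 of 16-bit full scale, comfortably below saturation), sigma
  0.625 × frame size so the frame corners stay above the dark floor
  after attenuation.
- **Scene**: axis-aligned rectangles and ellipses plus full-frame
  overlay layers; the `blocks` preset places meat (0.5 cm), bone
  (0.3 cm) and skin (0.2 cm) slabs side by side, and `covered` adds a
  0.1 cm skin overlay across the whole frame — the occluded-specimen
  scenario.
- **Sensor**: multiplicative lognormal speckle (median 1, default
  σ = 0.02), additive Gaussian read noise (default 2 counts), clipping
  at the saturation level, then half-away-from-zero rounding to integer
  counts. Reference and object frames draw independent noise — they are
  separate exposures. Defaults for the noise levels are package choices
  of a plausible bench magnitude; no measured camera values exist for
  them. Output is bit-identical for a fixed seed.

What the phantom does *not* model: physical scattering between layers,
case reflections, wavelength-dependent beam shape, nonuniform sensor
response. Passing tests on phantoms therefore demonstrate the
correctness of the inversion and the predicted sensitivity to noise and
conditioning — not the field accuracy on real tissue, which depends on
exactly the effects excluded here.

## Evaluation

Binary masks come from thresholding a thickness map — Otsu by default,
as a reproducible stand-in for manual boundary tracing; prediction and
reference are thresholded with the same method so the score measures
the decomposition, not the thresholding. Two overlap statistics are
reported side by side because the field's verbal definition (overlap
over reference area) and its named criterion (Sørensen–Dice) disagree:
`overlap = |P∩R|/|R|` (asymmetric) and `dice = 2|P∩R|/(|P|+|R|)`
(symmetric, both-empty defined as 1). Continuous recovery adds
per-tissue RMSE, max absolute error and bias in cm over the jointly
valid mask.

## Numerical choices and degenerate inputs

- Negative thicknesses from the solve are unphysical; the default
  `clip_zero` policy zeroes them while `raw_values` keeps the honest
  solver output and `negatives_fraction` summarizes how often it
  happened.
- An all-invalid frame decomposes to all-NaN with a warning and a
  negatives fraction of 0 over the empty set.
- Grayscale renders map 0 cm → white and `display_max` → black
  (inverse-video); `display_max` defaults to the 99th percentile of the
  map because no fixed display scaling convention exists. Rounding is
  half-away-from-zero.
- A constant map cannot be Otsu-thresholded; the error suggests fixed
  mode.
- Coefficient matrices must be complete label grids; zero entries are
  tolerated (a transparent tissue in synthetic settings) but negative
  ones are not.

## Problem sizes

Tests and the acceptance script use 256×256 frames for the exact
round-trip studies, 128×128 for the noisy speckle sweeps, 2000 noise
draws for the conditioning study and 200 replicates for the fit-bias
check — sizes at which every quantity reported is stable while the full
suite runs in seconds.
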