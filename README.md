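# biodecomp

Decompose multispectral transmittance images of layered biological
specimens into per-tissue thickness maps.

## The problem

A near-infrared transmittance image of a layered specimen superimposes
every tissue along the optical path: a single frame cannot say whether a
dark pixel is thick muscle or thin bone. But attenuation is
tissue-*and*-wavelength specific. If a specimen made of k tissues is
photographed k times at k monochromatic wavelengths, each pixel yields k
Beer–Lambert equations in the k unknown tissue thicknesses:

```
T_λ(x, y) = I_λ(x, y) / I0_λ(x, y) = exp(-Σ_k μ_kλ d_k(x, y))
```

Taking `ln(1/T)` linearises the model. With the k×k attenuation matrix
`μ` (rows = wavelengths, columns = tissues, units cm⁻¹) measured once
per tissue panel, the per-pixel thickness vector is a linear solve:

```
d(x, y) = μ⁻¹ · ln T⁻¹(x, y)        [cm]
```

Repeating the solve over the frame produces one thickness image per
tissue. The package covers the whole loop:

- **core** — transmittance ratios, `ln(1/T)` fields, forward attenuation,
  validity masks (saturation, dark floor, clamping).
- **characterization** — per-pixel attenuation planes `-ln T / d` from
  homogeneous slabs of known thickness, masked means with ± spread, the
  thick-slab extrapolation `μ(d) = β₀ + β₁/d³` that removes the
  specimen-case bias, matrix assembly and invertibility diagnostics
  (determinant, condition number).
- **decomposition** — one LU factorization applied to every valid pixel,
  negativity bookkeeping, inverse-video grayscale renders.
- **phantom** — a synthetic scene generator (Gaussian beam, multi-layer
  exponential attenuation, lognormal speckle, read noise, saturation
  clipping, quantization) with stored ground truth.
- **evaluation** — Sørensen–Dice and matching-area overlap of thresholded
  tissue masks, plus RMSE/bias against phantom ground truth.

A built-in reference matrix holds measured NIR coefficients for chicken
meat, bone and skin at 780/808/980 nm (e.g. meat 4.004 ± 0.286 cm⁻¹ at
780 nm); its determinant, 0.087 cm⁻³, is small enough that the
conditioning diagnostics matter — see `examples/noise_and_conditioning.py`.

## Worked example

`python examples/decompose_phantom.py` builds a noise-free 256×256
three-slab phantom, renders the three wavelength frames, inverts the
system and scores the result:

```
max |thickness error| = 4.5e-15 cm
tissue      overlap%    dice%    rmse_cm
meat          100.0%  100.0%  4.897e-16
bone          100.0%  100.0%  9.324e-16
skin          100.0%  100.0%  5.677e-16
```

With noise and quantization disabled the render→decompose pair is exact
to machine precision and every tissue's area is recovered perfectly.
`examples/characterize_slabs.py` shows the coefficient workflow (the
apparent coefficient falls from 3.96 to 3.39 cm⁻¹ as slabs thicken; the
fit recovers the 3.335 cm⁻¹ asymptote), and
`examples/noise_and_conditioning.py` shows how speckle and a
near-singular matrix degrade accuracy.

## Command line

The same pipeline is scriptable:

```sh
biodecomp simulate  --preset blocks --seed 7 --out sim/
biodecomp decompose --input sim/ --out dec/
biodecomp evaluate  --pred dec/ --truth sim/ --out eval/
```

Every run writes a JSON manifest (parameters, seed, version) sufficient
to reproduce it; `decompose` prints the matrix determinant and condition
number and warns when conditioning is poor.

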