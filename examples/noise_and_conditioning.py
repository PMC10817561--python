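"""How speckle noise and matrix conditioning limit decomposition accuracy.

First sweeps multiplicative speckle over the side-by-side phantom and
reports per-tissue Dice; then interpolates the attenuation matrix
toward one with proportional rows and reports how a fixed measurement
noise inflates the thickness error as the condition number grows.
"""

import numpy as np

from biodecomp import (
    AttenuationMatrix,
    chicken_reference_matrix,
    decompose_stack,
    evaluate_decomposition,
    generate,
    log_inverse_transmittance,
    matrix_diagnostics,
    preset,
    transmittance_stack,
)

matrix = chicken_reference_matrix()

print("speckle sweep (128x128 phantom):")
for sigma in (0.0, 0.02, 0.1):
    spec = preset("blocks", frame_shape=(128, 128), seed=13)
    spec.speckle_sigma, spec.read_sigma = sigma, 0.0
    phantom = generate(spec, matrix)
    stack, _ = transmittance_stack(phantom.object_images,
                                   phantom.reference_images)
    result = decompose_stack(log_inverse_transmittance(stack), matrix)
    report = evaluate_decomposition(result.thickness_maps,
                                    phantom.ground_truth)
    dices = {t: f"{100 * m['dice']:.1f}%"
             for t, m in report.per_tissue.items()}
    print(f"  sigma = {sigma:<5} dice = {dices}")

print("\nconditioning sweep (fixed ln(1/T) noise, sigma = 0.01):")
target = matrix.values.copy()
target[2] = target[0] * (target[2].sum() / target[0].sum())
truth = np.array([0.5, 0.2, 0.1])
noise = np.random.default_rng(7).normal(0, 0.01, (3, 2000))
for t in (0.0, 0.7, 0.95):
    vals = (1 - t) * matrix.values + t * target
    m = AttenuationMatrix(vals, matrix.wavelengths_nm, matrix.tissue_labels)
    diag = matrix_diagnostics(m)
    sol = np.linalg.solve(vals, (vals @ truth)[:, None] + noise)
    err = float(np.mean(np.abs(sol - truth[:, None])))
    print(f"  cond = {diag.condition_number:9.1f}  det = {diag.determinant:8.5f}"
          f"  mean |error| = {err:.4f} cm")

print("\nDice falls as speckle rises, and the same measurement noise costs")
print("more thickness accuracy as the matrix rows approach linear dependence:")
print("wavelength choice, not the solver, bounds the achievable accuracy.")
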