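"""Decompose a synthetic three-tissue phantom and score the result.

Builds a noise-free 256x256 scene with meat, bone and skin slabs side
by side, renders the three NIR camera frames with the built-in chicken
attenuation matrix, inverts the per-pixel Beer-Lambert system, and
compares the recovered thickness maps with the ground truth.
"""

import numpy as np

from biodecomp import (
    chicken_reference_matrix,
    decompose_stack,
    evaluate_decomposition,
    generate,
    log_inverse_transmittance,
    preset,
    transmittance_stack,
)

matrix = chicken_reference_matrix()
spec = preset("blocks", frame_shape=(256, 256), seed=0, noise=False,
              quantize=False)
phantom = generate(spec, matrix)

stack, _ = transmittance_stack(phantom.object_images, phantom.reference_images)
result = decompose_stack(log_inverse_transmittance(stack), matrix)

err = np.nanmax(np.abs(result.thickness_maps.values
                       - phantom.ground_truth.values))
print(f"max |thickness error| = {err:.3g} cm")
report = evaluate_decomposition(result.thickness_maps, phantom.ground_truth)
print(report.to_text())
print("\nWith noise and quantization disabled the decomposition is the exact")
print("inverse of the forward model: errors at machine precision, Dice and")
print("overlap at 100% for every tissue.")
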