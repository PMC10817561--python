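import numpy as np
import pytest

from biodecomp import (
    IntensityImage,
    chicken_reference_matrix,
    generate,
    preset,
)


@pytest.fixture(scope="session")
def table_matrix():
    """The built-in chicken-tissue reference matrix (3x3, cm^-1)."""
    return chicken_reference_matrix()


@pytest.fixture()
def flat_pair():
    """Factory for uniform object/reference image pairs."""

    def make(obj_counts, ref_counts, shape=(8, 8), wavelength=808.0, bit_depth=8):
        obj = IntensityImage(
            np.full(shape, float(obj_counts)), bit_depth, wavelength
        )
        ref = IntensityImage(
            np.full(shape, float(ref_counts)), bit_depth, wavelength
        )
        return obj, ref

    return make


@pytest.fixture(scope="session")
def clean_blocks(table_matrix):
    """Noise-free, unquantized side-by-side phantom at 64x64."""
    spec = preset("blocks", frame_shape=(64, 64), noise=False, quantize=False)
    return generate(spec, table_matrix)
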