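"""Per-pixel inversion of the attenuation linear system.

At every valid pixel the k-vector of log-inverse transmittances equals
the attenuation matrix times the k-vector of tissue thicknesses; the
decomposition solves that system once per pixel, reusing a single LU
factorization of the matrix across the whole frame.  The method is
strictly per-pixel: no spatial coupling, regularization or denoising.

Negative solutions can occur when noise pushes a pixel outside the
physical cone; they are clipped to zero by default but preserved in
``raw_values`` and summarized by ``negatives_fraction``.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings as _warnings

import numpy as np
from scipy.linalg import lu_factor, lu_solve

from .core import NO_DATA, IntensityImage, LogInvTransmittanceField, ThicknessMaps
from .characterization import AttenuationMatrix, MatrixDiagnostics, matrix_diagnostics

__all__ = [
    "DecompositionResult",
    "decompose_pixel",
    "decompose_stack",
    "postprocess",
    "render_thickness_image",
]


@dataclass
class DecompositionResult:
    """Thickness maps plus solver diagnostics for one frame."""

    thickness_maps: ThicknessMaps
    negatives_fraction: float  #: valid pixels with any raw negative component
    diagnostics: MatrixDiagnostics

    def __post_init__(self) -> None:
        if not 0.0 <= self.negatives_fraction <= 1.0:
            raise ValueError("negatives_fraction must lie in [0, 1]")


def _check_invertible(matrix: AttenuationMatrix) -> MatrixDiagnostics:
    diag = matrix_diagnostics(matrix)
    if not diag.invertible:
        raise np.linalg.LinAlgError(
            f"attenuation matrix is singular (determinant {diag.determinant:.3g}); "
            "cannot decompose"
        )
    return diag


def decompose_pixel(
    log_inv_vec: np.ndarray, matrix: AttenuationMatrix
) -> np.ndarray:
    """Solve one pixel's system: raw thickness vector in cm.

    Uses a linear solve rather than an explicitly formed inverse.  The
    result is the raw solution; negative components are not clipped
    here (see :func:`postprocess`).
    """
    _check_invertible(matrix)
    b = np.asarray(log_inv_vec, dtype=float)
    if b.shape != (matrix.k,):
        raise ValueError(f"expected a length-{matrix.k} vector, got shape {b.shape}")
    return np.linalg.solve(matrix.values, b)


def decompose_stack(
    field: LogInvTransmittanceField,
    matrix: AttenuationMatrix,
    *,
    policy: str = "clip_zero",
) -> DecompositionResult:
    """Invert the linear system at every valid pixel of the frame.

    The field's wavelength order must equal the matrix row order (checked
    by label; no silent reordering).  One LU factorization of the matrix
    is shared by all pixels.  Invalid pixels carry the no-data value in
    the output maps.
    """
    if tuple(field.wavelengths_nm) != tuple(matrix.wavelengths_nm):
        raise ValueError(
            f"wavelength order mismatch: field {field.wavelengths_nm} vs "
            f"matrix rows {matrix.wavelengths_nm}"
        )
    diag = _check_invertible(matrix)

    k = matrix.k
    frame = field.values.shape[1:]
    valid = field.valid_mask
    raw = np.full((k, *frame), NO_DATA)
    n_valid = int(valid.sum())
    if n_valid == 0:
        _warnings.warn(
            "all pixels invalid: empty decomposition", stacklevel=2
        )
        negatives_fraction = 0.0
    else:
        rhs = field.values[:, valid]  # (k, n_valid)
        lu = lu_factor(matrix.values)
        sol = lu_solve(lu, rhs)
        raw[:, valid] = sol
        negatives_fraction = float(np.any(sol < 0, axis=0).mean())

    maps = ThicknessMaps(
        values=_apply_policy(raw, policy, valid),
        tissue_labels=matrix.tissue_labels,
        valid_mask=valid,
        raw_values=raw,
        clipped=(policy == "clip_zero"),
    )
    return DecompositionResult(maps, negatives_fraction, diag)


def _apply_policy(raw: np.ndarray, policy: str, valid: np.ndarray) -> np.ndarray:
    if policy == "clip_zero":
        out = raw.copy()
        np.clip(out, 0.0, None, out=out)
        out[:, ~valid] = NO_DATA
        return out
    if policy == "keep_raw":
        return raw.copy()
    raise ValueError(f"unknown policy {policy!r}; use 'clip_zero' or 'keep_raw'")


def postprocess(result: DecompositionResult, policy: str = "clip_zero") -> ThicknessMaps:
    """Re-derive thickness maps from the raw solution under a policy.

    ``clip_zero`` replaces negative raw components with 0 (default);
    ``keep_raw`` passes the raw solver output through unchanged.
    """
    maps = result.thickness_maps
    assert maps.raw_values is not None
    return ThicknessMaps(
        values=_apply_policy(maps.raw_values, policy, maps.valid_mask),
        tissue_labels=maps.tissue_labels,
        valid_mask=maps.valid_mask,
        raw_values=maps.raw_values.copy(),
        clipped=(policy == "clip_zero"),
    )


def render_thickness_image(
    thickness_map: np.ndarray,
    display_max: float | None = None,
    *,
    bit_depth: int = 8,
    no_data_gray: int | None = None,
    wavelength_nm: float = 1.0,
) -> IntensityImage:
    """Render a thickness map as an inverse-video grayscale image.

    Zero thickness renders white (full scale) and ``display_max`` cm or
    more renders black — thicker is darker.  ``display_max`` defaults to
    the 99th percentile of the finite map values.  No-data pixels render
    at a sentinel gray (default mid-scale).  Rounding is
    half-away-from-zero, so at 8-bit half of ``display_max`` maps to
    127.5 and rounds to 128.
    """
    m = np.asarray(thickness_map, dtype=float)
    finite = np.isfinite(m)
    full = 2**bit_depth - 1
    if display_max is None:
        if not finite.any():
            raise ValueError("map has no finite values; pass display_max")
        display_max = float(np.percentile(m[finite], 99))
        if display_max <= 0:
            display_max = float(m[finite].max()) or 1.0
    if display_max <= 0:
        raise ValueError("display_max must be positive")
    if no_data_gray is None:
        no_data_gray = 2 ** (bit_depth - 1)

    frac = np.clip(m / display_max, 0.0, 1.0)
    gray = np.floor((1.0 - frac) * full + 0.5)  # half-away-from-zero for x >= 0
    out = np.where(finite, gray, float(no_data_gray)).astype(
        np.uint8 if bit_depth <= 8 else np.uint16
    )
    return IntensityImage(out, bit_depth=bit_depth, wavelength_nm=wavelength_nm)
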