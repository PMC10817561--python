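"""Beer-Lambert primitives shared by every stage of the pipeline.

A camera records intensity counts ``I(x, y)`` through a specimen and
``I0(x, y)`` through empty air (the reference beam).  Their per-pixel
ratio is the transmittance ``T = I / I0``; for a stack of homogeneous
layers the Beer-Lambert law gives ``T = exp(-sum_k mu_k d_k)`` where
``mu_k`` is the attenuation coefficient of layer ``k`` (cm^-1) and
``d_k`` its path length (cm).  Taking ``ln(1/T)`` linearises the model,
so a k-wavelength image stack becomes, pixel by pixel, a k-dimensional
linear system in the k unknown tissue thicknesses.

This module holds the domain containers (intensity images, transmittance
stacks, log-inverse-transmittance fields, thickness maps) and the scalar
and image-level transforms between them.  Units are fixed package-wide:
thickness in cm, attenuation coefficients in cm^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "DEFAULT_EPS",
    "DEFAULT_DARK_FLOOR_FRACTION",
    "NO_DATA",
    "IntensityImage",
    "TransmittanceStack",
    "LogInvTransmittanceField",
    "ThicknessMaps",
    "TransmittanceResult",
    "transmittance",
    "transmittance_stack",
    "log_inverse_transmittance",
    "forward_attenuation",
]

#: Lower clamp for transmittance; keeps ln(1/T) finite and nonnegative.
DEFAULT_EPS = 1e-6

#: Reference pixels below this fraction of the saturation level are
#: treated as dark floor and marked invalid (the ratio would be noise).
DEFAULT_DARK_FLOOR_FRACTION = 0.01

#: Value carried by invalid pixels in float outputs.
NO_DATA = np.nan


@dataclass
class IntensityImage:
    """Single-channel camera frame at one monochromatic wavelength.

    Parameters
    ----------
    pixels
        2-D array of nonnegative intensity counts.  May be float when
        quantization is disabled in simulation.
    bit_depth
        Camera bit depth; counts must not exceed ``2**bit_depth - 1``.
    wavelength_nm
        Illumination wavelength label.  Used to guard against pairing
        images taken at different wavelengths.
    saturation_level
        Counts at which the sensor clips.  Defaults to the full-scale
        value ``2**bit_depth - 1``.
    """

    pixels: np.ndarray
    bit_depth: int
    wavelength_nm: float
    saturation_level: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(
                f"intensity image must be single-channel 2-D, got shape "
                f"{self.pixels.shape} ({self.pixels.ndim} axes)"
            )
        if self.bit_depth <= 0:
            raise ValueError("bit_depth must be positive")
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength_nm must be positive")
        full_scale = 2**self.bit_depth - 1
        if self.saturation_level is None:
            self.saturation_level = float(full_scale)
        if self.saturation_level > full_scale:
            raise ValueError(
                f"saturation_level {self.saturation_level} exceeds full scale "
                f"{full_scale} for {self.bit_depth}-bit"
            )
        if np.any(self.pixels < 0):
            raise ValueError("intensity counts must be nonnegative")
        if np.any(self.pixels > full_scale):
            raise ValueError(
                f"intensity counts exceed full scale {full_scale} "
                f"for {self.bit_depth}-bit"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class TransmittanceStack:
    """k aligned transmittance images, one per wavelength.

    ``values`` has shape (k, M, N); valid entries lie in (0, 1].
    ``valid_mask`` is true where every wavelength's pixel is usable
    (unsaturated and above the reference dark floor).
    """

    values: np.ndarray
    wavelengths_nm: tuple[float, ...]
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        self.wavelengths_nm = tuple(float(w) for w in self.wavelengths_nm)
        if self.values.ndim != 3:
            raise ValueError("stack values must be 3-D (wavelength, rows, cols)")
        if len(self.wavelengths_nm) != self.values.shape[0]:
            raise ValueError("wavelength count does not match stack depth")
        if self.valid_mask.shape != self.values.shape[1:]:
            raise ValueError("valid_mask shape does not match frame")
        v = self.values[:, self.valid_mask]
        if v.size and (np.any(v <= 0) or np.any(v > 1) or not np.all(np.isfinite(v))):
            raise ValueError("valid transmittance values must lie in (0, 1]")

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.values.shape[1:]  # type: ignore[return-value]


@dataclass
class LogInvTransmittanceField:
    """Per-pixel vectors ln(1/T) over the frame; shape (k, M, N).

    This is the right-hand side of the per-pixel linear system.  Valid
    entries are finite and >= 0; invalid pixels carry NaN.
    """

    values: np.ndarray
    wavelengths_nm: tuple[float, ...]
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        self.wavelengths_nm = tuple(float(w) for w in self.wavelengths_nm)
        v = self.values[:, self.valid_mask]
        if v.size and (np.any(v < 0) or not np.all(np.isfinite(v))):
            raise ValueError("valid ln(1/T) values must be finite and >= 0")


@dataclass
class ThicknessMaps:
    """Per-tissue thickness images in cm; shape (k, M, N).

    ``values`` holds the clipped (physical, >= 0) maps; ``raw_values``
    preserves the unclipped solver output, which may dip negative under
    noise and is kept for diagnostics.
    """

    values: np.ndarray
    tissue_labels: tuple[str, ...]
    valid_mask: np.ndarray
    raw_values: np.ndarray | None = None
    clipped: bool = True  #: False when values carry the raw (signed) solution

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        self.tissue_labels = tuple(str(t) for t in self.tissue_labels)
        if self.raw_values is None:
            self.raw_values = self.values.copy()
        else:
            self.raw_values = np.asarray(self.raw_values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("thickness maps must be 3-D (tissue, rows, cols)")
        if len(self.tissue_labels) != self.values.shape[0]:
            raise ValueError("tissue label count does not match map count")
        if self.raw_values.shape != self.values.shape:
            raise ValueError("raw_values shape must match values")
        if self.valid_mask.shape != self.values.shape[1:]:
            raise ValueError("valid_mask shape does not match frame")
        v = self.values[:, self.valid_mask]
        if self.clipped and v.size and np.any(v < 0):
            raise ValueError("clipped thickness values must be >= 0")

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.values.shape[1:]  # type: ignore[return-value]

    def map_for(self, tissue: str) -> np.ndarray:
        """Return one tissue's 2-D thickness map (clipped values)."""
        try:
            i = self.tissue_labels.index(tissue)
        except ValueError:
            raise KeyError(
                f"unknown tissue {tissue!r}; have {self.tissue_labels}"
            ) from None
        return self.values[i]


class TransmittanceResult(NamedTuple):
    """Output of :func:`transmittance`."""

    values: np.ndarray
    valid_mask: np.ndarray
    n_clamped_high: int  #: pixels brighter than the reference, clamped to 1
    n_clamped_low: int  #: pixels clamped up to eps to keep ln finite


def transmittance(
    object_img: IntensityImage,
    reference_img: IntensityImage,
    *,
    dark_floor: float | None = None,
    dark_floor_fraction: float = DEFAULT_DARK_FLOOR_FRACTION,
    eps: float = DEFAULT_EPS,
) -> TransmittanceResult:
    """Per-pixel transmittance T = I / I0 with validity bookkeeping.

    Pixels are invalid where the reference is at or below the dark
    floor (default 1% of the saturation level) or where either frame is
    saturated; such pixels carry no attenuation information.  Valid
    ratios above 1 (possible with noise) are clamped to 1, and ratios at
    or below ``eps`` are clamped to ``eps``; both events are counted so
    downstream users can audit the clamping.
    """
    if object_img.shape != reference_img.shape:
        raise ValueError(
            f"image shape mismatch: object {object_img.shape} vs "
            f"reference {reference_img.shape}"
        )
    if object_img.wavelength_nm != reference_img.wavelength_nm:
        raise ValueError(
            f"wavelength mismatch: object {object_img.wavelength_nm} nm vs "
            f"reference {reference_img.wavelength_nm} nm"
        )
    ref = reference_img.pixels.astype(float)
    obj = object_img.pixels.astype(float)
    if dark_floor is None:
        dark_floor = dark_floor_fraction * reference_img.saturation_level

    valid = (
        (ref > dark_floor)
        & (ref < reference_img.saturation_level)
        & (obj < object_img.saturation_level)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        t = obj / ref
    t = np.where(valid, t, NO_DATA)

    high = valid & (t > 1.0)
    low = valid & (t <= eps)
    t[high] = 1.0
    t[low] = eps
    return TransmittanceResult(t, valid, int(high.sum()), int(low.sum()))


def transmittance_stack(
    object_images: Sequence[IntensityImage],
    reference_images: Sequence[IntensityImage],
    **kwargs,
) -> tuple[TransmittanceStack, dict]:
    """Build a :class:`TransmittanceStack` from paired image lists.

    The stack's validity mask is the AND over wavelengths: a pixel must
    be usable at every wavelength to enter the linear system.  Returns
    the stack plus a diagnostics dict with per-wavelength clamp counts.
    """
    if len(object_images) != len(reference_images):
        raise ValueError("need one reference image per object image")
    if not object_images:
        raise ValueError("empty image list")
    planes, masks, diags = [], [], []
    for obj, ref in zip(object_images, reference_images):
        res = transmittance(obj, ref, **kwargs)
        planes.append(res.values)
        masks.append(res.valid_mask)
        diags.append(
            {
                "wavelength_nm": obj.wavelength_nm,
                "n_clamped_high": res.n_clamped_high,
                "n_clamped_low": res.n_clamped_low,
            }
        )
    valid = np.logical_and.reduce(masks)
    values = np.stack(planes)
    values[:, ~valid] = NO_DATA
    stack = TransmittanceStack(
        values, tuple(img.wavelength_nm for img in object_images), valid
    )
    return stack, {"per_wavelength": diags}


def log_inverse_transmittance(stack: TransmittanceStack) -> LogInvTransmittanceField:
    """Elementwise ln(1/T); the linearised attenuation field."""
    with np.errstate(divide="ignore", invalid="ignore"):
        values = -np.log(stack.values)
    values[:, ~stack.valid_mask] = NO_DATA
    return LogInvTransmittanceField(values, stack.wavelengths_nm, stack.valid_mask)


def forward_attenuation(
    thicknesses: Sequence[float], coefficients: Sequence[float]
) -> float:
    """Transmittance of a stack of layers: exp(-sum_k mu_k d_k).

    ``thicknesses`` in cm (>= 0), ``coefficients`` in cm^-1 (> 0).
    """
    d = np.asarray(thicknesses, dtype=float)
    mu = np.asarray(coefficients, dtype=float)
    if d.shape != mu.shape:
        raise ValueError("thicknesses and coefficients must have equal length")
    if np.any(d < 0):
        raise ValueError("negative thickness is unphysical")
    if np.any(mu <= 0):
        raise ValueError("attenuation coefficients must be positive")
    return float(np.exp(-float(d @ mu)))
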