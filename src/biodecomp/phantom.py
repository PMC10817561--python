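"""Synthetic phantom generator: ground-truth maps plus camera frames.

The generator emulates the acquisition geometry end to end: a Gaussian
illumination beam, exponential multi-layer attenuation through stacked
tissue regions, multiplicative lognormal speckle, additive Gaussian
read noise, sensor saturation clipping and integer quantization.  The
ground-truth thickness maps are stored alongside the rendered frames so
a decomposition run can be scored exactly.

Two presets reproduce the canonical bench layouts:

``blocks``
    three tissue slabs (meat, bone, skin) arranged side by side.
``covered``
    the same three slabs with a uniform skin layer overlaid across the
    whole frame — the occluded-specimen scenario.

With ``speckle_sigma = read_sigma = 0`` and ``quantize = False`` the
rendered stack is the exact Beer-Lambert forward model, so the phantom
and the decomposition form a machine-precision inverse pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .core import IntensityImage, ThicknessMaps
from .characterization import AttenuationMatrix, chicken_reference_matrix

__all__ = [
    "Region",
    "PhantomSpec",
    "PhantomOutput",
    "make_thickness_maps",
    "gaussian_beam",
    "render_stack",
    "generate",
    "preset",
    "PRESETS",
]


@dataclass(frozen=True)
class Region:
    """One tissue slab: an axis-aligned rectangle or ellipse.

    Geometry is in 0-based pixel coordinates, x = column, y = row.
    Rectangle geometry is (x0, y0, width, height); ellipse geometry is
    (cx, cy, semi_x, semi_y).
    """

    tissue_label: str
    shape: str  # "rectangle" | "ellipse"
    geometry: tuple[float, float, float, float]
    thickness_cm: float

    def __post_init__(self) -> None:
        if self.shape not in ("rectangle", "ellipse"):
            raise ValueError(f"unknown region shape {self.shape!r}")
        if self.thickness_cm < 0:
            raise ValueError("region thickness must be >= 0")

    def rasterize(self, frame_shape: tuple[int, int]) -> np.ndarray:
        m, n = frame_shape
        yy, xx = np.mgrid[0:m, 0:n]
        if self.shape == "rectangle":
            x0, y0, w, h = self.geometry
            return (xx >= x0) & (xx < x0 + w) & (yy >= y0) & (yy < y0 + h)
        cx, cy, sx, sy = self.geometry
        if sx <= 0 or sy <= 0:
            raise ValueError("ellipse semi-axes must be positive")
        return ((xx - cx) / sx) ** 2 + ((yy - cy) / sy) ** 2 <= 1.0


@dataclass
class PhantomSpec:
    """Scene description for one synthetic acquisition.

    Beam parameters are (amplitude counts, center (x0, y0) in pixels,
    sigma in pixels).  ``speckle_sigma`` is the lognormal sigma of the
    multiplicative speckle (median 1; 0 disables); ``read_sigma`` is the
    additive Gaussian read noise in counts.  ``quantize = False`` keeps
    float frames for exact round-trip studies.
    """

    frame_shape: tuple[int, int] = (256, 256)
    tissue_labels: tuple[str, ...] = ("meat", "bone", "skin")
    regions: tuple[Region, ...] = ()
    overlay_layers: tuple[tuple[str, float], ...] = ()
    beam_amplitude: float = 52000.0
    beam_center: tuple[float, float] | None = None  # defaults to frame centre
    beam_sigma: float = 160.0
    speckle_sigma: float = 0.02
    read_sigma: float = 2.0
    bit_depth: int = 16
    saturation_level: float | None = None
    quantize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beam_sigma <= 0:
            raise ValueError("beam_sigma must be positive")
        if self.speckle_sigma < 0 or self.read_sigma < 0:
            raise ValueError("noise sigmas must be >= 0")
        if self.saturation_level is None:
            self.saturation_level = float(2**self.bit_depth - 1)
        if self.beam_center is None:
            m, n = self.frame_shape
            self.beam_center = ((n - 1) / 2.0, (m - 1) / 2.0)
        known = set(self.tissue_labels)
        for r in self.regions:
            if r.tissue_label not in known:
                raise ValueError(
                    f"region references unknown tissue {r.tissue_label!r}; "
                    f"known: {sorted(known)}"
                )
        for t, d in self.overlay_layers:
            if t not in known:
                raise ValueError(f"overlay references unknown tissue {t!r}")
            if d < 0:
                raise ValueError("overlay thickness must be >= 0")


@dataclass
class PhantomOutput:
    """Ground truth plus the frames a camera would record."""

    ground_truth: ThicknessMaps
    reference_images: list[IntensityImage]
    object_images: list[IntensityImage]
    spec: PhantomSpec


def make_thickness_maps(spec: PhantomSpec) -> ThicknessMaps:
    """Rasterize regions and overlays into per-tissue thickness maps.

    Each tissue's map is the sum of its regions' thicknesses plus any
    full-frame overlay; pixels outside every region and overlay are 0.
    """
    k = len(spec.tissue_labels)
    values = np.zeros((k, *spec.frame_shape))
    for r in spec.regions:
        i = spec.tissue_labels.index(r.tissue_label)
        values[i][r.rasterize(spec.frame_shape)] += r.thickness_cm
    for t, d in spec.overlay_layers:
        values[spec.tissue_labels.index(t)] += d
    return ThicknessMaps(
        values=values,
        tissue_labels=spec.tissue_labels,
        valid_mask=np.ones(spec.frame_shape, dtype=bool),
    )


def gaussian_beam(
    frame_shape: tuple[int, int],
    amplitude: float,
    center: tuple[float, float],
    sigma: float,
) -> np.ndarray:
    """Isotropic Gaussian beam profile evaluated at pixel centres.

    ``center`` is (x0, y0) in pixel coordinates (x = column, y = row).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    m, n = frame_shape
    yy, xx = np.mgrid[0:m, 0:n]
    x0, y0 = center
    r2 = (xx - x0) ** 2 + (yy - y0) ** 2
    return amplitude * np.exp(-r2 / (2.0 * sigma**2))


def _sensor(
    ideal: np.ndarray, spec: PhantomSpec, rng: np.random.Generator
) -> np.ndarray:
    """Apply speckle, read noise, saturation clipping and quantization."""
    out = ideal
    if spec.speckle_sigma > 0:
        out = out * rng.lognormal(0.0, spec.speckle_sigma, size=out.shape)
    if spec.read_sigma > 0:
        out = out + rng.normal(0.0, spec.read_sigma, size=out.shape)
    out = np.clip(out, 0.0, spec.saturation_level)
    if spec.quantize:
        out = np.floor(out + 0.5)  # half-away-from-zero for counts >= 0
    return out


def render_stack(
    maps: ThicknessMaps, matrix: AttenuationMatrix, spec: PhantomSpec
) -> PhantomOutput:
    """Render reference and object frames at every wavelength.

    Per wavelength the ideal object intensity is the beam times
    ``exp(-sum_t mu[lambda, t] * d_t(x, y))``; reference frames run the
    same sensor pipeline with zero thickness.  Reference and object use
    independent noise draws (they are separate exposures).  Deterministic
    for a fixed spec seed.
    """
    if tuple(maps.tissue_labels) != tuple(matrix.tissue_labels):
        raise ValueError(
            f"tissue order mismatch: maps {maps.tissue_labels} vs "
            f"matrix columns {matrix.tissue_labels}"
        )
    if maps.frame_shape != tuple(spec.frame_shape):
        raise ValueError("thickness maps frame does not match spec frame_shape")
    rng = np.random.default_rng(spec.seed)
    beam = gaussian_beam(
        spec.frame_shape, spec.beam_amplitude, spec.beam_center, spec.beam_sigma
    )
    # optical depth per wavelength: (k, M, N)
    depth = np.tensordot(matrix.values, maps.values, axes=(1, 0))
    refs, objs = [], []
    for i, wl in enumerate(matrix.wavelengths_nm):
        ref = _sensor(beam, spec, rng)
        obj = _sensor(beam * np.exp(-depth[i]), spec, rng)
        kwargs = dict(
            bit_depth=spec.bit_depth,
            wavelength_nm=wl,
            saturation_level=spec.saturation_level,
        )
        refs.append(IntensityImage(ref, **kwargs))
        objs.append(IntensityImage(obj, **kwargs))
    return PhantomOutput(maps, refs, objs, spec)


def generate(
    spec: PhantomSpec, matrix: AttenuationMatrix | None = None
) -> PhantomOutput:
    """Convenience: rasterize the spec's maps and render the stack."""
    if matrix is None:
        matrix = chicken_reference_matrix()
    return render_stack(make_thickness_maps(spec), matrix, spec)


def _blocks_regions(frame_shape: tuple[int, int]) -> tuple[Region, ...]:
    """Three side-by-side slabs with small gaps, one per tissue."""
    m, n = frame_shape
    gap = max(2, n // 32)
    w = (n - 4 * gap) // 3
    y0, h = m // 8, m - m // 4
    thick = {"meat": 0.5, "bone": 0.3, "skin": 0.2}
    regions = []
    for j, tissue in enumerate(("meat", "bone", "skin")):
        x0 = gap + j * (w + gap)
        regions.append(
            Region(tissue, "rectangle", (x0, y0, w, h), thick[tissue])
        )
    return tuple(regions)


def preset(
    name: str,
    *,
    frame_shape: tuple[int, int] = (256, 256),
    seed: int = 0,
    noise: bool = True,
    quantize: bool = True,
) -> PhantomSpec:
    """Build a named preset scene.

    ``blocks``: meat (0.5 cm), bone (0.3 cm) and skin (0.2 cm) slabs
    side by side.  ``covered``: the same slabs under a 0.1 cm full-frame
    skin overlay.  ``noise=False`` zeroes both noise sources.
    """
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    spec = PhantomSpec(
        frame_shape=frame_shape,
        regions=_blocks_regions(frame_shape),
        overlay_layers=(("skin", 0.1),) if name == "covered" else (),
        beam_sigma=0.625 * min(frame_shape),
        seed=seed,
        quantize=quantize,
    )
    if not noise:
        spec = replace(spec, speckle_sigma=0.0, read_sigma=0.0)
    return spec


PRESETS = ("blocks", "covered")
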