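"""File formats: raster images, coefficient tables, configs, manifests.

Raster I/O is single-channel TIFF (8/16-bit integer or 32-bit float)
and PNG (8/16-bit).  Arrays are row-major with origin at top-left;
x = column index, y = row index, 0-based.  Color inputs are rejected —
the acquisition model is monochromatic.

Coefficient tables travel as CSV with columns
(wavelength_nm, tissue, mu_cm_inv, sd) or as JSON; an assembled matrix
plus its diagnostics serializes to JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .characterization import (
    AttenuationMatrix,
    MatrixDiagnostics,
    build_attenuation_matrix,
)
from .core import IntensityImage, ThicknessMaps
from .phantom import PhantomSpec, Region

__all__ = [
    "read_image",
    "write_image",
    "write_thickness_tiff",
    "read_thickness_tiff",
    "read_matrix_csv",
    "write_matrix_csv",
    "matrix_to_json",
    "matrix_from_json",
    "write_manifest",
    "read_manifest",
    "spec_from_toml",
    "spec_to_dict",
    "spec_from_dict",
]

_TIFF_SUFFIXES = {".tif", ".tiff"}
_PNG_SUFFIXES = {".png"}


def _bit_depth_of(arr: np.ndarray, path: Path) -> int:
    if arr.dtype == np.uint8:
        return 8
    if arr.dtype == np.uint16:
        return 16
    if arr.dtype == np.uint32:
        return 32
    raise ValueError(f"unsupported integer dtype {arr.dtype} in {path}")


def read_image(path: str | Path, *, wavelength_nm: float = 1.0) -> IntensityImage:
    """Read a single-channel TIFF/PNG as an :class:`IntensityImage`.

    Bit depth is inferred from the stored dtype and recorded.  Float
    TIFFs (e.g. unquantized simulations) are read with a nominal 16-bit
    depth.  Multi-channel images are rejected, not converted.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in _TIFF_SUFFIXES:
        arr = tifffile.imread(path)
    elif suffix in _PNG_SUFFIXES:
        arr = iio.imread(path)
    else:
        raise ValueError(f"unsupported image format {suffix!r} ({path})")
    if arr.ndim != 2:
        raise ValueError(
            f"{path} has {arr.shape[-1] if arr.ndim == 3 else '?'} channels; "
            "only single-channel images are supported"
        )
    if np.issubdtype(arr.dtype, np.floating):
        bit_depth = 16
    else:
        bit_depth = _bit_depth_of(arr, path)
    return IntensityImage(arr, bit_depth=bit_depth, wavelength_nm=wavelength_nm)


def write_image(img: IntensityImage, path: str | Path) -> None:
    """Write an intensity image losslessly (integer) to TIFF/PNG.

    Float pixel arrays (unquantized simulations) are written as 32-bit
    float TIFF; PNG requires integer data.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    arr = img.pixels
    if np.issubdtype(arr.dtype, np.floating):
        if suffix not in _TIFF_SUFFIXES:
            raise ValueError("float images can only be written as TIFF")
        tifffile.imwrite(path, arr.astype(np.float32))
        return
    dtype = np.uint8 if img.bit_depth <= 8 else np.uint16
    arr = arr.astype(dtype)
    if suffix in _TIFF_SUFFIXES:
        tifffile.imwrite(path, arr)
    elif suffix in _PNG_SUFFIXES:
        iio.imwrite(path, arr)
    else:
        raise ValueError(f"unsupported image format {suffix!r} ({path})")


def write_thickness_tiff(maps: ThicknessMaps, directory: str | Path) -> list[Path]:
    """Write each tissue map as a 32-bit float TIFF (cm units)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, t in enumerate(maps.tissue_labels):
        p = directory / f"thickness_{t}.tif"
        tifffile.imwrite(p, maps.values[i].astype(np.float32))
        paths.append(p)
    return paths


def read_thickness_tiff(
    directory: str | Path, tissue_labels: list[str]
) -> ThicknessMaps:
    """Read per-tissue float TIFFs written by :func:`write_thickness_tiff`."""
    directory = Path(directory)
    planes = [
        tifffile.imread(directory / f"thickness_{t}.tif").astype(float)
        for t in tissue_labels
    ]
    values = np.stack(planes)
    valid = np.all(np.isfinite(values), axis=0)
    values[:, ~valid] = np.nan
    return ThicknessMaps(values, tuple(tissue_labels), valid)


def write_matrix_csv(matrix: AttenuationMatrix, path: str | Path) -> None:
    rows = []
    for i, wl in enumerate(matrix.wavelengths_nm):
        for j, t in enumerate(matrix.tissue_labels):
            sd = (
                float(matrix.uncertainties[i, j])
                if matrix.uncertainties is not None
                else np.nan
            )
            rows.append(
                {
                    "wavelength_nm": wl,
                    "tissue": t,
                    "mu_cm_inv": float(matrix.values[i, j]),
                    "sd": sd,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_matrix_csv(path: str | Path) -> AttenuationMatrix:
    """Read a (wavelength_nm, tissue, mu_cm_inv[, sd]) CSV table.

    Row order fixes the wavelength order; within-row column order fixes
    the tissue order (first appearance wins for both).
    """
    df = pd.read_csv(path)
    required = {"wavelength_nm", "tissue", "mu_cm_inv"}
    if not required.issubset(df.columns):
        raise ValueError(f"coefficient table needs columns {sorted(required)}")
    wavelengths = list(dict.fromkeys(float(w) for w in df["wavelength_nm"]))
    tissues = list(dict.fromkeys(str(t) for t in df["tissue"]))
    have_sd = "sd" in df.columns and df["sd"].notna().all()
    entries = {}
    for _, row in df.iterrows():
        key = (float(row["wavelength_nm"]), str(row["tissue"]))
        if key in entries:
            raise ValueError(f"duplicate coefficient row for {key}")
        entries[key] = (
            (float(row["mu_cm_inv"]), float(row["sd"]))
            if have_sd
            else float(row["mu_cm_inv"])
        )
    return build_attenuation_matrix(entries, wavelengths, tissues)


def matrix_to_json(
    matrix: AttenuationMatrix,
    path: str | Path,
    diagnostics: MatrixDiagnostics | None = None,
) -> None:
    payload = {
        "wavelengths_nm": list(matrix.wavelengths_nm),
        "tissue_labels": list(matrix.tissue_labels),
        "values_cm_inv": matrix.values.tolist(),
        "uncertainties": (
            matrix.uncertainties.tolist()
            if matrix.uncertainties is not None
            else None
        ),
    }
    if diagnostics is not None:
        payload["diagnostics"] = asdict(diagnostics)
    Path(path).write_text(json.dumps(payload, indent=2))


def matrix_from_json(path: str | Path) -> AttenuationMatrix:
    data = json.loads(Path(path).read_text())
    return AttenuationMatrix(
        np.asarray(data["values_cm_inv"]),
        tuple(data["wavelengths_nm"]),
        tuple(data["tissue_labels"]),
        np.asarray(data["uncertainties"]) if data.get("uncertainties") else None,
    )


def write_manifest(path: str | Path, payload: dict) -> None:
    """Write a reproducibility manifest (inputs, parameters, seed)."""
    from . import __version__

    payload = {"package": "biodecomp", "version": __version__, **payload}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def spec_to_dict(spec: PhantomSpec) -> dict:
    d = asdict(spec)
    d["regions"] = [asdict(r) for r in spec.regions]
    d["frame_shape"] = list(spec.frame_shape)
    d["overlay_layers"] = [[t, th] for t, th in spec.overlay_layers]
    return d


def spec_from_dict(d: dict) -> PhantomSpec:
    d = dict(d)
    d["regions"] = tuple(
        Region(
            r["tissue_label"],
            r["shape"],
            tuple(r["geometry"]),
            r["thickness_cm"],
        )
        for r in d.get("regions", ())
    )
    d["overlay_layers"] = tuple(
        (t, float(th)) for t, th in d.get("overlay_layers", ())
    )
    d["frame_shape"] = tuple(d.get("frame_shape", (256, 256)))
    if "tissue_labels" in d:
        d["tissue_labels"] = tuple(d["tissue_labels"])
    if d.get("beam_center") is not None:
        d["beam_center"] = tuple(d["beam_center"])
    return PhantomSpec(**d)


def spec_from_toml(path: str | Path) -> PhantomSpec:
    """Read a phantom scene description from a TOML config."""
    import tomllib

    with open(path, "rb") as f:
        data = tomllib.load(f)
    return spec_from_dict(data.get("phantom", data))
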