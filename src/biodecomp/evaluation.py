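"""Accuracy assessment of decomposed tissue maps.

Two complementary views: binary-mask agreement (how well the recovered
tissue area matches the reference area) and continuous recovery error
against ground-truth thickness maps when they exist (phantoms).

Mask agreement is reported both as the asymmetric matching-area ratio
|pred ∩ ref| / |ref| and as the symmetric Sorensen-Dice coefficient
2|A∩B| / (|A| + |B|); the two coincide only when the areas match, so
both are always reported and labelled distinctly.

Masks are obtained by thresholding a thickness map — Otsu by default,
an automatic, reproducible surrogate for manual boundary tracing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .core import ThicknessMaps

__all__ = [
    "SegmentationMask",
    "AccuracyReport",
    "threshold_mask",
    "overlap_ratio",
    "dice",
    "recovery_metrics",
    "evaluate_decomposition",
]


@dataclass
class SegmentationMask:
    """Binary mask of one tissue's area."""

    pixels: np.ndarray
    tissue_label: str
    source: str  # "ground_truth" | "decomposed"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be 2-D")
        if self.source not in ("ground_truth", "decomposed"):
            raise ValueError(f"unknown mask source {self.source!r}")

    @property
    def area(self) -> int:
        return int(self.pixels.sum())


@dataclass
class AccuracyReport:
    """Per-tissue accuracy table.

    ``per_tissue[label]`` holds overlap_ratio, dice, area_pred,
    area_ref, and — when ground-truth maps were supplied — rmse_cm,
    max_abs_err_cm and bias_cm.
    """

    per_tissue: dict[str, dict[str, float]]

    def to_text(self) -> str:
        """Plain-text table: tissue x metric, percentages for overlaps."""
        lines = [f"{'tissue':<10} {'overlap%':>9} {'dice%':>8} {'rmse_cm':>10}"]
        for t, m in self.per_tissue.items():
            rmse = m.get("rmse_cm")
            lines.append(
                f"{t:<10} {100 * m['overlap_ratio']:>8.1f}% "
                f"{100 * m['dice']:>6.1f}% "
                + (f"{rmse:>10.4g}" if rmse is not None else f"{'-':>10}")
            )
        return "\n".join(lines)


def threshold_mask(
    thickness_map: np.ndarray,
    tissue_label: str,
    *,
    method: str = "otsu",
    fixed_value: float | None = None,
    source: str = "decomposed",
) -> SegmentationMask:
    """Binary mask of pixels whose thickness exceeds a threshold.

    ``otsu`` picks the threshold maximising between-class variance of
    the finite map values; a constant map has no such split and raises
    with a hint to use ``fixed`` mode.  No-data (NaN) pixels are always
    outside the mask.
    """
    m = np.asarray(thickness_map, dtype=float)
    finite = np.isfinite(m)
    if method == "fixed":
        if fixed_value is None:
            raise ValueError("fixed mode requires fixed_value")
        thr = float(fixed_value)
    elif method == "otsu":
        vals = m[finite]
        if np.unique(vals).size < 2:
            raise ValueError(
                "map is constant; Otsu thresholding needs >= 2 distinct "
                "values — use method='fixed' with an explicit threshold"
            )
        thr = float(threshold_otsu(vals))
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return SegmentationMask(finite & (m > thr), tissue_label, source)


def overlap_ratio(pred: SegmentationMask, ref: SegmentationMask) -> float:
    """Matching-area ratio |pred ∩ ref| / |ref| (asymmetric)."""
    if pred.pixels.shape != ref.pixels.shape:
        raise ValueError("mask shapes differ")
    denom = ref.area
    if denom == 0:
        raise ValueError("reference mask is empty; overlap ratio undefined")
    return float((pred.pixels & ref.pixels).sum() / denom)


def dice(pred: SegmentationMask, ref: SegmentationMask) -> float:
    """Sorensen-Dice coefficient 2|A∩B| / (|A| + |B|); both-empty is 1."""
    if pred.pixels.shape != ref.pixels.shape:
        raise ValueError("mask shapes differ")
    total = pred.area + ref.area
    if total == 0:
        return 1.0
    return float(2.0 * (pred.pixels & ref.pixels).sum() / total)


def recovery_metrics(
    pred: ThicknessMaps, truth: ThicknessMaps
) -> dict[str, dict[str, float]]:
    """Per-tissue rmse, max abs error and bias (cm) over the valid mask."""
    if pred.tissue_labels != truth.tissue_labels:
        raise ValueError(
            f"tissue order mismatch: {pred.tissue_labels} vs {truth.tissue_labels}"
        )
    if pred.frame_shape != truth.frame_shape:
        raise ValueError("frame shapes differ")
    mask = pred.valid_mask & truth.valid_mask
    if not mask.any():
        raise ValueError("no jointly valid pixels")
    out: dict[str, dict[str, float]] = {}
    for i, t in enumerate(pred.tissue_labels):
        err = pred.values[i][mask] - truth.values[i][mask]
        out[t] = {
            "rmse_cm": float(np.sqrt(np.mean(err**2))),
            "max_abs_err_cm": float(np.max(np.abs(err))),
            "bias_cm": float(np.mean(err)),
        }
    return out


def evaluate_decomposition(
    pred: ThicknessMaps,
    truth: ThicknessMaps,
    *,
    method: str = "otsu",
    fixed_value: float | None = None,
) -> AccuracyReport:
    """Full accuracy report of a decomposition against ground truth.

    Both maps are thresholded with the same method, so area agreement
    measures the decomposition rather than the thresholding convention.
    """
    cont = recovery_metrics(pred, truth)
    report: dict[str, dict[str, float]] = {}
    for i, t in enumerate(pred.tissue_labels):
        ref_mask = threshold_mask(
            truth.values[i], t, method=method, fixed_value=fixed_value,
            source="ground_truth",
        )
        pred_mask = threshold_mask(
            pred.values[i], t, method=method, fixed_value=fixed_value,
            source="decomposed",
        )
        report[t] = {
            "overlap_ratio": overlap_ratio(pred_mask, ref_mask),
            "dice": dice(pred_mask, ref_mask),
            "area_pred": float(pred_mask.area),
            "area_ref": float(ref_mask.area),
            **cont[t],
        }
    return AccuracyReport(report)
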