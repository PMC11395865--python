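"""Compartment segmentation and volumetry on wash-out maps and rCBV maps.

Wash-out (difference > +threshold) and wash-in (< −threshold) compartments
are segmented deterministically with a noise-scaled threshold and a
connected-component size filter — a reproducible stand-in for interactive
slice-by-slice level tracing.  Hyperperfusion is segmented from an rCBV map
at a fixed relative threshold (default 1.2) with a minimum in-plane
cross-sectional area filter (default 0.25 cm²).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume import Volume
from .washoutmap import DifferenceVolume

__all__ = [
    "CompartmentMasks",
    "VolumetryResult",
    "PerfusionResult",
    "robust_noise_scale",
    "segment_compartments",
    "measure",
    "segment_perfusion",
]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class CompartmentMasks:
    washout_mask: np.ndarray
    washin_mask: np.ndarray
    threshold: float
    min_component_mm3: float
    spacing: tuple[float, float, float]
    roi: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.washout_mask = np.asarray(self.washout_mask, dtype=bool)
        self.washin_mask = np.asarray(self.washin_mask, dtype=bool)
        if (self.washout_mask & self.washin_mask).any():
            raise ValueError("wash-out and wash-in masks overlap")


@dataclass
class VolumetryResult:
    washout_mm3: float
    washin_mm3: float
    washout_ratio: float  # NaN when undefined (both compartments empty)
    ratio_defined: bool
    lesion_count: int
    lesions: pd.DataFrame  # per-lesion: id, compartment, centroid mm, volume mm3
    perfusion_mm3: float = float("nan")


@dataclass
class PerfusionResult:
    mask: np.ndarray
    volume_mm3: float
    max_rcbv: float  # NaN when mask empty
    threshold: float
    min_area_cm2: float


def robust_noise_scale(diff: DifferenceVolume) -> float:
    """Robust σ of the difference over valid foreground (1.4826·MAD).

    Lesions occupy a small fraction of foreground, so the median absolute
    deviation estimates the background noise scale of the subtraction.
    """
    vals = diff.data[diff.valid_mask]
    if vals.size == 0:
        return 0.0
    med = np.median(vals)
    return float(1.4826 * np.median(np.abs(vals - med)))


def _filter_components(mask: np.ndarray, min_mm3: float, voxel_mm3: float) -> np.ndarray:
    if min_mm3 <= 0 or not mask.any():
        return mask
    labels, nlab = ndimage.label(mask, structure=_STRUCT_26)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, nlab + 1))
    keep = np.flatnonzero(sizes * voxel_mm3 >= min_mm3) + 1
    return np.isin(labels, keep)


def segment_compartments(
    diff: DifferenceVolume,
    threshold: float | None = None,
    k: float = 3.0,
    threshold_floor: float = 0.0,
    min_component_mm3: float = 50.0,
    roi: np.ndarray | None = None,
) -> CompartmentMasks:
    """Threshold the difference into wash-out (+) and wash-in (−) compartments.

    ``threshold`` defaults to ``max(k·σ_bg, threshold_floor)`` with σ_bg the
    robust noise scale of the difference (see :func:`robust_noise_scale`);
    the floor guards the degenerate noise-free case where σ_bg → 0.
    Components smaller than ``min_component_mm3`` (26-connected) are dropped.
    """
    if roi is not None:
        roi = np.asarray(roi, dtype=bool)
        if not roi.any():
            raise ValueError("ROI is empty")
    if threshold is None:
        threshold = max(k * robust_noise_scale(diff), threshold_floor)
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    domain = diff.valid_mask if roi is None else (diff.valid_mask & roi)
    voxel_mm3 = float(np.prod(diff.reference.spacing))
    washout = (diff.data > threshold) & domain
    washin = (diff.data < -threshold) & domain
    washout = _filter_components(washout, min_component_mm3, voxel_mm3)
    washin = _filter_components(washin, min_component_mm3, voxel_mm3)
    return CompartmentMasks(
        washout_mask=washout, washin_mask=washin, threshold=float(threshold),
        min_component_mm3=float(min_component_mm3),
        spacing=diff.reference.spacing, roi=roi,
    )


def measure(
    masks: CompartmentMasks,
    spacing: tuple[float, float, float] | None = None,
    perfusion: "PerfusionResult | None" = None,
) -> VolumetryResult:
    """Volumes (voxel count × voxel volume, exact) and the wash-out ratio.

    wash-out ratio = WO / (WO + WI); undefined (NaN, flagged) when both
    compartments are empty.
    """
    spacing = spacing or masks.spacing
    voxel_mm3 = float(np.prod(spacing))
    wo = float(masks.washout_mask.sum()) * voxel_mm3
    wi = float(masks.washin_mask.sum()) * voxel_mm3
    defined = (wo + wi) > 0
    ratio = wo / (wo + wi) if defined else float("nan")

    rows = []
    affine_sp = np.asarray(spacing)
    for name, mask in (("washout", masks.washout_mask), ("washin", masks.washin_mask)):
        labels, nlab = ndimage.label(mask, structure=_STRUCT_26)
        if nlab == 0:
            continue
        centroids = ndimage.center_of_mass(mask, labels, index=np.arange(1, nlab + 1))
        sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                                   index=np.arange(1, nlab + 1))
        for li, (com, sz) in enumerate(zip(np.atleast_2d(centroids), sizes), start=1):
            rows.append({
                "lesion_id": f"{name}_{li}",
                "compartment": name,
                "centroid_x_mm": com[0] * affine_sp[0],
                "centroid_y_mm": com[1] * affine_sp[1],
                "centroid_z_mm": com[2] * affine_sp[2],
                "volume_mm3": float(sz) * voxel_mm3,
            })
    lesions = pd.DataFrame(
        rows, columns=["lesion_id", "compartment", "centroid_x_mm", "centroid_y_mm",
                       "centroid_z_mm", "volume_mm3"],
    )
    return VolumetryResult(
        washout_mm3=wo, washin_mm3=wi, washout_ratio=ratio, ratio_defined=defined,
        lesion_count=int(len(lesions)), lesions=lesions,
        perfusion_mm3=perfusion.volume_mm3 if perfusion is not None else float("nan"),
    )


def segment_perfusion(
    rcbv: Volume,
    rcbv_threshold: float = 1.2,
    min_area_cm2: float = 0.25,
    enhancement_mask: np.ndarray | None = None,
) -> PerfusionResult:
    """Segment hyperperfusion: rCBV > threshold, small components removed.

    A component is retained only if its largest in-plane (axial slice)
    cross-sectional area reaches ``min_area_cm2`` — the area criterion is 2-D,
    evaluated slice by slice.  Reports the retained volume and the maximum
    rCBV inside the retained mask (per-lesion rCBV summary).
    """
    data = np.asarray(rcbv.data, dtype=np.float64)
    mask = data > rcbv_threshold
    if enhancement_mask is not None:
        mask &= np.asarray(enhancement_mask, dtype=bool)
    pixel_area_cm2 = (rcbv.spacing[0] * rcbv.spacing[1]) / 100.0  # mm² -> cm²
    if mask.any() and min_area_cm2 > 0:
        labels, nlab = ndimage.label(mask, structure=_STRUCT_26)
        keep = []
        for lab in range(1, nlab + 1):
            comp = labels == lab
            max_area = comp.sum(axis=(0, 1)).max() * pixel_area_cm2
            if max_area > min_area_cm2:  # strict: "area > 0.25 cm²"
                keep.append(lab)
        mask = np.isin(labels, keep) if keep else np.zeros_like(mask)
    volume = float(mask.sum()) * float(np.prod(rcbv.spacing))
    max_rcbv = float(data[mask].max()) if mask.any() else float("nan")
    return PerfusionResult(
        mask=mask, volume_mm3=volume, max_rcbv=max_rcbv,
        threshold=float(rcbv_threshold), min_area_cm2=float(min_area_cm2),
    )
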