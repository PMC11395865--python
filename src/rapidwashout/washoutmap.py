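"""Subtraction of the registered series and red/green map encoding.

The signed difference (early minus late, both mean-normalized) is the core
quantity: positive values mean contrast wash-out between the two
acquisitions (active tumor tissue / vessels, rendered red), negative values
wash-in (slow-enhancing scar / necrosis, rendered green).

Display encoding: the observed value range is halved into a symmetric clip
range ±C, and values are mapped linearly to 8 bits with 0 centred exactly at
127 of 255.  The mapping uses a uniform step of 2C/255 with round-half-up,
which pins d=0 -> 127, d=+C -> 255, d=-C -> 0 and bounds the decode∘encode
error by C/255 (half a quantization step) at every voxel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .volume import RgbVolume, Volume

__all__ = ["DifferenceVolume", "WashoutMap", "subtract", "encode", "decode"]


@dataclass
class DifferenceVolume:
    """Signed early-minus-late difference on the early grid."""

    data: np.ndarray
    valid_mask: np.ndarray
    reference: Volume  # carries the grid geometry
    clip_range: float | None = None  # symmetric display clip ±C; set by encode

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.data.shape != self.valid_mask.shape:
            raise ValueError("difference data and valid_mask shapes differ")
        if self.clip_range is not None and self.clip_range <= 0:
            raise ValueError("clip_range must be positive")

    def negated(self) -> "DifferenceVolume":
        return DifferenceVolume(-self.data, self.valid_mask.copy(), self.reference,
                                self.clip_range)


@dataclass
class WashoutMap:
    difference: DifferenceVolume
    gray: Volume       # encoded 0..255
    rgb: RgbVolume
    provenance: dict[str, Any] = field(default_factory=dict)


def subtract(
    early: Volume,
    late_registered: Volume,
    foreground: np.ndarray | None = None,
) -> DifferenceVolume:
    """Voxelwise early − late on the (shared) early grid.

    Both inputs must already be mean-normalized and resampled to the same
    grid.  NaN voxels (resampling fill outside the late field of view) are
    excluded from ``valid_mask``; the difference is zero there.
    Antisymmetric: ``subtract(a, b).data == -subtract(b, a).data``.
    """
    if not early.same_grid_as(late_registered):
        raise ValueError("early and late volumes are not on the same grid; register first")
    e = np.asarray(early.data, dtype=np.float64)
    l = np.asarray(late_registered.data, dtype=np.float64)
    valid = np.isfinite(e) & np.isfinite(l)
    if foreground is not None:
        valid &= np.asarray(foreground, dtype=bool)
    diff = np.zeros_like(e)
    diff[valid] = e[valid] - l[valid]
    return DifferenceVolume(data=diff, valid_mask=valid, reference=early)


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def _encode_gray(d: np.ndarray, C: float) -> np.ndarray:
    g = _round_half_up(127.0 + d * (255.0 / (2.0 * C)))
    return np.clip(g, 0, 255).astype(np.uint8)


def encode(
    diff: DifferenceVolume,
    clip_range: float | None = None,
    clip_percentile: float | None = None,
    underlay: Volume | None = None,
    underlay_max: int = 160,
    provenance: dict[str, Any] | None = None,
) -> WashoutMap:
    """Encode a difference volume as 8-bit grayscale and red/green RGB maps.

    Parameters
    ----------
    diff
        Signed difference volume.
    clip_range
        Symmetric clip ±C.  Default: half the observed peak-to-peak range of
        the valid difference values ("value range halved").
    clip_percentile
        Robustness option: derive the range from the given upper percentile
        of |d| (e.g. 99.5) instead of the raw extremes.
    underlay
        Optional anatomy volume (same grid) rendered as a dimmed grayscale
        beneath the color coding, so red/green appear in anatomical context.
        Without it the neutral level is a flat mid-gray 127.
    """
    d = diff.data
    valid = diff.valid_mask
    vals = d[valid] if valid.any() else d.ravel()
    uniform = vals.size == 0 or np.ptp(vals) == 0
    if clip_range is not None:
        C = float(clip_range)
    elif uniform:
        warnings.warn("difference volume is uniform; emitting a flat 127 map")
        C = 1.0
    elif clip_percentile is not None:
        C = float(np.percentile(np.abs(vals), clip_percentile))
        C = C if C > 0 else 1.0
    else:
        C = float(np.ptp(vals)) / 2.0
    diff.clip_range = C

    gray_u8 = _encode_gray(d, C)
    gray_u8[~valid] = 127

    m = np.clip(np.abs(d) / C, 0.0, 1.0)
    if underlay is not None:
        if underlay.data.shape != d.shape:
            raise ValueError("underlay grid does not match difference grid")
        u = np.asarray(underlay.data, dtype=np.float64)
        lo, hi = np.percentile(u[valid], [1, 99]) if valid.any() else (u.min(), u.max())
        neutral = np.clip((u - lo) / max(hi - lo, 1e-12), 0, 1) * underlay_max
    else:
        neutral = np.full(d.shape, 127.0)
    active = _round_half_up(neutral + (255.0 - neutral) * m)
    passive = _round_half_up(neutral * (1.0 - m))
    pos = d > 0
    neg = d < 0
    r = np.where(pos, active, np.where(neg, passive, _round_half_up(neutral)))
    g = np.where(neg, active, np.where(pos, passive, _round_half_up(neutral)))
    b = np.where(pos | neg, passive, _round_half_up(neutral))
    rgb = np.stack([r, g, b], axis=-1)
    rgb[~valid] = (0, 0, 0)
    ref = diff.reference
    prov = dict(provenance or {})
    prov.update({"clip_range": C, "clip_percentile": clip_percentile,
                 "underlay": underlay is not None})
    return WashoutMap(
        difference=diff,
        gray=Volume(gray_u8, ref.spacing, ref.origin, ref.orientation.copy(),
                    {**ref.meta, "encoding": "washout-gray-127"}),
        rgb=RgbVolume(np.clip(rgb, 0, 255), ref.spacing, ref.origin,
                      ref.orientation.copy(), {**ref.meta, "encoding": "washout-rgb"}),
        provenance=prov,
    )


def decode(wmap: WashoutMap) -> DifferenceVolume:
    """Invert the grayscale encoding back to difference units.

    ``|decode(encode(d)) − clip(d, −C, +C)| ≤ C/255`` at every valid voxel.
    """
    C = wmap.difference.clip_range
    if C is None:
        raise ValueError("clip_range missing; map was not produced by encode()")
    g = np.asarray(wmap.gray.data, dtype=np.float64)
    d = (g - 127.0) * (2.0 * C / 255.0)
    return DifferenceVolume(
        data=d, valid_mask=wmap.difference.valid_mask.copy(),
        reference=wmap.difference.reference, clip_range=C,
    )
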