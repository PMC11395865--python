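"""End-to-end orchestration: read → bias-correct → normalize → register →
subtract → encode → segment → measure → report.

`run_volumes` executes the pipeline on in-memory volumes and returns every
intermediate product plus a provenance manifest; `run_case` adds the file
I/O around it (DICOM/NIfTI inputs, NIfTI + DICOM + CSV + JSON outputs).
All settings live in :class:`RunConfig`, which is serialized verbatim into
the manifest so a run can be reproduced from its manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import __version__
from .io import read_dicom_series, read_nifti, write_gray_dicom, write_nifti, write_rgb_dicom
from .preprocess import correct_bias, foreground_mask, normalize_means
from .register import RegistrationResult, RigidTransform, apply_transform, estimate_rigid, save_transform
from .volume import Volume
from .volumetry import (PerfusionResult, VolumetryResult, measure,
                        segment_compartments, segment_perfusion)
from .washoutmap import WashoutMap, decode, encode, subtract

__all__ = ["RunConfig", "CaseResult", "PipelineError", "run_volumes", "run_case",
           "shortened_protocol_check", "load_volume"]


class PipelineError(RuntimeError):
    """Stage-labelled pipeline failure."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RunConfig:
    """All pipeline settings; defaults follow the published protocol values
    where one exists (bias shrink 3, rCBV threshold 1.2, minimum enhancing
    area 0.25 cm²)."""

    early: str = ""
    late: str = ""
    rcbv: str | None = None
    roi: str | None = None
    native: str | None = None
    output_dir: str = "washout_out"

    bias_enabled: bool = True
    bias_shrink: int = 3

    register_enabled: bool = True
    register_cost: str = "mi"          # 'mi' (mutual information) or 'corr'
    register_levels: int = 3
    register_multistart: bool = True

    encode_clip_percentile: float | None = None  # None: half peak-to-peak range
    encode_underlay: bool = True

    seg_threshold: float | None = None  # None: k·σ_bg with floor below
    seg_k: float = 3.0
    seg_threshold_floor_frac: float = 0.02  # × normalization target mean
    seg_min_component_mm3: float = 50.0
    seg_roi_erosion_mm: float = 4.0     # shrink foreground ROI away from the scalp edge

    rcbv_threshold: float = 1.2
    rcbv_min_area_cm2: float = 0.25

    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)


@dataclass
class CaseResult:
    config: RunConfig
    early_fg: np.ndarray
    scale_factors: tuple[float, float]
    registration: RegistrationResult | None
    wmap: WashoutMap
    volumetry: VolumetryResult
    perfusion: PerfusionResult | None
    manifest: dict
    washout_mask: np.ndarray = field(default=None)  # convenience aliases
    washin_mask: np.ndarray = field(default=None)


def _sha256(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()


def load_volume(path: str | Path) -> Volume:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.is_dir():
        return read_dicom_series(path)
    return read_nifti(path)


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(name, str(exc)) from exc
    return wrap


def run_volumes(
    early: Volume,
    late: Volume,
    rcbv: Volume | None = None,
    roi: np.ndarray | None = None,
    config: RunConfig | None = None,
) -> CaseResult:
    """Run the full pipeline on in-memory volumes."""
    cfg = config or RunConfig()
    timings: dict[str, float] = {}
    manifest: dict = {"software": {"rapidwashout": __version__},
                      "config": cfg.to_dict(), "flags": {}}

    def timed(stage, fn, *args, **kwargs):
        t0 = time.perf_counter()
        out = _stage(stage)(fn, *args, **kwargs)
        timings[stage] = round(time.perf_counter() - t0, 4)
        return out

    # bias correction (independently per series, before normalization)
    if cfg.bias_enabled:
        bc_e = timed("bias_early", correct_bias, early, cfg.bias_shrink)
        bc_l = timed("bias_late", correct_bias, late, cfg.bias_shrink)
        early_c, late_c = bc_e.corrected, bc_l.corrected
        manifest["flags"]["bias_constant_input"] = bc_e.constant_input or bc_l.constant_input
    else:
        early_c, late_c = early, late

    fg_early = timed("foreground", foreground_mask, early_c)
    fg_late = timed("foreground", foreground_mask, late_c)

    early_n, late_n, scales = timed("normalize", normalize_means,
                                    early_c, late_c, fg_early, fg_late)
    target_mean = float(np.mean(early_n.data[fg_early]))
    manifest["normalization"] = {"scale_early": scales[0], "scale_late": scales[1],
                                 "target_mean": target_mean}

    # registration of the late series onto the early grid
    registration = None
    if cfg.register_enabled:
        if late_n.same_grid_as(early_n):
            union = fg_early | fg_late
        else:
            fg_late_on_early = apply_transform(
                late_n.with_data(fg_late.astype(np.uint8)), RigidTransform.identity(),
                early_n, interpolation="nearest", fill=0).data.astype(bool)
            union = fg_early | fg_late_on_early
        registration = timed("register", estimate_rigid, early_n, late_n,
                             mask=union, cost=cfg.register_cost,
                             levels=cfg.register_levels,
                             multistart=cfg.register_multistart)
        manifest["registration"] = {
            "matrix": registration.transform.as_matrix.tolist(),
            "cost": registration.cost,
            "identity_cost": registration.identity_cost,
            "success": registration.success,
            "message": registration.message,
        }
        manifest["flags"]["registration_fallback"] = not registration.success
        late_r = timed("resample", apply_transform, late_n,
                       registration.transform, early_n)
    else:
        late_r = late_n if late_n.same_grid_as(early_n) else timed(
            "resample", apply_transform, late_n, RigidTransform.identity(), early_n)

    diff = timed("subtract", subtract, early_n, late_r, fg_early)
    wmap = timed("encode", encode, diff,
                 clip_percentile=cfg.encode_clip_percentile,
                 underlay=early_n if cfg.encode_underlay else None)
    manifest["encode"] = {"clip_range": diff.clip_range,
                          "clip_percentile": cfg.encode_clip_percentile}

    if roi is None and cfg.seg_roi_erosion_mm > 0:
        it = max(1, int(round(cfg.seg_roi_erosion_mm / min(early_n.spacing))))
        roi = ndimage.binary_erosion(fg_early, iterations=it)
    floor = cfg.seg_threshold_floor_frac * target_mean
    masks = timed("segment", segment_compartments, diff,
                  threshold=cfg.seg_threshold, k=cfg.seg_k, threshold_floor=floor,
                  min_component_mm3=cfg.seg_min_component_mm3, roi=roi)
    manifest["segmentation"] = {"threshold": masks.threshold,
                                "threshold_floor": floor,
                                "min_component_mm3": masks.min_component_mm3}

    perfusion = None
    if rcbv is not None:
        perfusion = timed("perfusion", segment_perfusion, rcbv,
                          rcbv_threshold=cfg.rcbv_threshold,
                          min_area_cm2=cfg.rcbv_min_area_cm2)
    vol = timed("measure", measure, masks, perfusion=perfusion)
    manifest["volumetry"] = {
        "washout_mm3": vol.washout_mm3, "washin_mm3": vol.washin_mm3,
        "washout_ratio": None if not vol.ratio_defined else vol.washout_ratio,
        "ratio_defined": vol.ratio_defined, "lesion_count": vol.lesion_count,
        "perfusion_mm3": None if perfusion is None else perfusion.volume_mm3,
        "max_rcbv": None if perfusion is None or np.isnan(perfusion.max_rcbv)
        else perfusion.max_rcbv,
    }
    manifest["timings_s"] = timings
    manifest["checksums"] = {
        "difference": _sha256(diff.data),
        "gray": _sha256(wmap.gray.data),
        "rgb": _sha256(wmap.rgb.data),
        "washout_mask": _sha256(masks.washout_mask),
        "washin_mask": _sha256(masks.washin_mask),
    }
    return CaseResult(
        config=cfg, early_fg=fg_early, scale_factors=scales,
        registration=registration, wmap=wmap, volumetry=vol, perfusion=perfusion,
        manifest=manifest, washout_mask=masks.washout_mask,
        washin_mask=masks.washin_mask,
    )


def run_case(config: RunConfig) -> CaseResult:
    """Run the pipeline from files and write the full output bundle."""
    early = _stage("read_early")(load_volume, config.early)
    late = _stage("read_late")(load_volume, config.late)
    rcbv = _stage("read_rcbv")(load_volume, config.rcbv) if config.rcbv else None
    roi = None
    if config.roi:
        roi_vol = _stage("read_roi")(load_volume, config.roi)
        roi = np.asarray(roi_vol.data) > 0

    result = run_volumes(early, late, rcbv=rcbv, roi=roi, config=config)

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    ref = result.wmap.difference.reference
    write_nifti(ref.with_data(result.wmap.difference.data.astype(np.float32)),
                out / "difference.nii.gz")
    write_nifti(result.wmap.gray, out / "washout_gray.nii.gz")
    write_nifti(ref.with_data(result.washout_mask.astype(np.uint8)),
                out / "washout_mask.nii.gz")
    write_nifti(ref.with_data(result.washin_mask.astype(np.uint8)),
                out / "washin_mask.nii.gz")
    write_gray_dicom(result.wmap.gray, ref, out / "gray_dicom")
    write_rgb_dicom(result.wmap.rgb, ref, out / "rgb_dicom")
    if result.registration is not None:
        save_transform(result.registration.transform, out / "transform.txt")
    if result.perfusion is not None:
        write_nifti(ref.with_data(result.perfusion.mask.astype(np.uint8)),
                    out / "perfusion_mask.nii.gz")
    result.volumetry.lesions.to_csv(out / "lesions.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, default=float)
    return result


def shortened_protocol_check(
    early: Volume,
    native: Volume | None = None,
    score_threshold: float = 5.0,
) -> tuple[bool, str, float | None]:
    """Advisory check mirroring the clinical protocol-shortening rule.

    When no contrast enhancement is seen on the first post-contrast series,
    the remaining protocol is clinically shortened.  Given the pre-contrast
    (native) series, this computes an enhancement score — the 99th percentile
    of the mean-normalized early−native difference over the foreground, in
    units of the robust noise scale — and recommends skipping when it falls
    below ``score_threshold``.  Advisory only; the pipeline never auto-aborts.

    Returns ``(proceed, reason, score)``.
    """
    if native is None:
        return True, "native series not provided; enhancement not evaluated", None
    fg = foreground_mask(early)
    early_n, native_n, _ = normalize_means(early, native, fg, foreground_mask(native))
    if not early_n.same_grid_as(native_n):
        native_n = apply_transform(native_n, RigidTransform.identity(), early_n)
    d = np.asarray(early_n.data - native_n.data)[fg]
    d = d[np.isfinite(d)]
    sigma = 1.4826 * float(np.median(np.abs(d - np.median(d))))
    p99 = float(np.percentile(d, 99))
    if sigma == 0:
        score = 0.0 if p99 <= 0 else float("inf")
    else:
        score = p99 / sigma
    if score >= score_threshold:
        return True, f"enhancement detected (score {score:.1f})", score
    return False, f"no relevant enhancement (score {score:.1f}); consider shortening", score
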