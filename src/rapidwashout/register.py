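"""Rigid (6-DOF) registration of the late series onto the early series.

The late acquisition is registered TO the early one (early is the fixed
reference) so that subtraction happens on the early grid.  The similarity
cost is Mattes mutual information by default (robust to residual bias field
on same-modality pairs; correlation is offered as an alternative), optimized
coarse-to-fine over a 3-level pyramid with a deterministic multi-start at the
coarsest level.  All randomness is avoided (dense metric sampling), so a
given input pair always yields the same transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .volume import Volume, from_sitk, to_sitk

__all__ = [
    "RigidTransform",
    "RegistrationResult",
    "RegistrationError",
    "estimate_rigid",
    "apply_transform",
    "save_transform",
    "load_transform",
]

_RAS_LPS = np.diag([-1.0, -1.0, 1.0])


class RegistrationError(RuntimeError):
    """Raised when registration preconditions fail (e.g. empty overlap)."""


def _rot_xyz(rx: float, ry: float, rz: float) -> np.ndarray:
    """Rotation matrix for extrinsic rotations about x, then y, then z (degrees)."""
    rx, ry, rz = np.deg2rad([rx, ry, rz])
    cx, sx, cy, sy, cz, sz = np.cos(rx), np.sin(rx), np.cos(ry), np.sin(ry), np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


@dataclass
class RigidTransform:
    """6-DOF mapping of fixed-space world points (RAS mm) into moving space.

    ``T(x) = R (x - c) + c + t`` — the resampling convention: the value of the
    registered moving image at fixed-grid point ``x`` is ``moving(T(x))``.
    """

    matrix: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        self.center = np.asarray(self.center, dtype=float)
        if not np.allclose(self.matrix.T @ self.matrix, np.eye(3), atol=1e-6):
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(self.matrix) < 0:
            raise ValueError("rotation matrix must have determinant +1 (no reflections)")

    # -- constructors -------------------------------------------------------

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_params(
        cls,
        rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0),
        translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0),
        center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0),
    ) -> "RigidTransform":
        return cls(_rot_xyz(*rotation_deg), np.asarray(translation_mm, float),
                   np.asarray(center_mm, float))

    @classmethod
    def from_matrix(cls, homogeneous: np.ndarray) -> "RigidTransform":
        homogeneous = np.asarray(homogeneous, dtype=float)
        return cls(homogeneous[:3, :3], homogeneous[:3, 3], np.zeros(3))

    # -- algebra ------------------------------------------------------------

    @property
    def as_matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix (center folded into the translation)."""
        A = np.eye(4)
        A[:3, :3] = self.matrix
        A[:3, 3] = self.translation + self.center - self.matrix @ self.center
        return A

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        return (self.matrix @ (points - self.center).T).T + self.center + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self ∘ other`` (apply ``other`` first)."""
        return RigidTransform.from_matrix(self.as_matrix @ other.as_matrix)

    def inverse(self) -> "RigidTransform":
        return RigidTransform.from_matrix(np.linalg.inv(self.as_matrix))

    @property
    def rotation_angle_deg(self) -> float:
        """Total rotation angle (degrees) of the rotation part."""
        c = np.clip((np.trace(self.matrix) - 1.0) / 2.0, -1.0, 1.0)
        return float(np.rad2deg(np.arccos(c)))

    # -- SimpleITK interop (RAS <-> LPS) -------------------------------------

    def to_sitk(self) -> sitk.Euler3DTransform:
        t = sitk.Euler3DTransform()
        t.SetCenter(tuple((_RAS_LPS @ self.center).tolist()))
        t.SetMatrix(tuple((_RAS_LPS @ self.matrix @ _RAS_LPS).flatten().tolist()), 1e-8)
        t.SetTranslation(tuple((_RAS_LPS @ self.translation).tolist()))
        return t

    @classmethod
    def from_sitk(cls, t: sitk.Transform) -> "RigidTransform":
        t = sitk.Euler3DTransform(t.Downcast() if hasattr(t, "Downcast") else t)
        R = np.asarray(t.GetMatrix()).reshape(3, 3)
        return cls(
            _RAS_LPS @ R @ _RAS_LPS,
            _RAS_LPS @ np.asarray(t.GetTranslation()),
            _RAS_LPS @ np.asarray(t.GetCenter()),
        )


@dataclass
class RegistrationResult:
    transform: RigidTransform
    cost: float
    identity_cost: float
    success: bool
    message: str = ""


def _metric_method(cost: str, mask_img: sitk.Image | None) -> sitk.ImageRegistrationMethod:
    reg = sitk.ImageRegistrationMethod()
    if cost == "mi":
        reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=40)
    elif cost == "corr":
        reg.SetMetricAsCorrelation()
    else:
        raise ValueError(f"unknown cost {cost!r}; use 'mi' or 'corr'")
    reg.SetMetricSamplingStrategy(reg.NONE)  # dense: deterministic
    reg.SetInterpolator(sitk.sitkLinear)
    if mask_img is not None:
        reg.SetMetricFixedMask(mask_img)
    return reg


_COARSE_STARTS: list[tuple[tuple[float, float, float], tuple[float, float, float]]] = [
    ((0, 0, 0), (0, 0, 0)),
    ((6, 0, 0), (0, 0, 0)), ((-6, 0, 0), (0, 0, 0)),
    ((0, 6, 0), (0, 0, 0)), ((0, -6, 0), (0, 0, 0)),
    ((0, 0, 6), (0, 0, 0)), ((0, 0, -6), (0, 0, 0)),
    ((0, 0, 0), (6, 0, 0)), ((0, 0, 0), (-6, 0, 0)),
    ((0, 0, 0), (0, 6, 0)), ((0, 0, 0), (0, -6, 0)),
    ((0, 0, 0), (0, 0, 6)), ((0, 0, 0), (0, 0, -6)),
]


def estimate_rigid(
    fixed: Volume,
    moving: Volume,
    mask: np.ndarray | None = None,
    cost: str = "mi",
    levels: int = 3,
    multistart: bool = True,
    iterations: int = 150,
) -> RegistrationResult:
    """Estimate the rigid transform aligning ``moving`` onto ``fixed``.

    Multi-resolution (``levels`` pyramid levels, shrink 4/2/1 by default) with
    a deterministic grid of coarse starts evaluated at the lowest resolution.
    The returned cost is the final metric value; if it is worse than the
    metric at identity, the identity transform is returned with
    ``success=False`` instead of a degraded alignment.

    ``mask`` (boolean, fixed grid) restricts the metric to foreground — pass
    the union of the two foreground masks to keep air from diluting the
    similarity measure.
    """
    if np.ptp(fixed.data) == 0 or np.ptp(moving.data) == 0:
        raise RegistrationError("cannot register constant images")
    f_img = to_sitk(fixed, dtype=np.float32)
    m_img = to_sitk(moving, dtype=np.float32)
    mask_img = None
    if mask is not None:
        mask_img = to_sitk(fixed.with_data(np.asarray(mask, dtype=np.uint8)))

    center_world = fixed.index_to_world((np.asarray(fixed.shape) - 1) / 2.0)[0]
    identity = RigidTransform(center=center_world)

    def evaluate(t: RigidTransform, shrink: int = 4) -> float:
        reg = _metric_method(cost, sitk.Shrink(mask_img, [shrink] * 3) if mask_img is not None else None)
        reg.SetInitialTransform(t.to_sitk(), inPlace=False)
        return float(reg.MetricEvaluate(sitk.Shrink(f_img, [shrink] * 3),
                                        sitk.Shrink(m_img, [shrink] * 3)))

    try:
        identity_cost_coarse = evaluate(identity)
    except RuntimeError as exc:
        raise RegistrationError(f"foreground overlap is empty at identity: {exc}") from exc

    start = identity
    if multistart:
        best = identity_cost_coarse
        for rot, tr in _COARSE_STARTS[1:]:
            cand = RigidTransform.from_params(rot, tr, center_world)
            try:
                val = evaluate(cand)
            except RuntimeError:
                continue
            if val < best:
                best, start = val, cand

    shrinks = [4, 2, 1][-levels:]
    sigmas = [2.0, 1.0, 0.0][-levels:]
    reg = _metric_method(cost, mask_img)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=2.0, minStep=1e-4, numberOfIterations=int(iterations),
        gradientMagnitudeTolerance=1e-7,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel(shrinks)
    reg.SetSmoothingSigmasPerLevel(sigmas)
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
    reg.SetInitialTransform(start.to_sitk(), inPlace=True)
    try:
        final_sitk = reg.Execute(f_img, m_img)
    except RuntimeError as exc:
        raise RegistrationError(f"registration failed: {exc}") from exc
    final = RigidTransform.from_sitk(final_sitk)

    # full-resolution metric comparison against identity
    reg_eval = _metric_method(cost, mask_img)
    reg_eval.SetInitialTransform(identity.to_sitk(), inPlace=False)
    identity_cost = float(reg_eval.MetricEvaluate(f_img, m_img))
    reg_eval = _metric_method(cost, mask_img)
    reg_eval.SetInitialTransform(final.to_sitk(), inPlace=False)
    final_cost = float(reg_eval.MetricEvaluate(f_img, m_img))

    if final_cost > identity_cost:
        return RegistrationResult(
            transform=identity, cost=identity_cost, identity_cost=identity_cost,
            success=False, message="optimization did not improve on identity",
        )
    return RegistrationResult(
        transform=final, cost=final_cost, identity_cost=identity_cost, success=True,
    )


def apply_transform(
    vol: Volume,
    t: RigidTransform,
    reference_grid: Volume,
    interpolation: str = "linear",
    fill: float = np.nan,
) -> Volume:
    """Resample ``vol`` onto ``reference_grid`` through ``t``.

    Out-of-field voxels receive ``fill`` (NaN by default, so they can be
    excluded from downstream subtraction statistics).  Use nearest-neighbour
    interpolation (``fill=0``) for label masks.
    """
    interp = {"linear": sitk.sitkLinear, "nearest": sitk.sitkNearestNeighbor}[interpolation]
    if interpolation == "nearest":
        moving = to_sitk(vol)
        if np.isnan(fill):
            fill = 0.0
    else:
        moving = to_sitk(vol, dtype=np.float64)
    ref = to_sitk(reference_grid, dtype=np.float32)
    out = sitk.Resample(moving, ref, t.to_sitk(), interp, float(fill), moving.GetPixelID())
    result = from_sitk(out, meta=dict(vol.meta))
    return result


def save_transform(t: RigidTransform, file: str | Path) -> Path:
    """Serialize as a plain-text 4x4 homogeneous matrix sidecar.

    Convention (header line): world mm, RAS, maps fixed-space points into
    moving space (resampling direction).
    """
    file = Path(file)
    A = t.as_matrix
    lines = ["# rigid transform: 4x4 homogeneous, world mm, RAS, fixed->moving"]
    lines += [" ".join(f"{v:.12g}" for v in row) for row in A]
    file.write_text("\n".join(lines) + "\n")
    return file


def load_transform(file: str | Path) -> RigidTransform:
    rows = []
    for line in Path(file).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append([float(v) for v in line.split()])
    A = np.asarray(rows)
    if A.shape != (4, 4):
        raise ValueError(f"expected a 4x4 matrix in {file}, got shape {A.shape}")
    return RigidTransform.from_matrix(A)
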