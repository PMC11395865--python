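"""Digital contrast-kinetics phantom: paired early/late post-contrast T1
volumes with full ground truth.

Each tissue class follows its own contrast-enhancement-vs-time curve:
enhancing tumor and vessels peak early (gamma-variate-like curve, peak
~2-5 min after injection) and have partly washed out by the late scan;
scar/necrosis accumulates contrast slowly (saturating exponential,
wash-in); normal brain and background stay flat.  Sampling the curves at
the two acquisition times (defaults: 5 and 20 min post-injection) yields
the early and late series; the late series is additionally moved through a
known rigid transform, and both are corrupted by independent smooth
multiplicative bias fields and noise.  A matched synthetic rCBV map marks
vessel/tumor classes as hyperperfused.

Everything is seeded and reproducible; the returned truth object carries
the class labels, true compartment masks, applied transform, bias fields
and kinetic parameters, so every pipeline stage can be scored against an
analytic oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .register import RigidTransform, apply_transform
from .volume import Volume

__all__ = [
    "TissueKinetics",
    "Lesion",
    "PhantomLayout",
    "PhantomTruth",
    "PhantomCase",
    "enhancement",
    "default_kinetics",
    "default_layout",
    "random_rigid",
    "generate",
]

BACKGROUND, NORMAL, VESSEL, TUMOR, SCAR, EDEMA = 0, 1, 2, 3, 4, 5
_CLASS_IDS = {
    "background": BACKGROUND, "normal": NORMAL, "vessel": VESSEL,
    "enhancing_tumor": TUMOR, "necrosis_scar": SCAR, "edema": EDEMA,
}


@dataclass
class TissueKinetics:
    """Enhancement curve of one tissue class: intensity(t) = baseline + A·f(t).

    Curve families (all satisfy f(0) = 0, continuous in t):

    - ``gamma``: gamma-variate-like ``f(t) = ((t/tp)·exp(1 − t/tp))**shape``,
      peaking at ``f(tp) = 1`` — fast-enhancing classes that wash out.
    - ``satexp``: ``f(t) = 1 − exp(−t/tau)`` — slow monotone wash-in.
    - ``flat``: ``f ≡ 0`` — non-enhancing tissue.
    """

    name: str
    baseline: float
    amplitude: float = 0.0
    family: str = "flat"
    tp_min: float = 5.0     # gamma: time to peak (minutes)
    shape: float = 2.0      # gamma: sharpness
    tau_min: float = 10.0   # satexp: uptake time constant (minutes)
    rcbv: float = 0.0       # value in the synthetic rCBV map

    def __post_init__(self) -> None:
        if self.baseline < 0:
            raise ValueError("baseline intensity must be >= 0")
        if self.family not in ("gamma", "satexp", "flat"):
            raise ValueError(f"unknown curve family {self.family!r}")


def enhancement(tk: TissueKinetics, t: float) -> float:
    """Signal intensity of a tissue class ``t`` minutes after injection."""
    if t < 0:
        raise ValueError("time must be >= 0")
    if tk.family == "flat" or tk.amplitude == 0:
        return tk.baseline
    if tk.family == "gamma":
        x = t / tk.tp_min
        return tk.baseline + tk.amplitude * (x * np.exp(1.0 - x)) ** tk.shape
    return tk.baseline + tk.amplitude * (1.0 - np.exp(-t / tk.tau_min))


def default_kinetics() -> dict[str, TissueKinetics]:
    """Default tissue classes.

    Tumor enhancement peaks at 5 min (glioblastoma-like; reported maxima fall
    around 3-8 min post-injection) so the early scan catches the peak and the
    late scan the decline; scar/necrosis takes up contrast slowly over tens of
    minutes.  Intensities are arbitrary T1 units with normal brain at 100.
    """
    return {
        "background": TissueKinetics("background", baseline=0.0, rcbv=0.0),
        "normal": TissueKinetics("normal", baseline=100.0, rcbv=0.8),
        "vessel": TissueKinetics("vessel", baseline=120.0, amplitude=100.0,
                                 family="gamma", tp_min=2.0, shape=2.0, rcbv=3.5),
        "enhancing_tumor": TissueKinetics("enhancing_tumor", baseline=100.0,
                                          amplitude=80.0, family="gamma",
                                          tp_min=5.0, shape=2.0, rcbv=2.5),
        "necrosis_scar": TissueKinetics("necrosis_scar", baseline=100.0,
                                        amplitude=80.0, family="satexp",
                                        tau_min=10.0, rcbv=0.4),
        "edema": TissueKinetics("edema", baseline=110.0, rcbv=0.9),
    }


@dataclass
class Lesion:
    tissue: str
    kind: str = "sphere"            # sphere | ring | cylinder
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)  # offset from head center
    radius_mm: float = 8.0
    thickness_mm: float = 3.0       # ring shell thickness
    half_length_mm: float = 25.0    # cylinder half length (z)


@dataclass
class PhantomLayout:
    shape: tuple[int, int, int] = (72, 72, 60)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    head_semiaxes_mm: tuple[float, float, float] = (55.0, 65.0, 50.0)
    lesions: list[Lesion] = field(default_factory=list)


def default_layout(
    tumor_volume_cm3: float = 2.0,
    shape: tuple[int, int, int] = (72, 72, 60),
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0),
) -> PhantomLayout:
    """Head ellipsoid with a tumor sphere, a scar sphere and a vessel segment."""
    r_tumor = (3.0 * tumor_volume_cm3 * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    return PhantomLayout(
        shape=shape, spacing=spacing,
        lesions=[
            Lesion("enhancing_tumor", "sphere", (20.0, 10.0, 5.0), radius_mm=r_tumor),
            Lesion("necrosis_scar", "sphere", (-25.0, -10.0, 0.0), radius_mm=10.0),
            Lesion("vessel", "cylinder", (35.0, -25.0, 0.0), radius_mm=2.5,
                   half_length_mm=22.0),
        ],
    )


@dataclass
class PhantomTruth:
    labels: np.ndarray
    washout_mask: np.ndarray
    washin_mask: np.ndarray
    transform: RigidTransform          # alignment late -> early that registration should recover
    bias_early: np.ndarray
    bias_late: np.ndarray
    kinetics: dict[str, TissueKinetics]
    t_early: float
    t_late: float
    snr: float
    seed: int


@dataclass
class PhantomCase:
    early: Volume
    late: Volume
    rcbv: Volume
    truth: PhantomTruth


def random_rigid(
    rng: np.random.Generator,
    max_rotation_deg: float = 5.0,
    max_translation_mm: float = 5.0,
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> RigidTransform:
    """Uniform random rigid perturbation within the given bounds."""
    rot = rng.uniform(-max_rotation_deg, max_rotation_deg, size=3)
    tr = rng.uniform(-max_translation_mm, max_translation_mm, size=3)
    return RigidTransform.from_params(tuple(rot), tuple(tr), center_mm)


def _world_grids(layout: PhantomLayout) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """World coordinates (mm, relative to the volume center) per voxel."""
    axes = [
        (np.arange(n) - (n - 1) / 2.0) * s
        for n, s in zip(layout.shape, layout.spacing)
    ]
    return np.meshgrid(*axes, indexing="ij")


def _build_labels(layout: PhantomLayout) -> np.ndarray:
    X, Y, Z = _world_grids(layout)
    a, b, c = layout.head_semiaxes_mm
    head = (X / a) ** 2 + (Y / b) ** 2 + (Z / c) ** 2 <= 1.0
    labels = np.where(head, NORMAL, BACKGROUND).astype(np.uint8)
    for les in layout.lesions:
        cx, cy, cz = les.center_mm
        if les.kind == "sphere":
            inside = (X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2 <= les.radius_mm**2
        elif les.kind == "ring":
            r = np.sqrt((X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2)
            inside = (r <= les.radius_mm) & (r >= les.radius_mm - les.thickness_mm)
        elif les.kind == "cylinder":
            inside = (
                ((X - cx) ** 2 + (Y - cy) ** 2 <= les.radius_mm**2)
                & (np.abs(Z - cz) <= les.half_length_mm)
            )
        else:
            raise ValueError(f"unknown lesion kind {les.kind!r}")
        if not inside.any():
            raise ValueError(f"lesion {les.tissue} voxelizes to an empty region")
        if (inside & ~head).any():
            raise ValueError(f"lesion {les.tissue} extends outside the head")
        labels[inside] = _CLASS_IDS[les.tissue]
    return labels


def _smooth_bias(
    rng: np.random.Generator, layout: PhantomLayout, amplitude: float
) -> np.ndarray:
    """Smooth multiplicative field in [1-amplitude, 1+amplitude]."""
    if amplitude == 0:
        return np.ones(layout.shape)
    X, Y, Z = _world_grids(layout)
    extent = [n * s / 2.0 for n, s in zip(layout.shape, layout.spacing)]
    plane = sum(g * rng.uniform(-1, 1) / e for g, e in zip((X, Y, Z), extent))
    cx, cy, cz = (rng.uniform(-0.5, 0.5) * 2 * e for e in extent)
    sig = rng.uniform(0.5, 1.0) * min(extent)
    bump = rng.uniform(-1, 1) * np.exp(
        -((X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2) / (2 * sig**2)
    )
    s = plane + bump
    s = s / max(np.abs(s).max(), 1e-12)
    return 1.0 + amplitude * s


def _class_image(labels: np.ndarray, values: dict[int, float]) -> np.ndarray:
    lut = np.zeros(max(values) + 1)
    for k, v in values.items():
        lut[k] = v
    return lut[labels]


def generate(
    layout: PhantomLayout | None = None,
    kinetics: dict[str, TissueKinetics] | None = None,
    t_early: float = 5.0,
    t_late: float = 20.0,
    transform: RigidTransform | None = None,
    bias_amplitude: float = 0.2,
    snr: float = 20.0,
    noise: str = "gaussian",
    seed: int = 0,
    identical_series: bool = False,
) -> PhantomCase:
    """Generate one paired phantom case with ground truth.

    Acquisition times default to 5 min (early) and 20 min (late) after
    injection — a ~15 min inter-scan delay.  ``transform`` is the rigid
    misalignment of the late acquisition (identity when omitted); the truth
    object stores it as the alignment a registration step should recover.
    ``snr`` is the ratio of the mean head intensity to the noise σ.
    ``identical_series=True`` returns the late series as a bit-identical copy
    of the early one (shared noise draw): the null case.
    """
    if snr <= 0:
        raise ValueError("SNR must be positive")
    layout = layout or default_layout()
    kinetics = kinetics or default_kinetics()
    rng = np.random.default_rng(seed)
    labels = _build_labels(layout)

    early_vals, late_vals, rcbv_vals = {}, {}, {}
    for name, cid in _CLASS_IDS.items():
        tk = kinetics.get(name)
        if tk is None:
            tk = TissueKinetics(name, baseline=0.0)
        early_vals[cid] = enhancement(tk, t_early)
        late_vals[cid] = enhancement(tk, t_late)
        rcbv_vals[cid] = tk.rcbv
    clean_early = _class_image(labels, early_vals)
    clean_late = _class_image(labels, late_vals)

    head = labels != BACKGROUND
    washout = head & (clean_early > clean_late)
    washin = head & (clean_late > clean_early)

    geom = dict(spacing=layout.spacing, orientation=np.eye(3))
    origin = tuple(-(np.asarray(layout.shape) - 1) / 2.0 * np.asarray(layout.spacing))
    sigma = float(clean_early[head].mean()) / snr

    bias_e = _smooth_bias(rng, layout, bias_amplitude)
    bias_l = _smooth_bias(rng, layout, bias_amplitude)
    t_align = transform or RigidTransform.identity()

    def acquire(clean: np.ndarray, bias: np.ndarray, t_min: float) -> np.ndarray:
        img = clean * bias
        if noise == "gaussian":
            img = img + rng.normal(0.0, sigma, size=img.shape)
        elif noise == "rician":
            img = np.sqrt(
                (img + rng.normal(0.0, sigma, size=img.shape)) ** 2
                + rng.normal(0.0, sigma, size=img.shape) ** 2
            )
        else:
            raise ValueError(f"unknown noise model {noise!r}")
        return img

    early_data = acquire(clean_early, bias_e, t_early)
    early = Volume(early_data, layout.spacing, origin, np.eye(3),
                   {"series": "early", "t_min": t_early, "seed": seed})

    if identical_series:
        late = early.with_data(early_data.copy(), series="late", t_min=t_late)
        t_align = RigidTransform.identity()
        bias_l = bias_e.copy()
    else:
        clean_late_vol = Volume(clean_late, layout.spacing, origin, np.eye(3))
        if not np.allclose(t_align.as_matrix, np.eye(4)):
            moved = apply_transform(clean_late_vol, t_align.inverse(), clean_late_vol,
                                    interpolation="linear", fill=0.0)
            clean_late_acq = np.nan_to_num(moved.data, nan=0.0)
        else:
            clean_late_acq = clean_late
        late_data = acquire(clean_late_acq, bias_l, t_late)
        late = Volume(late_data, layout.spacing, origin, np.eye(3),
                      {"series": "late", "t_min": t_late, "seed": seed})

    rcbv_clean = _class_image(labels, rcbv_vals)
    rcbv_data = np.clip(rcbv_clean + rng.normal(0.0, 0.05, size=rcbv_clean.shape), 0, None)
    rcbv_data[~head] = 0.0
    rcbv = Volume(rcbv_data, layout.spacing, origin, np.eye(3), {"series": "rcbv"})

    truth = PhantomTruth(
        labels=labels, washout_mask=washout, washin_mask=washin,
        transform=t_align, bias_early=bias_e, bias_late=bias_l,
        kinetics=kinetics, t_early=t_early, t_late=t_late, snr=snr, seed=seed,
    )
    return PhantomCase(early=early, late=late, rcbv=rcbv, truth=truth)
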