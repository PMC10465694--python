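"""Synthetic brain phantoms for dopamine-transporter SPECT.

Clinical DAT-SPECT datasets cannot be redistributed, so this module builds
analytic stand-ins: a head modelled as nested ellipsoids (skull shell, soft
tissue, nasal/oral air cavities), bilateral striatal uptake with a
controllable left/right asymmetry, a cerebellar background region, and a
pseudo-CT constructed by inverting the bilinear HU->mu model so the CT->mu
round trip is exact.  All geometry is closed-form, which makes volumes,
uptake ratios and asymmetry indices analytically checkable.

Linear attenuation coefficients default to measured 140 keV head-tissue
values: skull bone 0.21-0.27 cm^-1, soft tissue 0.14-0.15 cm^-1, air ~0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .corrections import BilinearModel
from .volume import ValidationError, Volume3D, VOISet

__all__ = [
    "CavitySpec",
    "PhantomSpec",
    "CohortJitter",
    "Phantom",
    "generate_phantom",
    "generate_cohort",
]


@dataclass(frozen=True)
class CavitySpec:
    """One air cavity: an ellipsoid given by its centre (as fractions of the
    head semi-axes; +y anterior, +z superior) and semi-axes in cm."""

    center_frac: tuple[float, float, float]
    radii_cm: tuple[float, float, float]


DEFAULT_CAVITIES = (
    CavitySpec(center_frac=(0.0, 0.72, -0.40), radii_cm=(1.0, 1.6, 1.0)),   # nasal
    CavitySpec(center_frac=(0.0, 0.50, -0.68), radii_cm=(1.6, 1.4, 0.9)),   # oral
)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic head.

    The default grid matches the post-resampling clinical protocol of
    scanner A (128^3 at 0.2761 cm/voxel).  ``striatum_uptake_ratio`` is the
    striatum:background activity concentration ratio; the left/right striata
    are scaled by ``(1 +/- asymmetry_fraction / 2)`` so that the noiseless
    asymmetry index grows monotonically with ``asymmetry_fraction`` and is
    exactly zero for a symmetric phantom.
    """

    matrix_size: int = 128
    voxel_size_cm: float = 0.2761
    head_radii_cm: tuple[float, float, float] = (7.0, 8.8, 7.4)
    center_offset_cm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    skull_thickness_cm: float = 0.6
    mu_soft_tissue: float = 0.148
    mu_skull: float = 0.24
    mu_air: float = 0.0
    striatum_uptake_ratio: float = 2.0
    asymmetry_fraction: float = 0.0
    background_activity: float = 10.0
    cavity_spec: tuple[CavitySpec, ...] = DEFAULT_CAVITIES
    seed: int = 0
    # anatomy details (scaled together with head_radii_cm in cohorts)
    striatum_radii_cm: tuple[float, float, float] = (1.1, 2.0, 1.2)
    striatum_offset_cm: tuple[float, float, float] = (1.9, 1.0, 0.4)
    bg_roi_size: tuple[int, int] = (10, 6)
    bg_roi_center_frac: tuple[float, float] = (-0.52, -0.50)  # (y, z) fractions
    bg_roi_slices: int = 4

    def validate(self) -> None:
        if self.matrix_size < 16:
            raise ValidationError("matrix_size must be >= 16")
        if self.voxel_size_cm <= 0:
            raise ValidationError("voxel_size_cm must be positive")
        if not (0.0 <= self.asymmetry_fraction < 1.0):
            raise ValidationError("asymmetry_fraction must lie in [0, 1)")
        if self.striatum_uptake_ratio <= 0:
            raise ValidationError("striatum_uptake_ratio must be positive")
        if self.background_activity < 0:
            raise ValidationError("background_activity must be non-negative")
        if self.skull_thickness_cm <= 0:
            raise ValidationError("skull_thickness_cm must be positive")
        if any(r <= self.skull_thickness_cm for r in self.head_radii_cm):
            raise ValidationError("head radii must exceed the skull thickness")


@dataclass(frozen=True)
class CohortJitter:
    """Uniform variation ranges applied across a synthetic cohort.

    ``activity_scale`` varies the global activity concentration per
    subject, emulating the wide clinical spread of injected dose, scan
    timing and tracer delivery; the striatum:background ratio is varied
    independently.
    """

    head_scale: tuple[float, float] = (0.92, 1.08)
    uptake_ratio: tuple[float, float] = (1.4, 2.8)
    asymmetry: tuple[float, float] = (0.0, 0.3)
    activity_scale: tuple[float, float] = (0.7, 1.4)

    def validate(self) -> None:
        for name in ("head_scale", "uptake_ratio", "asymmetry", "activity_scale"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValidationError(f"jitter range {name} is empty: ({lo}, {hi})")


@dataclass
class Phantom:
    """One generated phantom: emission, mu-map, pseudo-CT and ground-truth VOIs."""

    emission: Volume3D
    mumap: Volume3D
    pseudo_ct: Volume3D
    vois: VOISet
    spec: PhantomSpec

    def __iter__(self):
        return iter((self.emission, self.mumap, self.pseudo_ct, self.vois))


def _coords_cm(n: int, voxel: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    c = (n - 1) / 2.0
    ax = (np.arange(n) - c) * voxel
    return np.meshgrid(ax, ax, ax, indexing="ij")


def _ellipsoid(x, y, z, center, radii) -> np.ndarray:
    return (
        ((x - center[0]) / radii[0]) ** 2
        + ((y - center[1]) / radii[1]) ** 2
        + ((z - center[2]) / radii[2]) ** 2
    ) <= 1.0


def generate_phantom(spec: PhantomSpec, bilinear: BilinearModel | None = None) -> Phantom:
    """Build one phantom from its spec.

    Fully deterministic: the same spec produces a bit-identical phantom.
    The pseudo-CT is the exact inverse image of the mu-map under
    ``bilinear`` (default model), so converting it back reproduces the
    mu-map to floating-point precision.
    """
    spec.validate()
    if bilinear is None:
        bilinear = BilinearModel()
    n, v = spec.matrix_size, spec.voxel_size_cm
    x, y, z = _coords_cm(n, v)
    # patient positioning: shift the whole head (and every structure tied
    # to it) off the grid centre
    x = x - spec.center_offset_cm[0]
    y = y - spec.center_offset_cm[1]
    z = z - spec.center_offset_cm[2]

    head = _ellipsoid(x, y, z, (0, 0, 0), spec.head_radii_cm)
    inner_radii = tuple(r - spec.skull_thickness_cm for r in spec.head_radii_cm)
    brain = _ellipsoid(x, y, z, (0, 0, 0), inner_radii)
    skull = head & ~brain

    cavities = np.zeros_like(head)
    for cav in spec.cavity_spec:
        center = tuple(f * r for f, r in zip(cav.center_frac, spec.head_radii_cm))
        cavities |= _ellipsoid(x, y, z, center, cav.radii_cm) & head
    tissue = brain & ~cavities

    mu = np.zeros((n, n, n))
    mu[skull & ~cavities] = spec.mu_skull
    mu[tissue] = spec.mu_soft_tissue
    mu[cavities] = spec.mu_air

    # striata: mirrored ellipsoids; "left" is +x by this package's convention
    ox, oy, oz = spec.striatum_offset_cm
    left = _ellipsoid(x, y, z, (+ox, oy, oz), spec.striatum_radii_cm)
    right = _ellipsoid(x, y, z, (-ox, oy, oz), spec.striatum_radii_cm)
    if not (left & tissue).sum() or not (right & tissue).sum():
        raise ValidationError("striatum falls outside the soft-tissue region")
    if (left & ~tissue).any() or (right & ~tissue).any():
        raise ValidationError("striatum is not fully inside soft tissue")
    if (left & right).any():
        raise ValidationError("striatum ellipsoids overlap; reduce radii or widen offset")

    a = spec.asymmetry_fraction
    emission = np.zeros((n, n, n))
    emission[tissue] = spec.background_activity
    emission[left] = spec.striatum_uptake_ratio * spec.background_activity * (1 + a / 2)
    emission[right] = spec.striatum_uptake_ratio * spec.background_activity * (1 - a / 2)

    vois = VOISet(left, right, _background_roi(spec, tissue, left | right))

    hu = bilinear.mu_to_hu(mu)
    return Phantom(
        emission=Volume3D(emission, v, "counts"),
        mumap=Volume3D(mu, v, "cm^-1"),
        pseudo_ct=Volume3D(hu, v, "HU"),
        vois=vois,
        spec=spec,
    )


def _background_roi(spec: PhantomSpec, tissue: np.ndarray, striatum: np.ndarray) -> np.ndarray:
    """Rectangular cerebellar background ROI, replicated over a few slices.

    Mirrors the clinical convention of a 2D 10 x 6 pixel ROI in the
    cerebellum (posterior-inferior), stacked into a small VOI.
    """
    n, v = spec.matrix_size, spec.voxel_size_cm
    c = (n - 1) / 2.0
    ox, oy, oz = (o / v for o in spec.center_offset_cm)
    inner = tuple(r - spec.skull_thickness_cm for r in spec.head_radii_cm)
    fy, fz = spec.bg_roi_center_frac
    cy = int(round(c + oy + fy * inner[1] / v))
    cz = int(round(c + oz + fz * inner[2] / v))
    wx, wy = spec.bg_roi_size
    x0 = int(round(c + ox)) - wx // 2
    x1 = x0 + wx
    y0, y1 = cy - wy // 2, cy - wy // 2 + wy
    roi = np.zeros_like(tissue)
    roi[x0:x1, y0:y1, cz : cz + spec.bg_roi_slices] = True
    roi &= tissue & ~striatum
    if not roi.any():
        raise ValidationError("background ROI fell outside the brain; adjust bg_roi_*")
    return roi


def generate_cohort(
    n: int,
    base_spec: PhantomSpec | None = None,
    jitter: CohortJitter | None = None,
    seed: int = 0,
    bilinear: BilinearModel | None = None,
) -> list[Phantom]:
    """Generate ``n`` phantoms with randomised head size, uptake ratio and
    asymmetry drawn uniformly from ``jitter`` ranges.  Reproducible under
    ``seed``; striatal anatomy scales with the head."""
    if n < 1:
        raise ValidationError("cohort size must be >= 1")
    base_spec = base_spec if base_spec is not None else PhantomSpec()
    jitter = jitter if jitter is not None else CohortJitter()
    jitter.validate()
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        s = rng.uniform(*jitter.head_scale)
        ratio = rng.uniform(*jitter.uptake_ratio)
        asym = rng.uniform(*jitter.asymmetry)
        act = rng.uniform(*jitter.activity_scale)
        spec = replace(
            base_spec,
            head_radii_cm=tuple(s * r for r in base_spec.head_radii_cm),
            striatum_radii_cm=tuple(s * r for r in base_spec.striatum_radii_cm),
            striatum_offset_cm=tuple(s * r for r in base_spec.striatum_offset_cm),
            striatum_uptake_ratio=ratio,
            asymmetry_fraction=asym,
            background_activity=act * base_spec.background_activity,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        out.append(generate_phantom(spec, bilinear=bilinear))
    return out
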