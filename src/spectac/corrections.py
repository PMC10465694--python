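"""Scatter, CT-based and Chang attenuation corrections.

Covers the three CT-less/CT-based correction building blocks of the
clinical protocol:

* dual-energy-window (DEW) scatter subtraction from a lower adjacent
  energy window,
* the bilinear Hounsfield-unit -> linear-attenuation-coefficient model at
  the 140 keV photopeak,
* Chang's uniform mu-map construction from a thresholded NAC
  reconstruction (the clinical CT-less route: threshold 2, uniform
  0.148 cm^-1, converted to per-voxel units) and the classical first-order
  Chang correction-factor image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from . import projector as proj
from .recon import ReconConfig
from .volume import ValidationError, Volume3D

__all__ = [
    "ScannerProfile",
    "BilinearModel",
    "scanner_a",
    "scanner_b",
    "dew_scatter_correct",
    "ct_to_mumap",
    "chang_mumap",
    "chang_first_order_factors",
]


@dataclass(frozen=True)
class ScannerProfile:
    """Acquisition/reconstruction parameters of one scanner."""

    name: str
    matrix_size: int
    voxel_size_cm: float
    n_views: int
    primary_window_kev: tuple[float, float]
    scatter_window_kev: tuple[float, float]
    filter_sigma_voxels: float
    osem: ReconConfig = field(default_factory=ReconConfig)

    def geometry(self, matrix_size: int | None = None) -> proj.Geometry:
        n = matrix_size if matrix_size is not None else self.matrix_size
        return proj.Geometry(self.n_views, n, n, self.voxel_size_cm)

    def desk(self, matrix_size: int, n_views: int, voxel_size_cm: float) -> "ScannerProfile":
        """Scaled-down variant for CPU-sized experiments; energy windows,
        post-filter and OS-EM settings are kept."""
        return replace(
            self, matrix_size=matrix_size, n_views=n_views, voxel_size_cm=voxel_size_cm
        )


def scanner_a() -> ScannerProfile:
    """GE Infinia Hawkeye protocol (after resampling to 128^3)."""
    return ScannerProfile(
        name="A", matrix_size=128, voxel_size_cm=0.2761, n_views=120,
        primary_window_kev=(126.0, 154.0), scatter_window_kev=(114.0, 126.0),
        filter_sigma_voxels=0.8,
    )


def scanner_b() -> ScannerProfile:
    """Siemens Symbia protocol."""
    return ScannerProfile(
        name="B", matrix_size=128, voxel_size_cm=0.2697, n_views=120,
        primary_window_kev=(126.0, 154.0), scatter_window_kev=(109.0, 126.0),
        filter_sigma_voxels=1.2,
    )


# ------------------------------------------------------------------- DEW

def dew_scatter_correct(mw: proj.MultiWindowSinogram, k: float = 0.5) -> np.ndarray:
    """Dual-energy-window scatter correction of the photopeak sinogram.

    The per-bin scatter estimate is ``scatter_counts * (primary_width /
    scatter_width) * k`` (``k = 0.5`` is the usual dual-window
    convention); the corrected sinogram is clamped at zero.
    """
    if k <= 0:
        raise ValidationError("DEW scale factor k must be positive")
    p_lo, p_hi = mw.primary_window_kev
    s_lo, s_hi = mw.scatter_window_kev
    estimate = mw.scatter * ((p_hi - p_lo) / (s_hi - s_lo)) * k
    return np.maximum(mw.primary - estimate, 0.0)


# -------------------------------------------------------------- bilinear

@dataclass(frozen=True)
class BilinearModel:
    """Piecewise-linear HU -> mu conversion at 140 keV.

    Below the breakpoint (0 HU) mu interpolates linearly between air
    (-1000 HU -> 0) and water (0 HU -> ``mu_water_cm1``); above it bone
    adds ``bone_slope_cm1_per_hu`` per HU.  Defaults place +1000 HU at
    0.25 cm^-1, inside the measured 0.21-0.27 cm^-1 skull range.
    """

    mu_water_cm1: float = 0.150
    bone_slope_cm1_per_hu: float = 1.0e-4
    breakpoint_hu: float = 0.0

    def hu_to_mu(self, hu: np.ndarray) -> np.ndarray:
        hu = np.asarray(hu, dtype=np.float64)
        soft = self.mu_water_cm1 * (hu + 1000.0) / 1000.0
        bone = self.mu_water_cm1 + self.bone_slope_cm1_per_hu * (hu - self.breakpoint_hu)
        return np.maximum(np.where(hu <= self.breakpoint_hu, soft, bone), 0.0)

    def mu_to_hu(self, mu: np.ndarray) -> np.ndarray:
        """Exact inverse on mu >= 0 (used to build pseudo-CTs)."""
        mu = np.asarray(mu, dtype=np.float64)
        soft = 1000.0 * mu / self.mu_water_cm1 - 1000.0
        bone = self.breakpoint_hu + (mu - self.mu_water_cm1) / self.bone_slope_cm1_per_hu
        return np.where(mu <= self.mu_water_cm1, soft, bone)


def ct_to_mumap(ct: Volume3D, model: BilinearModel | None = None) -> Volume3D:
    """Convert a CT volume in Hounsfield units to a mu-map in cm^-1."""
    if ct.unit != "HU":
        raise ValidationError(f"CT volume must be tagged 'HU', got {ct.unit!r}")
    model = model if model is not None else BilinearModel()
    return Volume3D(model.hu_to_mu(ct.data), ct.voxel_size_cm, "cm^-1")


# ----------------------------------------------------------------- Chang

def chang_mumap(
    nac: Volume3D,
    threshold: float = 2.0,
    mu_uniform_cm1: float = 0.148,
    voxel_size_cm: float | None = None,
) -> Volume3D:
    """Uniform mu-map from a thresholded NAC reconstruction.

    The brain mask is the largest connected component above ``threshold``
    (in reconstructed count units), hole-filled.  In-mask voxels carry the
    uniform coefficient expressed per voxel, truncated at four decimals to
    match the printed clinical convention (0.148 cm^-1 -> 0.0408 voxel^-1
    at 0.2761 cm, 0.0399 voxel^-1 at 0.2697 cm).
    """
    if nac.data.min() < 0:
        raise ValidationError("NAC image must be non-negative")
    v = voxel_size_cm if voxel_size_cm is not None else nac.voxel_size_cm
    binary = nac.data > threshold
    if not binary.any():
        raise ValidationError(
            f"threshold {threshold} leaves an empty brain mask; adjust the threshold"
        )
    labels, nlab = ndimage.label(binary)
    largest = np.argmax(ndimage.sum_labels(binary, labels, index=np.arange(1, nlab + 1))) + 1
    mask = ndimage.binary_fill_holes(labels == largest)
    mu_voxel = math.floor(mu_uniform_cm1 * v * 1e4) / 1e4
    return Volume3D(np.where(mask, mu_voxel, 0.0), v, "voxel^-1")


def chang_first_order_factors(
    mask: np.ndarray,
    mu_uniform_cm1: float = 0.148,
    angles: int = 64,
    voxel_size_cm: float = 0.2761,
) -> np.ndarray:
    """Classical first-order Chang correction-factor image.

    For each voxel the factor is ``1 / mean_over_angles(exp(-mu * d))``
    where ``d`` is the in-mask, in-plane path length from the voxel to the
    contour along each projection angle.  Factors are >= 1 inside the mask
    and exactly 1 outside (no correction).  Provided for comparison with
    the clinical pipeline, which instead feeds the uniform mu-map into the
    OS-EM system model.
    """
    if angles < 4:
        raise ValidationError("need at least 4 angles")
    mask = np.asarray(mask)
    if mask.ndim != 3:
        raise ValidationError("mask must be 3D")
    n = mask.shape[0]
    if mask.shape[1] != n:
        raise ValidationError("in-plane mask dimensions must be square")
    z = mask.shape[2]
    mu = np.where(mask, mu_uniform_cm1, 0.0).reshape(n * n, z)
    acc = np.zeros((n * n, z))
    norm = np.zeros(n * n)
    ones = np.ones(n * n)
    thetas = 2.0 * np.pi * np.arange(angles) / angles
    for t in thetas:
        m = proj.rotation_matrix(n, t)
        m_inv = proj.rotation_matrix(n, -t)
        murot = (m @ mu).reshape(n, n, z)
        cum = np.cumsum(murot[:, ::-1, :], axis=1)[:, ::-1, :] - 0.5 * murot
        w = np.exp(-voxel_size_cm * cum)
        acc += m_inv @ w.reshape(n * n, z)
        norm += m_inv @ ones
    # normalize by the interpolated rotation mass so that mu = 0 yields
    # factors of exactly 1 everywhere, including near the grid corners
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_att = (acc / np.maximum(norm, 1e-12)[:, None]).reshape(n, n, z)
    factors = np.ones((n, n, z))
    inside = mask & (mean_att > 0)
    factors[inside] = 1.0 / mean_att[inside]
    return np.maximum(factors, 1.0)
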