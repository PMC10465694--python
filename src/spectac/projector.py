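"""Attenuated parallel-beam projector and acquisition simulator.

The system model is rotation-based: for each view the volume is resampled
into the detector frame by an in-plane rotation, attenuated with the line
integral of mu from each voxel to the detector, and summed along the ray
axis.  The rotation is assembled once per (grid, angle) as an explicit
sparse matrix of bilinear interpolation weights, so the back-projector is
the exact matrix transpose and the pair satisfies the adjoint identity
<A x, y> = <x, A^T y> to machine precision — the property OS-EM relies on.

Geometry is slice-by-slice 2D parallel-beam (parallel-hole collimation):
rays run along the +y axis of the rotated frame, the detector bins are the
x coordinates, and the axial (z) dimension is carried through unchanged.
Collimator-detector response is not modelled; resolution matching is left
to the reconstruction post-filter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.ndimage import gaussian_filter

from .volume import ValidationError, Volume3D

__all__ = [
    "Geometry",
    "MultiWindowSinogram",
    "forward_project",
    "back_project",
    "simulate_acquisition",
]


@dataclass(frozen=True)
class Geometry:
    """Acquisition geometry: evenly spaced views over ``arc_degrees``."""

    n_views: int
    detector_bins: int
    axial_slices: int
    voxel_size_cm: float
    arc_degrees: float = 360.0

    def __post_init__(self) -> None:
        if self.n_views < 1:
            raise ValidationError("n_views must be >= 1")
        if self.voxel_size_cm <= 0:
            raise ValidationError("voxel_size_cm must be positive")

    @property
    def angles_rad(self) -> np.ndarray:
        return np.deg2rad(self.arc_degrees) * np.arange(self.n_views) / self.n_views

    @classmethod
    def for_volume(cls, vol: Volume3D, n_views: int, arc_degrees: float = 360.0) -> "Geometry":
        n = vol.shape[0]
        return cls(n_views, n, vol.shape[2], vol.voxel_size_cm, arc_degrees)

    def sinogram_shape(self) -> tuple[int, int, int]:
        return (self.n_views, self.detector_bins, self.axial_slices)


# --------------------------------------------------------------- rotations

_ROT_CACHE: dict[tuple[int, float, bool], sp.csr_matrix] = {}


def rotation_matrix(n: int, theta: float, conserve_mass: bool = False) -> sp.csr_matrix:
    """Sparse (n^2, n^2) bilinear pull-rotation of an n x n slice about its
    centre.  Out-of-grid source positions are dropped (zero padding).

    With ``conserve_mass`` the columns are renormalized to unit sum (where
    at least half of a source pixel's weight lands in-grid), so the total
    of any in-grid image is preserved exactly — the variant used for the
    emission system matrix.  The plain variant preserves values in
    constant regions and is used to resample attenuation maps.
    """
    key = (n, round(float(theta), 12), conserve_mass)
    if key in _ROT_CACHE:
        return _ROT_CACHE[key]
    c = (n - 1) / 2.0
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    u, v = ii.ravel() - c, jj.ravel() - c
    ct, st = np.cos(theta), np.sin(theta)
    px = c + ct * u - st * v
    py = c + st * u + ct * v
    x0, y0 = np.floor(px).astype(int), np.floor(py).astype(int)
    fx, fy = px - x0, py - y0
    rows, cols, vals = [], [], []
    out_idx = np.arange(n * n)
    for dx, wx in ((0, 1 - fx), (1, fx)):
        for dy, wy in ((0, 1 - fy), (1, fy)):
            xs, ys = x0 + dx, y0 + dy
            ok = (xs >= 0) & (xs < n) & (ys >= 0) & (ys < n)
            w = wx * wy
            ok &= w > 0
            rows.append(out_idx[ok])
            cols.append((xs * n + ys)[ok])
            vals.append(w[ok])
    m = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n * n, n * n),
    ).tocsr()
    if conserve_mass:
        # Sinkhorn-style row/column balancing: rows ~1 keeps constants
        # constant (smooth views), the final column pass makes in-grid
        # mass conservation exact; boundary-clipped rows/columns are left
        # alone so truncated mass is not redistributed inward
        for axis in (1, 0) * 8:
            sums = np.asarray(m.sum(axis=axis)).ravel()
            inv = np.where(sums > 0.5, 1.0 / np.maximum(sums, 0.5), 1.0)
            m = (sp.diags(inv) @ m if axis == 1 else m @ sp.diags(inv)).tocsr()
    if len(_ROT_CACHE) > 1024:
        _ROT_CACHE.clear()
    _ROT_CACHE[key] = m
    return m


def _rotations(geom: Geometry, conserve_mass: bool = True) -> list[sp.csr_matrix]:
    n = geom.detector_bins
    return [rotation_matrix(n, t, conserve_mass) for t in geom.angles_rad]


def _check_mumap(emission: Volume3D, mumap: Volume3D | None) -> None:
    if mumap is None:
        return
    if mumap.unit not in ("cm^-1", "voxel^-1"):
        raise ValidationError(f"mu-map unit must be cm^-1 or voxel^-1, got {mumap.unit!r}")
    if mumap.shape != emission.shape or not np.isclose(
        mumap.voxel_size_cm, emission.voxel_size_cm
    ):
        raise ValidationError("emission and mu-map must share grid and voxel size")


def attenuation_weights(
    mumap: Volume3D | None, geom: Geometry, mats: list[sp.csr_matrix] | None = None
) -> list[np.ndarray]:
    """Per-view voxel survival factors exp(-integral of mu to the detector).

    The line integral uses a cumulative sum along the ray towards the
    detector with half-voxel self-attenuation at the source voxel.
    """
    n, z = geom.detector_bins, geom.axial_slices
    if mats is None:
        mats = _rotations(geom, conserve_mass=False)
    if mumap is None:
        return [np.ones((n, n, z))] * geom.n_views
    step = geom.voxel_size_cm if mumap.unit == "cm^-1" else 1.0
    flat = mumap.data.reshape(n * n, z)
    out = []
    for m in mats:
        murot = (m @ flat).reshape(n, n, z)
        # cum[x, y, z] = sum_{y' >= y} mu - mu/2  (detector at +y)
        cum = np.cumsum(murot[:, ::-1, :], axis=1)[:, ::-1, :] - 0.5 * murot
        out.append(np.exp(-step * cum))
    return out


def forward_project(
    emission: Volume3D, mumap: Volume3D | None, geom: Geometry
) -> np.ndarray:
    """Attenuated parallel-beam projection -> array (n_views, bins, slices)."""
    if emission.shape[0] != geom.detector_bins or emission.shape[2] != geom.axial_slices:
        raise ValidationError("emission grid does not match geometry")
    _check_mumap(emission, mumap)
    att = attenuation_weights(mumap, geom, _rotations(geom, conserve_mass=False))
    return _forward(emission.data, att, _rotations(geom), geom)


def _forward(
    vol: np.ndarray,
    att: list[np.ndarray],
    mats: list[sp.csr_matrix],
    geom: Geometry,
    views: np.ndarray | None = None,
) -> np.ndarray:
    n, z = geom.detector_bins, geom.axial_slices
    flat = vol.reshape(n * n, z)
    view_list = list(range(geom.n_views)) if views is None else list(views)
    sino = np.empty((len(view_list), n, z))
    for k, v in enumerate(view_list):
        rot = (mats[v] @ flat).reshape(n, n, z)
        sino[k] = (rot * att[v]).sum(axis=1)
    return sino


def _backward(
    sino: np.ndarray,
    att: list[np.ndarray],
    mats: list[sp.csr_matrix],
    geom: Geometry,
    views: np.ndarray | None = None,
) -> np.ndarray:
    n, z = geom.detector_bins, geom.axial_slices
    acc = np.zeros((n * n, z))
    view_list = list(range(geom.n_views)) if views is None else list(views)
    for k, v in enumerate(view_list):
        vol3 = att[v] * sino[k][:, None, :]
        acc += mats[v].T @ vol3.reshape(n * n, z)
    return acc.reshape(n, n, z)


def back_project(sino: np.ndarray, mumap: Volume3D | None, geom: Geometry) -> Volume3D:
    """Exact adjoint of :func:`forward_project` with the same attenuation
    weighting."""
    sino = np.asarray(sino, dtype=np.float64)
    if sino.shape != geom.sinogram_shape():
        raise ValidationError(
            f"sinogram shape {sino.shape} does not match geometry {geom.sinogram_shape()}"
        )
    if mumap is not None:
        _check_mumap(Volume3D(np.zeros((geom.detector_bins,) * 2 + (geom.axial_slices,)),
                              geom.voxel_size_cm, "counts"), mumap)
    att = attenuation_weights(mumap, geom, _rotations(geom, conserve_mass=False))
    return Volume3D(_backward(sino, att, _rotations(geom), geom),
                    geom.voxel_size_cm, "counts")


# ---------------------------------------------------------- acquisition

@dataclass
class MultiWindowSinogram:
    """Projection counts in the photopeak (primary) and the adjacent lower
    scatter energy window, plus the acquisition geometry."""

    primary: np.ndarray
    scatter: np.ndarray
    primary_window_kev: tuple[float, float]
    scatter_window_kev: tuple[float, float]
    geometry: Geometry

    def __post_init__(self) -> None:
        self.primary = np.asarray(self.primary, dtype=np.float64)
        self.scatter = np.asarray(self.scatter, dtype=np.float64)
        for lo, hi in (self.primary_window_kev, self.scatter_window_kev):
            if hi <= lo:
                raise ValidationError(f"degenerate energy window ({lo}, {hi}) keV")
        if self.primary.shape != self.geometry.sinogram_shape():
            raise ValidationError("primary window shape does not match geometry")
        if self.scatter.shape != self.primary.shape:
            raise ValidationError("scatter window shape does not match primary")

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez_compressed(path, primary=self.primary, scatter=self.scatter)
        sidecar = {
            "primary_window_kev": list(self.primary_window_kev),
            "scatter_window_kev": list(self.scatter_window_kev),
            "geometry": {
                "n_views": self.geometry.n_views,
                "detector_bins": self.geometry.detector_bins,
                "axial_slices": self.geometry.axial_slices,
                "voxel_size_cm": self.geometry.voxel_size_cm,
                "arc_degrees": self.geometry.arc_degrees,
            },
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "MultiWindowSinogram":
        path = Path(path)
        if path.suffix != ".npz":
            path = path.with_suffix(".npz")
        arrays = np.load(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(
            arrays["primary"],
            arrays["scatter"],
            tuple(meta["primary_window_kev"]),
            tuple(meta["scatter_window_kev"]),
            Geometry(**meta["geometry"]),
        )


def simulate_acquisition(
    emission: Volume3D,
    mumap: Volume3D | None,
    profile,
    total_counts: float | None = None,
    seed: int = 0,
    scatter_fraction: float = 0.3,
    scatter_blur_sigma: float = 2.0,
    noise: bool = True,
    dew_k: float = 0.5,
) -> MultiWindowSinogram:
    """Simulate a noisy dual-energy-window acquisition.

    The photopeak window holds Poisson counts of the attenuated projection
    plus a scatter component modelled as a wide-Gaussian blur of the trues
    scaled by ``scatter_fraction``.  The lower window holds a
    scatter-dominated signal scaled such that the dual-energy-window
    estimate with scale factor ``dew_k`` is unbiased for the photopeak
    scatter.  ``profile`` supplies views and energy windows (duck-typed:
    any object with ``n_views``, ``primary_window_kev``,
    ``scatter_window_kev``).
    """
    if total_counts is not None and total_counts <= 0:
        raise ValidationError("total_counts must be positive")
    if scatter_fraction < 0:
        raise ValidationError("scatter_fraction must be non-negative")
    geom = Geometry.for_volume(emission, profile.n_views)
    trues = forward_project(emission, mumap, geom)
    if scatter_fraction > 0:
        scatter_true = scatter_fraction * gaussian_filter(
            trues, sigma=(0.0, scatter_blur_sigma, scatter_blur_sigma), mode="constant"
        )
    else:
        scatter_true = np.zeros_like(trues)
    scale = 1.0
    if total_counts is not None:
        denom = trues.sum() + scatter_true.sum()
        if denom <= 0:
            raise ValidationError("emission projects to zero counts")
        scale = total_counts / denom
    primary_mean = scale * (trues + scatter_true)
    p_lo, p_hi = profile.primary_window_kev
    s_lo, s_hi = profile.scatter_window_kev
    width_ratio = (s_hi - s_lo) / (p_hi - p_lo)
    scatter_mean = scale * scatter_true * width_ratio / dew_k
    if noise:
        rng = np.random.default_rng(seed)
        primary = rng.poisson(primary_mean).astype(np.float64)
        scatter = rng.poisson(scatter_mean).astype(np.float64)
    else:
        primary, scatter = primary_mean, scatter_mean
    return MultiWindowSinogram(
        primary, scatter, tuple(profile.primary_window_kev),
        tuple(profile.scatter_window_kev), geom,
    )
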