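"""Minimal 3D volume container with unit tagging and NIfTI-1 I/O.

Axes are ordered ``(x, y, z)`` with ``z`` axial; voxel indices are 0-based.
Units are tracked with a string tag so that downstream operations can check
that, e.g., an attenuation map really is in cm^-1 before exponentiating
line integrals, or that a CT volume is in Hounsfield units before the
bilinear conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

#: recognised unit tags
UNITS = ("counts", "cm^-1", "voxel^-1", "HU", "arbitrary")


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass
class Volume3D:
    """A 3D scalar field on a regular isotropic grid.

    Parameters
    ----------
    data
        3D array, axes ``(x, y, z)``.
    voxel_size_cm
        Isotropic voxel edge length in cm.
    unit
        One of :data:`UNITS`.  All units except ``HU`` must be
        non-negative.
    """

    data: np.ndarray
    voxel_size_cm: float
    unit: str = "arbitrary"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValidationError(f"expected a 3D array, got ndim={self.data.ndim}")
        if not np.isfinite(self.voxel_size_cm) or self.voxel_size_cm <= 0:
            raise ValidationError(f"voxel_size_cm must be positive, got {self.voxel_size_cm}")
        if self.unit not in UNITS:
            raise ValidationError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        if self.unit != "HU" and self.data.min() < 0:
            raise ValidationError(f"{self.unit!r} volume must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def copy(self) -> "Volume3D":
        return replace(self, data=self.data.copy())

    def with_data(self, data: np.ndarray, unit: str | None = None) -> "Volume3D":
        """Return a new volume on the same grid with different data."""
        return Volume3D(data, self.voxel_size_cm, unit if unit is not None else self.unit)

    # ---------------------------------------------------------------- I/O
    def save(self, path: str | Path) -> None:
        """Write as NIfTI-1; voxel size goes to the header zooms and the
        unit tag into the ``descrip`` field."""
        affine = np.diag([self.voxel_size_cm * 10.0] * 3 + [1.0])  # NIfTI mm
        img = nib.Nifti1Image(self.data.astype(np.float32), affine)
        img.header.set_zooms((self.voxel_size_cm * 10.0,) * 3)
        img.header["descrip"] = f"unit={self.unit}".encode()
        nib.save(img, str(path))

    @classmethod
    def load(cls, path: str | Path, unit: str | None = None) -> "Volume3D":
        img = nib.load(str(path))
        zooms = img.header.get_zooms()[:3]
        data = np.asanyarray(img.dataobj).astype(np.float64)
        if unit is None:
            descrip = bytes(img.header["descrip"]).decode(errors="ignore")
            unit = "arbitrary"
            for u in UNITS:
                if f"unit={u}" in descrip:
                    unit = u
                    break
        return cls(data, float(zooms[0]) / 10.0, unit)


@dataclass
class VOISet:
    """Ground-truth volumes of interest: left/right striatum and a
    cerebellar background region.

    The background region follows the clinical convention of a 10 x 6 pixel
    2D ROI replicated over a small axial slice range.
    """

    striatum_left: np.ndarray
    striatum_right: np.ndarray
    background: np.ndarray

    def __post_init__(self) -> None:
        for name in ("striatum_left", "striatum_right", "background"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=bool))
        if not (self.striatum_left.shape == self.striatum_right.shape == self.background.shape):
            raise ValidationError("VOI masks must share one grid")
        if (self.striatum_left & self.striatum_right).any():
            raise ValidationError("left/right striatum masks overlap")
        if (self.background & (self.striatum_left | self.striatum_right)).any():
            raise ValidationError("background ROI overlaps the striatum")

    @property
    def striatum(self) -> np.ndarray:
        """Whole-striatum mask (left | right)."""
        return self.striatum_left | self.striatum_right

    def to_labelmap(self) -> np.ndarray:
        """0 = none, 1 = left striatum, 2 = right striatum, 3 = background."""
        lab = np.zeros(self.striatum_left.shape, dtype=np.int16)
        lab[self.striatum_left] = 1
        lab[self.striatum_right] = 2
        lab[self.background] = 3
        return lab

    @classmethod
    def from_labelmap(cls, lab: np.ndarray) -> "VOISet":
        lab = np.asarray(lab)
        return cls(lab == 1, lab == 2, lab == 3)

    def save(self, path: str | Path, voxel_size_cm: float) -> None:
        affine = np.diag([voxel_size_cm * 10.0] * 3 + [1.0])
        nib.save(nib.Nifti1Image(self.to_labelmap().astype(np.int16), affine), str(path))

    @classmethod
    def load(cls, path: str | Path) -> "VOISet":
        img = nib.load(str(path))
        return cls.from_labelmap(np.asanyarray(img.dataobj))
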