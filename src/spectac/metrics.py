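"""Quantitative evaluation: NMSE, SSIM, SUR, %ASI, count profiles,
Bland-Altman agreement and paired tests with Bonferroni correction.

The striatal specific uptake ratio

    SUR = (mean_striatum - mean_background) / mean_background

and the percent asymmetry index

    %ASI = |(SUR_L - SUR_R) / (SUR_L + SUR_R)| * 100

are the clinically reported dopamine-transporter quantities; NMSE and SSIM
compare whole-brain image similarity against the CT-based AC reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import map_coordinates, uniform_filter

from .volume import ValidationError, Volume3D, VOISet

__all__ = [
    "nmse",
    "ssim",
    "brain_mask",
    "sur",
    "asi_percent",
    "count_profile",
    "BlandAltmanStats",
    "bland_altman",
    "paired_tests",
    "MetricsReport",
]


def _data(x) -> np.ndarray:
    return x.data if isinstance(x, Volume3D) else np.asarray(x, dtype=np.float64)


def nmse(x, ref, mask: np.ndarray | None = None) -> float:
    """Normalized mean square error sum((x-ref)^2) / sum(ref^2), optionally
    restricted to a mask."""
    x, ref = _data(x), _data(ref)
    if x.shape != ref.shape:
        raise ValidationError("shape mismatch")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        x, ref = x[mask], ref[mask]
    denom = float((ref**2).sum())
    if denom == 0:
        raise ValidationError("reference is all-zero (within the mask)")
    return float(((x - ref) ** 2).sum() / denom)


def brain_mask(mumap: Volume3D | np.ndarray, mu_min_cm1: float = 0.01) -> np.ndarray:
    """Whole-brain mask convention for NMSE/SSIM: reference attenuation
    above ``mu_min_cm1``."""
    return _data(mumap) > mu_min_cm1


def ssim(
    x,
    ref,
    win_size: int = 7,
    k1: float = 0.01,
    k2: float = 0.03,
    data_range: float | None = None,
    mask: np.ndarray | None = None,
) -> float:
    """Mean local structural similarity over 3D box windows.

    Standard formulation with uniform windows, sample-covariance
    normalization, and the mean taken over windows fully inside the
    volume (further restricted to ``mask`` if given).  ``data_range``
    defaults to the maximum of the reference.
    """
    x, ref = _data(x), _data(ref)
    if x.shape != ref.shape:
        raise ValidationError("shape mismatch")
    if any(s < win_size for s in x.shape):
        raise ValidationError(f"window {win_size} larger than volume {x.shape}")
    if data_range is None:
        data_range = float(ref.max())
        if data_range == 0:
            raise ValidationError("reference is all-zero; pass data_range explicitly")
    np_win = win_size ** x.ndim
    cov_norm = np_win / (np_win - 1)
    ux = uniform_filter(x, win_size)
    uy = uniform_filter(ref, win_size)
    uxx = uniform_filter(x * x, win_size)
    uyy = uniform_filter(ref * ref, win_size)
    uxy = uniform_filter(x * ref, win_size)
    vx = cov_norm * (uxx - ux * ux)
    vy = cov_norm * (uyy - uy * uy)
    vxy = cov_norm * (uxy - ux * uy)
    c1, c2 = (k1 * data_range) ** 2, (k2 * data_range) ** 2
    s = ((2 * ux * uy + c1) * (2 * vxy + c2)) / ((ux**2 + uy**2 + c1) * (vx + vy + c2))
    pad = (win_size - 1) // 2
    sl = (slice(pad, -pad),) * s.ndim
    core = s[sl]
    if mask is not None:
        core_mask = np.asarray(mask, dtype=bool)[sl]
        if not core_mask.any():
            raise ValidationError("mask empty inside the valid SSIM region")
        return float(core[core_mask].mean())
    return float(core.mean())


def sur(img, vois: VOISet) -> float:
    """Specific uptake ratio of the whole striatum to the background."""
    return _region_sur(img, vois.striatum, vois.background)


def _region_sur(img, striatum: np.ndarray, background: np.ndarray) -> float:
    data = _data(img)
    if not striatum.any() or not background.any():
        raise ValidationError("empty VOI mask")
    bg = float(data[background].mean())
    if bg == 0:
        raise ValidationError("background mean is zero")
    return float((data[striatum].mean() - bg) / bg)


def sur_left_right(img, vois: VOISet) -> tuple[float, float]:
    """Per-side SURs (left, right) against the shared background ROI."""
    return (
        _region_sur(img, vois.striatum_left, vois.background),
        _region_sur(img, vois.striatum_right, vois.background),
    )


def asi_percent(sur_left: float, sur_right: float) -> float:
    """Percent asymmetry index |(SUR_L - SUR_R)/(SUR_L + SUR_R)| * 100."""
    denom = sur_left + sur_right
    if denom == 0:
        raise ValidationError("SUR_L + SUR_R is zero; asymmetry index undefined")
    return float(abs((sur_left - sur_right) / denom) * 100.0)


def count_profile(img, start, end, n_samples: int = 40) -> np.ndarray:
    """Linearly interpolated intensities along the segment from ``start``
    to ``end`` (voxel coordinates, endpoints inclusive); the 40-sample
    default matches the clinical across-striatum profile convention."""
    data = _data(img)
    start = np.asarray(start, dtype=np.float64)
    end = np.asarray(end, dtype=np.float64)
    if start.shape != (data.ndim,) or end.shape != (data.ndim,):
        raise ValidationError("endpoints must have one coordinate per axis")
    for p in (start, end):
        if (p < 0).any() or (p > np.array(data.shape) - 1).any():
            raise ValidationError(f"endpoint {p} outside the volume")
    t = np.linspace(0.0, 1.0, n_samples)
    coords = start[:, None] * (1 - t) + end[:, None] * t
    return map_coordinates(data, coords, order=1)


@dataclass(frozen=True)
class BlandAltmanStats:
    """Mean difference and 95 % limits of agreement (mean +/- 1.96 sd)."""

    mean_difference: float
    sd_difference: float
    ci95: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not (lo <= self.mean_difference <= hi):
            raise ValidationError("limits of agreement must bracket the mean")


def bland_altman(values_method, values_reference) -> BlandAltmanStats:
    """Bland-Altman agreement of a method against a reference."""
    a = np.asarray(values_method, dtype=np.float64)
    b = np.asarray(values_reference, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("paired 1D samples required")
    if a.size < 2:
        raise ValidationError("need at least two pairs")
    d = a - b
    mean, sd = float(d.mean()), float(d.std(ddof=1))
    return BlandAltmanStats(mean, sd, (mean - 1.96 * sd, mean + 1.96 * sd))


def paired_tests(
    samples: dict[str, np.ndarray],
    comparisons: list[tuple[str, str]],
    alpha: float = 0.05,
    bonferroni: bool = True,
) -> pd.DataFrame:
    """Two-sided paired t-tests for each (method_a, method_b) comparison.

    Returns a table with the p-value, the (possibly Bonferroni-adjusted)
    significance threshold alpha/m, and a significance flag.  Zero-variance
    differences leave the p-value undefined (NaN) with a flag.
    """
    if not comparisons:
        raise ValidationError("no comparisons requested")
    m = len(comparisons)
    threshold = alpha / m if bonferroni else alpha
    rows = []
    for a_name, b_name in comparisons:
        a = np.asarray(samples[a_name], dtype=np.float64)
        b = np.asarray(samples[b_name], dtype=np.float64)
        if a.shape != b.shape or a.size < 2:
            raise ValidationError(f"paired samples of equal length >= 2 required "
                                  f"for ({a_name}, {b_name})")
        d = a - b
        if np.allclose(d.std(ddof=1), 0.0):
            rows.append((a_name, b_name, np.nan, threshold, False, True))
            continue
        t = stats.ttest_rel(a, b)
        rows.append((a_name, b_name, float(t.pvalue), threshold,
                     bool(t.pvalue < threshold), False))
    return pd.DataFrame(
        rows,
        columns=["method_a", "method_b", "p_value", "threshold", "significant",
                 "zero_variance"],
    )


@dataclass
class MetricsReport:
    """Per-subject metric rows plus per-method aggregates."""

    rows: pd.DataFrame  # columns: subject, method, nmse, ssim, sur, asi_percent

    REQUIRED = ("subject", "method", "nmse", "ssim", "sur", "asi_percent")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.rows.columns)
        if missing:
            raise ValidationError(f"report rows missing columns {sorted(missing)}")

    def aggregate(self) -> pd.DataFrame:
        """Mean +/- sd of each metric per method."""
        return self.rows.groupby("method")[["nmse", "ssim", "sur", "asi_percent"]].agg(
            ["mean", "std"]
        )

    def compare(
        self, metric: str, comparisons: list[tuple[str, str]], alpha: float = 0.05
    ) -> pd.DataFrame:
        wide = self.rows.pivot(index="subject", columns="method", values=metric)
        samples = {m: wide[m].to_numpy() for m in wide.columns}
        return paired_tests(samples, comparisons, alpha=alpha)

    def save(self, prefix) -> None:
        from pathlib import Path

        prefix = Path(prefix)
        self.rows.to_csv(prefix.with_suffix(".csv"), index=False)
        self.aggregate().to_json(prefix.with_suffix(".agg.json"))
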