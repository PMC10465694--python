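"""Scatter correction, bilinear CT conversion and Chang's method."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spectac import projector as P
from spectac.corrections import (
    BilinearModel,
    chang_first_order_factors,
    chang_mumap,
    ct_to_mumap,
    dew_scatter_correct,
    scanner_a,
    scanner_b,
)
from spectac.recon import ReconConfig, osem_reconstruct
from spectac.volume import ValidationError, Volume3D


def _mw(primary, scatter, pw=(126.0, 154.0), sw=(114.0, 126.0)):
    geom = P.Geometry(1, primary.shape[1], primary.shape[2], 0.4)
    return P.MultiWindowSinogram(primary, scatter, pw, sw, geom)


class TestScannerProfiles:
    def test_table_values(self):
        a, b = scanner_a(), scanner_b()
        assert (a.voxel_size_cm, b.voxel_size_cm) == (0.2761, 0.2697)
        assert a.primary_window_kev == b.primary_window_kev == (126.0, 154.0)
        assert a.scatter_window_kev == (114.0, 126.0)
        assert b.scatter_window_kev == (109.0, 126.0)
        assert (a.filter_sigma_voxels, b.filter_sigma_voxels) == (0.8, 1.2)
        assert a.n_views == 120
        assert a.osem == ReconConfig(iterations=8, subsets=4)


class TestDewScatterCorrect:
    def test_zero_scatter_window_leaves_primary_unchanged(self):
        primary = np.full((1, 4, 4), 7.0)
        out = dew_scatter_correct(_mw(primary, np.zeros_like(primary)))
        assert np.array_equal(out, primary)

    def test_scanner_a_windows_hand_arithmetic(self):
        """28 keV primary / 12 keV scatter widths, k=0.5, 12 scatter counts
        -> estimate 12 * (28/12) * 0.5 = 14."""
        primary = np.full((1, 2, 2), 20.0)
        scatter = np.full((1, 2, 2), 12.0)
        out = dew_scatter_correct(_mw(primary, scatter), k=0.5)
        assert np.allclose(out, 20.0 - 14.0)

    def test_overestimate_clamped_to_zero(self):
        primary = np.full((1, 2, 2), 5.0)
        scatter = np.full((1, 2, 2), 12.0)
        out = dew_scatter_correct(_mw(primary, scatter))
        assert np.all(out == 0.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.floats(0.0, 5.0), st.floats(0.0, 5.0), st.floats(0.1, 1.0))
    def test_linear_in_scatter_counts_below_clamp(self, s1, s2, k):
        primary = np.full((1, 1, 1), 1e6)  # far from the clamp
        est = lambda s: 1e6 - dew_scatter_correct(
            _mw(primary, np.full((1, 1, 1), s)), k=k
        )[0, 0, 0]
        assert est(s1) + est(s2) == pytest.approx(est(s1 + s2), abs=1e-6)

    def test_invalid_k_rejected(self):
        with pytest.raises(ValidationError):
            dew_scatter_correct(_mw(np.zeros((1, 1, 1)), np.zeros((1, 1, 1))), k=0.0)


class TestCtToMumap:
    @pytest.mark.parametrize("hu,mu", [(-1000.0, 0.0), (0.0, 0.150), (1000.0, 0.25)])
    def test_reference_points(self, hu, mu):
        ct = Volume3D(np.full((4, 4, 4), hu), 0.3, "HU")
        out = ct_to_mumap(ct, BilinearModel())
        assert np.allclose(out.data, mu)
        assert out.unit == "cm^-1"

    def test_skull_hu_lands_in_measured_range(self):
        ct = Volume3D(np.full((2, 2, 2), 1000.0), 0.3, "HU")
        mu = ct_to_mumap(ct).data[0, 0, 0]
        assert 0.21 <= mu <= 0.27

    def test_output_clamped_nonnegative(self):
        ct = Volume3D(np.full((2, 2, 2), -2000.0), 0.3, "HU")
        assert ct_to_mumap(ct).data.min() == 0.0

    def test_wrong_unit_rejected(self):
        with pytest.raises(ValidationError):
            ct_to_mumap(Volume3D(np.zeros((2, 2, 2)), 0.3, "counts"))

    def test_continuous_at_breakpoint(self):
        m = BilinearModel()
        below = m.hu_to_mu(np.array([-1e-9]))[0]
        above = m.hu_to_mu(np.array([+1e-9]))[0]
        assert below == pytest.approx(above, abs=1e-9)


class TestChangMumap:
    def _nac(self, n=24, value=10.0, voxel=0.2761):
        c = (n - 1) / 2
        ii, jj, kk = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
        ball = (ii - c) ** 2 + (jj - c) ** 2 + (kk - c) ** 2 <= (n / 3) ** 2
        return Volume3D(np.where(ball, value, 0.0), voxel, "counts"), ball

    @pytest.mark.parametrize("voxel,expected", [(0.2761, 0.0408), (0.2697, 0.0399)])
    def test_printed_per_voxel_coefficients(self, voxel, expected):
        nac, ball = self._nac(voxel=voxel)
        mu = chang_mumap(nac, threshold=2.0, mu_uniform_cm1=0.148)
        assert mu.unit == "voxel^-1"
        assert np.all(mu.data[ball] == expected)

    def test_all_zero_image_raises_empty_mask_error(self):
        nac = Volume3D(np.zeros((8, 8, 8)), 0.2761, "counts")
        with pytest.raises(ValidationError):
            chang_mumap(nac)

    def test_mask_grows_as_threshold_decreases(self):
        n = 24
        c = (n - 1) / 2
        ii, jj, kk = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
        r2 = (ii - c) ** 2 + (jj - c) ** 2 + (kk - c) ** 2
        nac = Volume3D(10.0 * np.exp(-r2 / (2 * 5.0**2)), 0.2761, "counts")
        sizes = [
            (chang_mumap(nac, threshold=t).data > 0).sum() for t in (8.0, 5.0, 2.0)
        ]
        assert sizes[0] < sizes[1] < sizes[2]

    def test_largest_component_kept_and_holes_filled(self):
        nac, ball = self._nac()
        data = nac.data.copy()
        data[1, 1, 1] = 50.0        # satellite speck
        data[11:13, 11:13, 11:13] = 0.0  # internal hole
        mu = chang_mumap(nac.with_data(data), threshold=2.0)
        mask = mu.data > 0
        assert not mask[1, 1, 1]
        assert mask[11, 11, 11]


class TestChangFirstOrderFactors:
    def test_zero_mu_gives_unit_factors(self):
        mask = np.ones((8, 8, 3), dtype=bool)
        f = chang_first_order_factors(mask, mu_uniform_cm1=0.0, voxel_size_cm=0.4)
        assert np.allclose(f, 1.0)

    def test_disc_centre_matches_closed_form(self):
        n, v, mu = 63, 0.4, 0.148
        c = (n - 1) // 2
        ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        disc = ((ii - c) ** 2 + (jj - c) ** 2 <= 12.4999**2)[:, :, None] & np.ones(3, bool)
        f = chang_first_order_factors(disc, mu, angles=64, voxel_size_cm=v)
        assert f[c, c, 1] == pytest.approx(np.exp(mu * 5.0), rel=5e-3)

    def test_factors_monotone_toward_disc_centre(self):
        n, v = 33, 0.4
        c = (n - 1) // 2
        ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        disc = ((ii - c) ** 2 + (jj - c) ** 2 <= 14.4**2)[:, :, None] & np.ones(3, bool)
        f = chang_first_order_factors(disc, 0.148, angles=32, voxel_size_cm=v)
        profile = f[c : c + 14, c, 1][::-1]  # rim -> centre
        assert np.all(np.diff(profile) >= -1e-6)

    def test_outside_mask_factor_is_one(self):
        mask = np.zeros((16, 16, 3), dtype=bool)
        mask[4:12, 4:12, :] = True
        f = chang_first_order_factors(mask, 0.148, angles=16, voxel_size_cm=0.4)
        assert np.allclose(f[~mask], 1.0)
        assert np.all(f[mask] >= 1.0)

    def test_too_few_angles_rejected(self):
        with pytest.raises(ValidationError):
            chang_first_order_factors(np.ones((4, 4, 1), bool), angles=2)


class TestChangVersusCtac:
    """Chang-AC matches CT-AC only while the uniform-mu assumption holds."""

    def _nmse_chang_vs_ctac(self, mu_skull):
        # tracer fills the whole head so the thresholded contour matches
        # the attenuating volume; only the shell mu changes between cases
        n, v = 24, 0.9
        c = (n - 1) / 2
        ii, jj, kk = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
        rb = np.array([7.65, 8.55, 7.65]) / v
        bb = np.array([5.85, 6.75, 5.85]) / v
        head = ((ii - c) / rb[0]) ** 2 + ((jj - c) / rb[1]) ** 2 + ((kk - c) / rb[2]) ** 2 <= 1.0
        brain = ((ii - c) / bb[0]) ** 2 + ((jj - c) / bb[1]) ** 2 + ((kk - c) / bb[2]) ** 2 <= 1.0
        mu = Volume3D(np.where(brain, 0.148, np.where(head, mu_skull, 0.0)), v, "cm^-1")
        emis = Volume3D(np.where(head, 10.0, 0.0), v, "counts")
        geom = P.Geometry(24, n, n, v)
        sino = P.forward_project(emis, mu, geom)
        ctac = osem_reconstruct(sino, mu, geom)
        nac = osem_reconstruct(sino, None, geom)
        chang_mu = chang_mumap(nac, threshold=2.0, voxel_size_cm=v)
        chang = osem_reconstruct(sino, chang_mu, geom)
        from spectac.metrics import nmse

        return nmse(chang, ctac, head)

    def test_uniform_head_reconstructs_like_ctac_but_skull_degrades_it(self):
        uniform = self._nmse_chang_vs_ctac(mu_skull=0.148)
        with_skull = self._nmse_chang_vs_ctac(mu_skull=0.24)
        assert uniform < 0.01
        assert with_skull > uniform
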