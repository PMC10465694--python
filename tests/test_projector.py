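"""Attenuated parallel-beam projector: adjointness, count conservation,
closed-form attenuation and acquisition simulation."""

import numpy as np
import pytest

from spectac import projector as P
from spectac.corrections import scanner_a
from spectac.volume import ValidationError, Volume3D


def _gaussian_blob(n, v, sigma_vox=4.0):
    c = (n - 1) / 2
    ii, jj, kk = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
    g = np.exp(-((ii - c) ** 2 + (jj - c) ** 2 + (kk - c) ** 2) / (2 * sigma_vox**2))
    return Volume3D(g, v, "counts")


class TestForwardProject:
    def test_zero_emission_gives_zero_sinogram(self):
        geom = P.Geometry(8, 16, 16, 0.4)
        emis = Volume3D(np.zeros((16, 16, 16)), 0.4, "counts")
        assert not P.forward_project(emis, None, geom).any()

    def test_unattenuated_projection_conserves_counts_per_view(self):
        n = 32
        geom = P.Geometry(16, n, n, 0.4)
        blob = _gaussian_blob(n, 0.4)
        sino = P.forward_project(blob, None, geom)
        totals = sino.sum(axis=(1, 2))
        assert np.allclose(totals, blob.data.sum(), rtol=1e-3)

    def test_central_voxel_attenuated_by_exp_mu_r(self):
        """Unit source at the centre of a uniform mu disc: every view reads
        exp(-mu R); checked against the closed form and a fine numerical
        quadrature of the line integral."""
        n, v, mu = 63, 0.4, 0.148
        c = (n - 1) // 2
        ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        r = np.sqrt((ii - c) ** 2 + (jj - c) ** 2)
        disc2d = r <= 12.4999  # half-voxel convention: path = 12.5 vox = 5 cm
        mumap = Volume3D(
            np.repeat(np.where(disc2d, mu, 0.0)[:, :, None], 5, axis=2), v, "cm^-1"
        )
        emis = np.zeros((n, n, 5))
        emis[c, c, 2] = 1.0
        geom = P.Geometry(4, n, 5, v)
        sino = P.forward_project(Volume3D(emis, v, "counts"), mumap, geom)
        view_totals = sino.sum(axis=(1, 2))
        closed_form = np.exp(-mu * 5.0)
        assert np.allclose(view_totals, closed_form, atol=1e-4)
        # independent quadrature oracle along the +y ray
        ys = np.linspace(0.0, (n - 1 - c) * v, 20001)
        mu_samples = np.where(ys <= 12.5 * v, mu, 0.0)
        quad = np.exp(-np.trapezoid(mu_samples, ys))
        assert view_totals[0] == pytest.approx(quad, abs=1e-4)

    def test_attenuation_monotonic_in_mu(self, uniform_disc):
        emission, mumap, geom, _ = uniform_disc
        s1 = P.forward_project(emission, mumap, geom)
        s2 = P.forward_project(emission, mumap.with_data(2 * mumap.data), geom)
        assert np.all(s2 <= s1 + 1e-12)

    def test_rotationally_symmetric_phantom_gives_equal_views(self):
        n = 32
        geom = P.Geometry(24, n, n, 0.4)
        blob = _gaussian_blob(n, 0.4)
        sino = P.forward_project(blob, None, geom)
        ref = sino[0]
        rms = np.sqrt(((sino - ref) ** 2).mean(axis=(1, 2))) / np.sqrt((ref**2).mean())
        assert rms.max() < 0.01

    def test_grid_mismatch_rejected(self):
        geom = P.Geometry(8, 16, 16, 0.4)
        emis = Volume3D(np.zeros((16, 16, 16)), 0.4, "counts")
        bad_mu = Volume3D(np.zeros((8, 8, 8)), 0.4, "cm^-1")
        with pytest.raises(ValidationError):
            P.forward_project(emis, bad_mu, geom)
        wrong_unit = Volume3D(np.zeros((16, 16, 16)), 0.4, "counts")
        with pytest.raises(ValidationError):
            P.forward_project(emis, wrong_unit, geom)


class TestBackProject:
    @pytest.mark.parametrize("n", [16, 32])
    def test_exact_adjoint_of_forward(self, n, rng):
        geom = P.Geometry(10, n, n, 0.4)
        mumap = Volume3D(rng.random((n, n, n)) * 0.2, 0.4, "cm^-1")
        x = Volume3D(rng.random((n, n, n)), 0.4, "counts")
        y = rng.random(geom.sinogram_shape())
        lhs = (P.forward_project(x, mumap, geom) * y).sum()
        rhs = (x.data * P.back_project(y, mumap, geom).data).sum()
        assert abs(lhs - rhs) / abs(lhs) < 1e-6

    def test_zero_sinogram_gives_zero_volume(self):
        geom = P.Geometry(8, 16, 16, 0.4)
        out = P.back_project(np.zeros(geom.sinogram_shape()), None, geom)
        assert not out.data.any()

    def test_uniform_sinogram_gives_symmetric_positive_volume(self):
        geom = P.Geometry(16, 24, 24, 0.5)
        out = P.back_project(np.ones(geom.sinogram_shape()), None, geom).data
        inner = out[4:-4, 4:-4, 4:-4]
        assert inner.min() > 0
        # in-plane mirror symmetry of the accumulated rotations
        assert np.allclose(inner, inner[::-1], rtol=0.02)


class TestSimulateAcquisition:
    def test_noiseless_scatterless_equals_forward_projection(self, uniform_disc):
        emission, mumap, geom, _ = uniform_disc
        profile = scanner_a().desk(matrix_size=32, n_views=32, voxel_size_cm=0.5)
        mw = P.simulate_acquisition(
            emission, mumap, profile, scatter_fraction=0.0, noise=False
        )
        assert np.allclose(mw.primary, P.forward_project(emission, mumap, geom))
        assert not mw.scatter.any()

    def test_fixed_seed_reproducible(self, uniform_disc):
        emission, mumap, _, _ = uniform_disc
        profile = scanner_a().desk(matrix_size=32, n_views=32, voxel_size_cm=0.5)
        a = P.simulate_acquisition(emission, mumap, profile, seed=5)
        b = P.simulate_acquisition(emission, mumap, profile, seed=5)
        assert np.array_equal(a.primary, b.primary)
        assert np.array_equal(a.scatter, b.scatter)

    def test_poisson_mean_matches_noiseless_projection(self, uniform_disc):
        emission, mumap, _, _ = uniform_disc
        profile = scanner_a().desk(matrix_size=32, n_views=8, voxel_size_cm=0.5)
        clean = P.simulate_acquisition(emission, mumap, profile, noise=False)
        n_rep = 200
        totals = np.array([
            P.simulate_acquisition(emission, mumap, profile, seed=s).primary.sum()
            for s in range(n_rep)
        ])
        expected = clean.primary.sum()
        sigma = np.sqrt(expected / n_rep)  # Poisson variance of the mean
        assert abs(totals.mean() - expected) < 3 * sigma

    def test_negative_counts_target_rejected(self, uniform_disc):
        emission, mumap, _, _ = uniform_disc
        profile = scanner_a().desk(matrix_size=32, n_views=8, voxel_size_cm=0.5)
        with pytest.raises(ValidationError):
            P.simulate_acquisition(emission, mumap, profile, total_counts=-1.0)

    def test_sinogram_roundtrip_via_archive(self, uniform_disc, tmp_path):
        emission, mumap, _, _ = uniform_disc
        profile = scanner_a().desk(matrix_size=32, n_views=8, voxel_size_cm=0.5)
        mw = P.simulate_acquisition(emission, mumap, profile, seed=1)
        mw.save(tmp_path / "sino.npz")
        back = P.MultiWindowSinogram.load(tmp_path / "sino.npz")
        assert np.array_equal(back.primary, mw.primary)
        assert back.geometry == mw.geometry
        assert back.primary_window_kev == mw.primary_window_kev

    def test_degenerate_window_rejected(self):
        geom = P.Geometry(4, 8, 8, 0.4)
        z = np.zeros(geom.sinogram_shape())
        with pytest.raises(ValidationError):
            P.MultiWindowSinogram(z, z, (126.0, 126.0), (114.0, 126.0), geom)
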