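"""Synthetic imagery: rendering, shot noise, scenes, holograms, propagation."""

import numpy as np
import pytest

from lodestar.simulate import (ComplexField, GridSpec, OpticalConfig,
                               SceneTruth, ShapeSpec, corrupt_with_noise,
                               default_shape, propagate_field, render_scene,
                               render_shape, rescale_scatter,
                               simulate_hologram)

GRID = GridSpec(64, 64)
CENTER = (31.5, 31.5)


class TestRenderShape:
    @pytest.mark.parametrize("kind", ["point", "sphere", "annulus", "ellipse", "crescent"])
    def test_deterministic_and_positive(self, kind):
        spec = default_shape(kind)
        a = render_shape(spec, CENTER, 0.3, GRID)
        b = render_shape(spec, CENTER, 0.3, GRID)
        assert np.array_equal(a, b)
        assert np.all(a > 0)

    def test_point_at_center_has_180_degree_symmetry(self):
        img = render_shape(default_shape("point"), CENTER, 0.0, GRID)
        assert np.allclose(img, np.rot90(img, 2), rtol=1e-10, atol=1e-10)

    def test_zero_amplitude_gives_flat_background(self):
        spec = default_shape("sphere", amplitude=0.0, background=50.0)
        img = render_shape(spec, CENTER, 0.0, GRID)
        assert np.allclose(img, 50.0)

    def test_integer_shift_matches_translated_rerender(self):
        spec = default_shape("sphere")
        a = render_shape(spec, (30.25, 29.75), 0.0, GRID)
        b = render_shape(spec, (31.25, 29.75), 0.0, GRID)
        # interior rows of the shifted render equal the original shifted by one row
        assert np.allclose(b[16:48, 16:48], a[15:47, 16:48], atol=1e-9)

    @pytest.mark.parametrize("kind", ["point", "sphere", "annulus", "ellipse", "crescent"])
    def test_flux_invariant_under_subpixel_shift(self, kind):
        spec = default_shape(kind)
        f0 = render_shape(spec, CENTER, 0.4, GRID).sum()
        f1 = render_shape(spec, (31.5 + 0.37, 31.5 - 0.21), 0.4, GRID).sum()
        assert abs(f1 - f0) / (f0 - 64 * 64 * spec.background + 1e-12) < 1e-3

    def test_errors(self):
        with pytest.raises(ValueError):
            ShapeSpec(kind="blob")
        with pytest.raises(ValueError):
            render_shape(default_shape("point"), (80.0, 10.0), 0.0, GRID)
        with pytest.raises(ValueError):
            render_shape(default_shape("sphere", radius=40.0), CENTER, 0.0, GRID)
        with pytest.raises(ValueError):
            ShapeSpec(kind="point", background=0.0)


class TestCorruptWithNoise:
    def test_deterministic_given_seed(self):
        nu = render_shape(default_shape("point"), CENTER, 0.0, GRID)
        a = corrupt_with_noise(nu, 10.0, np.random.default_rng(3))
        b = corrupt_with_noise(nu, 10.0, np.random.default_rng(3))
        assert np.array_equal(a, b)

    def test_poisson_mean_and_variance(self, rng):
        nu = render_shape(default_shape("point"), CENTER, 0.0, GRID)
        peak = np.unravel_index(np.argmax(nu), nu.shape)
        n = 10_000
        bg = nu.min()
        scale = 10.0 * np.sqrt(bg) / (nu.max() - bg)
        expected = bg + (nu[peak] - bg) * scale
        samples = np.array([corrupt_with_noise(nu, 10.0, rng)[peak] for _ in range(n)])
        se = np.sqrt(expected / n)
        assert abs(samples.mean() - expected) < 3 * se
        # variance ~ mean for Poisson
        assert abs(samples.var() / expected - 1.0) < 0.06

    def test_snr_definition(self, rng):
        nu = render_shape(default_shape("point"), CENTER, 0.0, GRID)
        bg = nu.min()
        peak_idx = np.unravel_index(np.argmax(nu), nu.shape)
        n = 1000
        peaks = [corrupt_with_noise(nu, 10.0, rng)[peak_idx] for _ in range(n)]
        measured_snr = (np.mean(peaks) - bg) / np.sqrt(bg)
        se = np.sqrt((bg + 10.0 * np.sqrt(bg)) / n) / np.sqrt(bg)
        assert abs(measured_snr - 10.0) < 3 * se

    def test_rejects_nonpositive(self, rng):
        with pytest.raises(ValueError):
            corrupt_with_noise(np.zeros((16, 16)), 10.0, rng)


class TestRenderScene:
    def test_single_particle_matches_pipeline(self):
        truth = SceneTruth.from_records([{"x": 30.0, "y": 33.0, "orientation": 0.0}])
        spec = default_shape("sphere")
        img, _ = render_scene(truth, spec, GRID, 10.0, np.random.default_rng(5))
        ref = corrupt_with_noise(render_shape(spec, (30.0, 33.0), 0.0, GRID), 10.0,
                                 np.random.default_rng(5), background=spec.background)
        assert np.array_equal(img, ref)

    def test_separated_particles_match_single_renders_locally(self):
        truth = SceneTruth.from_records([
            {"x": 16.0, "y": 16.0}, {"x": 47.0, "y": 47.0},
        ])
        spec = default_shape("point")
        nu, _ = render_scene(truth, spec, GRID, None)
        single = render_shape(spec, (16.0, 16.0), 0.0, GRID)
        assert np.allclose(nu[9:24, 9:24], single[9:24, 9:24], rtol=1e-6)

    def test_many_particles_truth_passthrough(self, rng):
        grid = GridSpec(256, 256)
        recs = [{"x": rng.uniform(20, 235), "y": rng.uniform(20, 235)} for _ in range(20)]
        truth = SceneTruth.from_records(recs)
        img, out = render_scene(truth, default_shape("sphere"), grid, 10.0, rng)
        assert len(out) == 20
        assert img.shape == (256, 256)
        assert np.all(out.positions() >= 0) and np.all(out.positions() <= 255)

    def test_empty_scene_rejected(self, rng):
        with pytest.raises(ValueError):
            render_scene(SceneTruth.from_records([]), default_shape("point"), GRID, 10.0, rng)


OPTICS = OpticalConfig()
HGRID = GridSpec(64, 64, OPTICS.pixel_size)


class TestHologram:
    def test_noise_only_rayleigh_statistics(self, rng):
        truth = SceneTruth.from_records([{"x": 31.5, "y": 31.5, "scale": 0.0,
                                          "radius": 0.228, "refractive_index": 1.5}])
        fld, _ = simulate_hologram(truth, OPTICS, snr=10.0, rng=rng, grid=HGRID)
        dev = np.abs(fld.values - 1.0)
        # |field - bg| is Rayleigh(sigma): mean = sigma*sqrt(pi/2)
        expected = fld.sigma * np.sqrt(np.pi / 2.0)
        assert abs(dev.mean() - expected) / expected < 0.05

    def test_in_focus_particle_peaks_in_imaginary_part(self, rng):
        truth = SceneTruth.from_records([{"x": 30.0, "y": 34.0, "z": 0.0,
                                          "radius": 0.228, "refractive_index": 1.5}])
        fld, _ = simulate_hologram(truth, OPTICS, snr=None, grid=HGRID)
        peak = np.unravel_index(np.argmax(np.abs(fld.imag)), fld.imag.shape)
        assert abs(peak[0] - 30.0) <= 0.5 and abs(peak[1] - 34.0) <= 0.5

    def test_scatter_linearity(self):
        base = [{"x": 31.5, "y": 31.5, "radius": 0.228, "refractive_index": 1.5}]
        f1, _ = simulate_hologram(SceneTruth.from_records(base), OPTICS, snr=None, grid=HGRID)
        doubled = [dict(base[0], scale=2.0)]
        f2, _ = simulate_hologram(SceneTruth.from_records(doubled), OPTICS, snr=None, grid=HGRID)
        assert np.allclose(f2.values - 1.0, 2.0 * (f1.values - 1.0), rtol=1e-10)

    def test_na_validation(self, rng):
        bad = OpticalConfig(numerical_aperture=1.4, n_medium=1.33)
        with pytest.raises(ValueError):
            simulate_hologram(SceneTruth.from_records([{"x": 1.0, "y": 1.0}]), bad,
                              snr=None, grid=HGRID)


class TestPropagation:
    def _field(self, rng):
        truth = SceneTruth.from_records([{"x": 31.5, "y": 31.5, "radius": 0.228,
                                          "refractive_index": 1.5}])
        fld, _ = simulate_hologram(truth, OPTICS, snr=None, grid=HGRID)
        return fld

    def test_zero_distance_is_identity(self, rng):
        fld = self._field(rng)
        out = propagate_field(fld, 0.0, OPTICS)
        assert np.allclose(out.values, fld.values, atol=1e-10)

    def test_roundtrip_unitarity(self, rng):
        fld = self._field(rng)
        out = propagate_field(propagate_field(fld, 1.5, OPTICS), -1.5, OPTICS)
        err = np.abs(out.values - fld.values).max() / np.abs(fld.values).max()
        assert err < 1e-8

    def test_energy_conserved_on_propagating_band(self, rng):
        fld = self._field(rng)
        out = propagate_field(fld, 2.0, OPTICS)
        # the scattered spectrum lives inside the NA circle, well below cutoff
        assert abs((np.abs(out.values) ** 2).sum() - (np.abs(fld.values) ** 2).sum()) / (
            np.abs(fld.values) ** 2
        ).sum() < 1e-6

    def test_gaussian_beam_expansion(self):
        # analytic check: 1/e field radius w0 grows as w0*sqrt(1+(dz/zR)^2)
        n = 128
        grid_px = 0.114
        coords = (np.arange(n) - n / 2) * grid_px
        xx, yy = np.meshgrid(coords, coords, indexing="ij")
        w0 = 1.0
        envelope = np.exp(-(xx**2 + yy**2) / w0**2).astype(complex)
        fld = ComplexField.from_complex(envelope, background=0.0, pixel_size=grid_px)
        dz = 4.0
        out = propagate_field(fld, dz, OPTICS)
        z_r = np.pi * w0**2 * OPTICS.n_medium / OPTICS.wavelength
        expected = w0 * np.sqrt(1.0 + (dz / z_r) ** 2)
        inten = np.abs(out.values) ** 2
        var = (inten * xx**2).sum() / inten.sum()
        measured = np.sqrt(4.0 * var)  # <x^2> of |E|^2 is w^2/4
        assert abs(measured - expected) / expected < 0.01


class TestRescaleScatter:
    def _field(self):
        truth = SceneTruth.from_records([{"x": 31.5, "y": 31.5, "radius": 0.228,
                                          "refractive_index": 1.5}])
        fld, _ = simulate_hologram(truth, OPTICS, snr=None, grid=HGRID)
        return fld

    def test_identity_and_inverse(self):
        fld = self._field()
        assert np.allclose(rescale_scatter(fld, 1.0).values, fld.values)
        back = rescale_scatter(rescale_scatter(fld, 2.0), 0.5)
        assert np.allclose(back.values, fld.values, rtol=1e-12)

    def test_linearity_and_background_fixed(self):
        fld = self._field()
        out = rescale_scatter(fld, 3.0)
        assert np.isclose(np.abs(out.values - 1.0).max(), 3.0 * np.abs(fld.values - 1.0).max())

    def test_rejects_nonpositive_scale(self):
        with pytest.raises(ValueError):
            rescale_scatter(self._field(), 0.0)
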