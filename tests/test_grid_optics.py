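import numpy as np
import pytest
from hypothesis import given, strategies as st

import lensless_qpi as q
from lensless_qpi.grid_optics import ComplexField

from conftest import brute_force_convolution, PIXEL, WAVELENGTH


class TestMakeGrid:
    def test_sensor_scale_camera(self):
        # the 1024 x 768 camera at 4.65 um pitch doubles to 2048 x 1536
        g = q.make_grid(1024, 768, 4.65e-6, 530e-9)
        assert g.shape == (2048, 1536)
        assert g.pixel == pytest.approx(4.65e-6)

    def test_origin_sample_is_zero(self):
        g = q.make_grid(8, 8, 1e-6, 5e-7)
        assert g.X[g.center_index] == 0.0
        assert g.Y[g.center_index] == 0.0

    def test_coordinate_extent(self):
        # indices -16..15 at 2 um pitch span 31 pitches
        g = q.make_grid(16, 16, 2e-6, 5e-7)
        assert g.X.max() - g.X.min() == pytest.approx(31 * 2e-6)
        assert np.array_equal(g.x, np.arange(-16, 16))

    @pytest.mark.parametrize("bad", [
        dict(n1=7, n2=8), dict(n1=8, n2=9), dict(n1=0, n2=8),
        dict(n1=-8, n2=8), dict(n1=6, n2=6),
    ])
    def test_rejects_odd_or_small_dimensions(self, bad):
        with pytest.raises(ValueError):
            q.make_grid(pixel=1e-6, wavelength=5e-7, **bad)

    @pytest.mark.parametrize("pixel,wavelength", [(0, 5e-7), (1e-6, 0),
                                                  (-1e-6, 5e-7)])
    def test_rejects_nonpositive_scales(self, pixel, wavelength):
        with pytest.raises(ValueError):
            q.make_grid(8, 8, pixel, wavelength)


class TestKernels:
    @given(d=st.floats(min_value=1e-3, max_value=10.0))
    def test_spherical_kernel_unit_modulus(self, d):
        g = q.make_grid(8, 8, PIXEL, WAVELENGTH)
        k = q.spherical_kernel(g, d)
        assert np.max(np.abs(np.abs(k.values) - 1.0)) < 1e-12

    def test_spherical_conjugate_symmetry(self, grid16):
        kf = q.spherical_kernel(grid16, 0.05)
        kb = q.spherical_kernel(grid16, -0.05)
        np.testing.assert_allclose(kb.values, np.conj(kf.values), rtol=0, atol=1e-14)

    def test_spherical_origin_phase(self, grid16):
        d = 0.05
        k = q.spherical_kernel(grid16, d)
        expected = np.exp(1j * 2 * np.pi * d / grid16.wavelength)
        assert k.values[grid16.center_index] == pytest.approx(expected)

    def test_spherical_offaxis_sample_matches_formula(self):
        # scalar evaluation of exp(j 2 pi sqrt(x^2 + d^2) / lambda) at
        # a 100-pixel offset along one axis
        g = q.make_grid(128, 128, 4.65e-6, 530e-9)
        d = 0.05
        k = q.spherical_kernel(g, d)
        i = g.center_index[0] + 100
        r = np.sqrt((100 * 4.65e-6) ** 2 + d**2)
        assert k.values[i, g.center_index[1]] == pytest.approx(
            np.exp(1j * 2 * np.pi * r / 530e-9))

    def test_spherical_rejects_zero_distance(self, grid16):
        with pytest.raises(ValueError):
            q.spherical_kernel(grid16, 0.0)

    def test_quadratic_zero_curvature_is_identity(self, grid16):
        k = q.quadratic_phase(grid16, 0.0)
        np.testing.assert_array_equal(k.values, np.ones(grid16.shape))

    def test_quadratic_conjugation(self, grid16):
        kp = q.quadratic_phase(grid16, 50.0)
        km = q.quadratic_phase(grid16, -50.0)
        np.testing.assert_allclose(km.values, np.conj(kp.values), atol=1e-14)

    def test_quadratic_matches_spherical_in_paraxial_region(self):
        # within X^2+Y^2 << d^2 the spherical kernel reduces to
        # Q(1/d) times the constant exp(j 2 pi d / lambda)
        g = q.make_grid(32, 32, 1e-6, 5e-7)
        d = 1.0
        sph = q.spherical_kernel(g, d).values
        quad = q.quadratic_phase(g, 1.0 / d).values
        const = np.exp(1j * 2 * np.pi * d / g.wavelength)
        np.testing.assert_allclose(sph, quad * const, rtol=0, atol=1e-5)


class TestPropagate:
    def test_matches_brute_force_convolution(self, grid16):
        rng = np.random.default_rng(11)
        f = ComplexField(rng.normal(size=grid16.shape)
                         + 1j * rng.normal(size=grid16.shape), grid16)
        k = q.spherical_kernel(grid16, 0.01)
        out = q.propagate(f, k, exact_spectrum=False)
        oracle = brute_force_convolution(f.values, k.values)
        oracle *= np.sqrt(np.sum(np.abs(f.values) ** 2)
                          / np.sum(np.abs(oracle) ** 2))
        err = np.linalg.norm(out.values - oracle) / np.linalg.norm(oracle)
        assert err < 1e-6

    def test_round_trip_is_identity(self, grid16):
        rng = np.random.default_rng(3)
        f = ComplexField(rng.normal(size=grid16.shape)
                         + 1j * rng.normal(size=grid16.shape), grid16)
        fwd = q.propagate(f, q.spherical_kernel(grid16, 0.05))
        back = q.propagate(fwd, q.spherical_kernel(grid16, -0.05))
        err = (np.linalg.norm((back.values - f.values)[grid16.central_block])
               / np.linalg.norm(f.values[grid16.central_block]))
        assert err < 0.01

    def test_plane_wave_stays_uniform(self, grid256):
        f = ComplexField(np.ones(grid256.shape, complex), grid256)
        out = q.propagate(f, q.spherical_kernel(grid256, 0.1))
        n1, n2 = grid256.center_index
        quarter = out.intensity[n1 - 64:n1 + 64, n2 - 64:n2 + 64]
        assert quarter.max() / quarter.min() < 1.01

    def test_power_conservation(self, grid16):
        rng = np.random.default_rng(5)
        f = ComplexField(rng.normal(size=grid16.shape)
                         + 1j * rng.normal(size=grid16.shape), grid16)
        out = q.propagate(f, q.spherical_kernel(grid16, 0.02))
        assert out.power == pytest.approx(f.power, rel=1e-10)

    def test_paraxial_and_spherical_agree_on_smooth_fields(self):
        # grid extent (64 um) far below d = 0.5 m: the Fresnel kernel is an
        # excellent approximation and central intensities must agree
        g = q.make_grid(16, 16, 2e-6, 5e-7)
        x = np.linspace(-2, 2, g.shape[0])
        gauss = np.exp(-np.add.outer(x**2, x**2))
        f = ComplexField(gauss.astype(complex), g)
        d = 0.5
        s = q.propagate(f, q.spherical_kernel(g, d)).intensity
        p = q.propagate(f, q.quadratic_phase(g, 1.0 / d)).intensity
        cb = g.central_block
        err = np.sqrt(np.mean((s[cb] - p[cb]) ** 2)) / s[cb].max()
        assert err < 0.01

    def test_shape_mismatch_raises(self, grid16, grid256):
        f = ComplexField(np.ones(grid16.shape, complex), grid16)
        with pytest.raises(ValueError):
            q.propagate(f, q.spherical_kernel(grid256, 0.1))


class TestForwardModel:
    def test_point_source_unit_modulus(self, grid16):
        f = q.point_source_illumination(grid16, 2.0)
        np.testing.assert_allclose(np.abs(f.values), 1.0, atol=1e-12)

    def test_far_source_is_quasi_plane(self, grid16):
        f = q.point_source_illumination(grid16, 100.0)
        phase = np.angle(f.values * np.conj(f.values[grid16.center_index]))
        assert np.ptp(phase) < 0.1

    def test_illumination_edge_phase_matches_formula(self, grid16):
        d1 = 0.5
        f = q.point_source_illumination(grid16, d1)
        r_edge = np.sqrt(grid16.X[0, 0] ** 2 + grid16.Y[0, 0] ** 2 + d1**2)
        assert f.values[0, 0] == pytest.approx(
            np.exp(1j * 2 * np.pi * r_edge / grid16.wavelength))

    def test_illumination_rejects_nonpositive_distance(self, grid16):
        with pytest.raises(ValueError):
            q.point_source_illumination(grid16, 0.0)

    def test_phase_object_zero_phase_is_identity(self, grid16):
        f = q.point_source_illumination(grid16, 1.0)
        out = q.apply_phase_object(f, np.zeros(grid16.sensor_shape))
        np.testing.assert_array_equal(out.values, f.values)

    def test_phase_object_preserves_modulus(self, grid16):
        rng = np.random.default_rng(0)
        f = ComplexField(rng.normal(size=grid16.shape)
                         + 1j * rng.normal(size=grid16.shape), grid16)
        phi = rng.uniform(0, 2 * np.pi, grid16.sensor_shape)
        out = q.apply_phase_object(f, phi)
        np.testing.assert_allclose(np.abs(out.values), np.abs(f.values),
                                   atol=1e-12)

    def test_phase_object_inverts(self, grid16):
        f = q.point_source_illumination(grid16, 1.0)
        phi = np.full(grid16.sensor_shape, 0.7)
        restored = q.apply_phase_object(q.apply_phase_object(f, phi), -phi)
        np.testing.assert_allclose(restored.values, f.values, atol=1e-12)

    def test_sensor_intensity_range(self, grid256, disc_phase_halfpi):
        f = q.point_source_illumination(grid256, 100.0)
        f = q.apply_phase_object(f, disc_phase_halfpi)
        intensity = q.sensor_intensity(f, 0.2)
        assert intensity.shape == grid256.sensor_shape
        assert intensity.min() >= 0.0
        assert intensity.max() == pytest.approx(1.0)

    def test_zero_phase_object_gives_uniform_frame(self, grid256):
        f = q.point_source_illumination(grid256, 100.0)
        intensity = q.sensor_intensity(f, 0.2)
        quarter = intensity[96:160, 96:160]
        assert quarter.max() - quarter.min() < 0.02

    def test_sensor_intensity_matches_convolution_oracle(self, grid16):
        f = q.point_source_illumination(grid16, 10.0)
        phi = np.zeros(grid16.sensor_shape)
        phi[6:10, 6:10] = 1.0
        f = q.apply_phase_object(f, phi)
        d2 = 0.01
        got = q.sensor_intensity(f, d2)
        oracle = brute_force_convolution(
            f.values, q.spherical_kernel(grid16, d2).values)
        oracle_i = np.abs(oracle[grid16.central_block]) ** 2
        oracle_i /= oracle_i.max()
        # oracle path uses the raw sampled-kernel spectrum
        raw = q.propagate(f, q.spherical_kernel(grid16, d2),
                          exact_spectrum=False)
        raw_i = np.abs(raw.values[grid16.central_block]) ** 2
        raw_i /= raw_i.max()
        np.testing.assert_allclose(raw_i, oracle_i, rtol=0, atol=1e-6)
        assert got.shape == oracle_i.shape

    def test_sensor_intensity_rejects_nonpositive_distance(self, grid16):
        f = q.point_source_illumination(grid16, 1.0)
        with pytest.raises(ValueError):
            q.sensor_intensity(f, -0.1)
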