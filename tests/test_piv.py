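import warnings

import numpy as np
import pytest
from scipy import ndimage as ndi

from lvphantom.flowfield import (
    ParticleImageSpec,
    VortexSpec,
    make_velocity_field,
    render_particle_pair,
)
from lvphantom.piv import (
    VectorField2D,
    background_subtract,
    correlate_pass,
    displacements_to_velocity,
    ensemble_average,
    fill_holes,
    multipass,
    validate_vectors,
)


def _uniform_pair(u_px, v_px=0.0, seed=0, spec=None):
    """Particle pair under uniform translation of (u_px, v_px) pixels."""
    spec = spec or ParticleImageSpec(image_px=(192, 192), magnification=0.25)
    # constant field in m/s chosen so displacement over dt=1 ms is u_px
    ux = u_px * spec.magnification / 1e-3 * 1e-3
    vy = v_px * spec.magnification / 1e-3 * 1e-3

    def field(x, y):
        x = np.asarray(x, float)
        return np.full_like(x, ux), np.full_like(x, vy)

    return render_particle_pair(field, dt=1e-3, spec=spec, seed=seed), spec


class TestBackgroundSubtract:
    def test_constant_image_goes_to_zero(self):
        assert np.allclose(background_subtract(np.full((32, 32), 0.4)), 0.0)

    def test_particle_peaks_survive_offset_removal(self):
        # sparse Gaussian particles on a flat 0.2 pedestal
        yy, xx = np.mgrid[:64, :64]
        img = np.zeros((64, 64))
        for cx, cy in [(12, 20), (40, 9), (30, 50)]:
            img += 0.5 * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * 0.8**2))
        cleaned = background_subtract(img + 0.2, scale=5)
        assert cleaned.max() == pytest.approx(img.max(), rel=0.05)

    def test_zero_scale_rejected(self):
        with pytest.raises(ValueError):
            background_subtract(np.zeros((8, 8)), scale=0)


class TestCorrelation:
    def test_integer_shift_recovery(self):
        (a, b), _ = _uniform_pair(6.0)
        f = multipass(a, b)
        interior = (slice(1, -1), slice(1, -1))
        assert np.abs(f.u[interior] - 6.0).max() < 0.05
        assert np.abs(f.v[interior]).max() < 0.05

    def test_subpixel_shift_recovery(self):
        (a, b), _ = _uniform_pair(6.3, seed=4)
        f = multipass(a, b)
        interior = (slice(1, -1), slice(1, -1))
        assert np.mean(f.u[interior]) == pytest.approx(6.3, abs=0.1)

    def test_identical_images_zero_field(self):
        (a, _), _ = _uniform_pair(0.0, seed=1)
        f = multipass(a, a)
        assert np.abs(f.u).max() < 1e-9
        assert np.abs(f.v).max() < 1e-9

    def test_shift_invariance(self):
        (a, b), _ = _uniform_pair(6.0, seed=2)
        f0 = multipass(a, b)
        a2 = np.roll(a, (16, 16), axis=(0, 1))
        b2 = np.roll(b, (16, 16), axis=(0, 1))
        f1 = multipass(a2, b2)
        interior = (slice(1, -1), slice(1, -1))
        assert np.allclose(f0.u[interior], f1.u[interior], atol=0.05)

    def test_zero_variance_window_invalid(self):
        rng = np.random.default_rng(0)
        a = np.zeros((128, 128))
        a[:, 64:] = rng.uniform(0, 1, (128, 64))
        f = correlate_pass(a, a, window=64, overlap=0.0)
        assert not f.valid[0, 0]  # blank half
        assert f.valid[0, 1]

    def test_oversized_window_rejected(self):
        with pytest.raises(ValueError):
            correlate_pass(np.zeros((32, 32)), np.zeros((32, 32)), window=64)


class TestValidationAndFilling:
    @staticmethod
    def _linear_field():
        x = np.arange(0, 160, 16.0)
        y = np.arange(0, 160, 16.0)
        gy, gx = np.meshgrid(y, x, indexing="ij")
        u = 0.01 * gx + 0.02 * gy
        v = -0.015 * gx + 0.005 * gy
        q = np.full(u.shape, 2.0)
        return VectorField2D(x, y, u, v, q, np.ones(u.shape, bool), 32, 0.5)

    def test_high_q_vectors_survive(self):
        f = self._linear_field()
        assert validate_vectors(f, 1.2).valid.all()

    def test_low_q_vector_deleted_then_filled(self):
        f = self._linear_field()
        f.q[4, 4] = 1.05
        g = validate_vectors(f, 1.2)
        assert not g.valid[4, 4]
        h = fill_holes(g)
        assert h.valid.all()

    def test_interior_hole_filled_by_linear_interpolant(self):
        f = self._linear_field()
        truth = f.u[5, 5]
        f.valid[5, 5] = False
        f.u[5, 5] = 999.0
        h = fill_holes(f)
        assert h.u[5, 5] == pytest.approx(truth, abs=1e-6)


class TestEnsemble:
    @staticmethod
    def _field(u, valid=None):
        x = np.arange(4.0)
        y = np.arange(3.0)
        shape = (3, 4)
        return VectorField2D(
            x, y, np.full(shape, float(u)), np.zeros(shape), np.full(shape, 2.0),
            np.ones(shape, bool) if valid is None else valid, 32, 0.5,
        )

    def test_identical_fields_mean(self):
        mean, count = ensemble_average([self._field(3.0)] * 200)
        assert np.allclose(mean.u, 3.0)
        assert (count == 200).all()

    def test_noise_reduction_rate(self):
        rng = np.random.default_rng(0)
        sigma = 0.5
        fields = [self._field(5.0 + rng.normal(0, sigma)) for _ in range(200)]
        mean, _ = ensemble_average(fields)
        # residual of the node mean ~ sigma / sqrt(200)
        assert abs(mean.u[0, 0] - 5.0) < 4 * sigma / np.sqrt(200)

    def test_node_invalid_everywhere_stays_invalid(self):
        bad = np.ones((3, 4), bool)
        bad[1, 2] = False
        mean, count = ensemble_average([self._field(1.0, valid=bad)] * 5)
        assert not mean.valid[1, 2]
        assert count[1, 2] == 0


class TestVelocityConversion:
    def test_unit_arithmetic(self):
        f = TestEnsemble._field(6.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            g = displacements_to_velocity(f, dt=600e-6, magnification=0.1)
        assert np.allclose(g.u_ms, 1.0)

    def test_zero_dt_rejected(self):
        with pytest.raises(ValueError):
            displacements_to_velocity(TestEnsemble._field(6.0), dt=0.0, magnification=0.1)

    def test_median_displacement_warning(self):
        f = TestEnsemble._field(2.0)  # below the 5-8 px design band
        with pytest.warns(UserWarning, match="5-8"):
            displacements_to_velocity(f, dt=1e-3, magnification=0.1)


class TestJetVortexRecovery:
    def test_field_peak_speed_is_the_jet_speed(self):
        vf = make_velocity_field(jet_speed=1.15)
        _, _, u, v = vf.sample(161, 161)
        assert np.hypot(u, v).max() == pytest.approx(1.15, rel=0.01)

    def test_zero_jet_no_vortices_identical_pair(self):
        vf = make_velocity_field(jet_speed=0.0, vortex_spec=None)
        a, b = render_particle_pair(vf, dt=1e-3, seed=0)
        assert np.array_equal(a, b)

    def test_ensemble_rms_below_5_percent_of_peak(self, piv_ensemble):
        vf, mean, spec = piv_ensemble["field"], piv_ensemble["mean"], piv_ensemble["spec"]
        d = vf.domain
        gx = d[0] + mean.x * spec.magnification
        gy = d[2] + mean.y * spec.magnification
        ut, vt = vf(*np.meshgrid(gx, gy))
        rms = np.sqrt(np.nanmean((mean.u_ms - ut) ** 2 + (mean.v_ms - vt) ** 2))
        assert rms / 1.15 < 0.05

    def test_peak_speed_recovered_within_3_percent(self, piv_ensemble):
        mean = piv_ensemble["mean"]
        speed = np.hypot(mean.u_ms, mean.v_ms)
        assert np.nanmax(speed) == pytest.approx(1.15, rel=0.03)

    def test_counter_rotating_vortices_flank_the_jet(self, piv_ensemble):
        mean, spec, vf = piv_ensemble["mean"], piv_ensemble["spec"], piv_ensemble["field"]
        dx = (mean.x[1] - mean.x[0]) * spec.magnification * 1e-3  # m
        u = np.nan_to_num(mean.u_ms)
        v = np.nan_to_num(mean.v_ms)
        vort = np.gradient(v, axis=1) / dx - np.gradient(u, axis=0) / dx
        jmax = np.unravel_index(np.argmax(vort), vort.shape)
        jmin = np.unravel_index(np.argmin(vort), vort.shape)
        x_pos = vf.domain[0] + mean.x[jmax[1]] * spec.magnification
        x_neg = vf.domain[0] + mean.x[jmin[1]] * spec.magnification
        assert x_pos * x_neg < 0  # opposite sides of the jet axis
        assert abs(abs(x_pos) - vf.vortices.separation_mm / 2) < 5.0
        assert abs(abs(x_neg) - vf.vortices.separation_mm / 2) < 5.0

    def test_displacement_in_design_band(self, piv_ensemble):
        mean = piv_ensemble["mean"]
        assert 5.0 <= np.nanmax(np.hypot(mean.u, mean.v)) <= 8.0
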