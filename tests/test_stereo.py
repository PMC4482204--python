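import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from lvphantom.camera import default_rig, make_calibration_target, make_camera
from lvphantom.geometry import deform_to_volume, volume_of
from lvphantom.markers import outer_surface_params
from lvphantom.stereo import (
    cloud_to_volume,
    dlt_fit,
    dlt_project,
    ensemble_average_cycles,
    ldlt_fit,
    mirror_cloud,
    triangulate,
    triangulate_many,
)
from lvphantom.stereo import calibrate_global


@pytest.fixture(scope="module")
def pinhole_cam():
    return make_camera("c", (600.0, 80.0, 35.0), (0.0, 0.0, 35.0))


@pytest.fixture(scope="module")
def control_points():
    rng = np.random.default_rng(7)
    return rng.uniform([-30, -30, 0], [30, 30, 80], size=(40, 3))


class TestDLT:
    def test_noiseless_reprojection(self, pinhole_cam, control_points):
        uv, _ = pinhole_cam.project(control_points)
        fit = dlt_fit(control_points, uv)
        assert fit.rms_px < 1e-6

    def test_noise_propagates_to_rms(self, pinhole_cam, control_points):
        rng = np.random.default_rng(1)
        uv, _ = pinhole_cam.project(control_points)
        fit = dlt_fit(control_points, uv + rng.normal(0, 0.5, uv.shape))
        assert 0.3 < fit.rms_px < 0.7

    def test_underdetermined_rejected(self, pinhole_cam, control_points):
        uv, _ = pinhole_cam.project(control_points[:5])
        with pytest.raises(ValueError, match="6 control points"):
            dlt_fit(control_points[:5], uv[:5])

    def test_coplanar_rejected(self, pinhole_cam):
        pts = np.random.default_rng(0).uniform(-30, 30, (20, 3))
        pts[:, 2] = 10.0
        uv, _ = pinhole_cam.project(pts)
        with pytest.raises(ValueError, match="coplanar"):
            dlt_fit(pts, uv)


class TestLDLT:
    def test_single_cell_matches_global(self):
        rig = default_rig()
        tgt = make_calibration_target(rig)
        loc = ldlt_fit(tgt, cell_spec=(1, 1, 1), margin=0.0)
        glob = calibrate_global(tgt)
        for cam in ("cam1", "cam2"):
            assert np.allclose(loc.local_coeffs[cam][0].L, glob.global_coeffs[cam].L, rtol=1e-9)

    def test_localized_beats_global_under_distortion(self):
        rig = default_rig(distortion_amplitude_px=2.0, seed=5)
        tgt = make_calibration_target(rig)
        loc = ldlt_fit(tgt, cell_spec=(3, 3, 3))
        for cam in ("cam1", "cam2"):
            global_rms = loc.global_coeffs[cam].rms_px
            local_mean = np.mean([c.rms_px for c in loc.local_coeffs[cam]])
            assert local_mean < global_rms

    def test_empty_cell_reported(self):
        rig = default_rig()
        tgt = make_calibration_target(rig, plane_x=[0.0, 10.0])
        with pytest.raises(ValueError, match="cell"):
            ldlt_fit(tgt, cell_spec=(6, 1, 1), margin=0.0)


class TestTriangulate:
    def test_noiseless_reconstruction(self, control_points):
        rig = default_rig()
        tgt = make_calibration_target(rig)
        calib = calibrate_global(tgt)
        uv1, _ = rig[0].project(control_points)
        uv2, _ = rig[1].project(control_points)
        pts, _ = triangulate_many(uv1, uv2, calib)
        assert np.abs(pts - control_points).max() < 1e-6

    def test_noise_monte_carlo_accuracy(self, control_points):
        rig = default_rig()
        tgt = make_calibration_target(rig)
        calib = calibrate_global(tgt)
        rng = np.random.default_rng(11)
        uv1, _ = rig[0].project(control_points)
        uv2, _ = rig[1].project(control_points)
        errs = []
        for _ in range(10):
            p, _ = triangulate_many(
                uv1 + rng.normal(0, 0.5, uv1.shape), uv2 + rng.normal(0, 0.5, uv2.shape), calib
            )
            errs.append(np.linalg.norm(p - control_points, axis=1))
        assert np.sqrt(np.mean(np.concatenate(errs) ** 2)) < 0.5

    def test_localized_triangulation_not_worse_than_global(self, control_points):
        rig = default_rig(distortion_amplitude_px=2.0, seed=5)
        tgt = make_calibration_target(rig)
        loc = ldlt_fit(tgt, cell_spec=(3, 3, 3))
        glob = calibrate_global(tgt)
        uv1, _ = rig[0].project(control_points)
        uv2, _ = rig[1].project(control_points)
        p_loc, _ = triangulate_many(uv1, uv2, loc)
        p_glob, _ = triangulate_many(uv1, uv2, glob)
        rms_loc = np.sqrt(np.mean(np.sum((p_loc - control_points) ** 2, axis=1)))
        rms_glob = np.sqrt(np.mean(np.sum((p_glob - control_points) ** 2, axis=1)))
        assert rms_loc <= rms_glob

    def test_missing_observation_errors(self):
        rig = default_rig()
        calib = calibrate_global(make_calibration_target(rig))
        with pytest.raises(ValueError):
            triangulate(None, (512.0, 512.0), calib)


class TestEnsembleAverage:
    @staticmethod
    def _tracks(n_cycles, noise, seed=0, n_frames=6, n_markers=4):
        rng = np.random.default_rng(seed)
        base = rng.uniform(100, 900, size=(n_markers, n_frames, 2))
        rows = []
        for c in range(n_cycles):
            for m in range(n_markers):
                for f in range(n_frames):
                    xy = base[m, f] + rng.normal(0, noise, 2)
                    rows.append(("m%d" % m, "cam1", c, f, xy[0], xy[1]))
        return (
            pd.DataFrame(rows, columns=["marker_id", "cam", "cycle", "frame", "x_px", "y_px"]),
            base,
        )

    def test_identical_cycles_passthrough(self):
        df, base = self._tracks(15, 0.0)
        out = ensemble_average_cycles(df)
        got = out.sort_values(["marker_id", "frame"])[["x_px", "y_px"]].to_numpy()
        assert np.allclose(got, base.reshape(-1, 2))
        assert (out.n_cycles == 15).all()

    def test_noise_reduction_scales_with_sqrt_cycles(self):
        reps = []
        for seed in range(30):
            df, base = self._tracks(15, 1.0, seed=seed, n_frames=2, n_markers=2)
            out = ensemble_average_cycles(df).sort_values(["marker_id", "frame"])
            reps.append(out[["x_px", "y_px"]].to_numpy() - base.reshape(-1, 2))
        resid = np.concatenate(reps).ravel()
        assert np.std(resid) == pytest.approx(1.0 / np.sqrt(15), rel=0.15)

    def test_partial_gap_bookkeeping(self):
        df, _ = self._tracks(15, 0.0)
        df = df.drop(df[(df.cycle == 3) & (df.frame == 2) & (df.marker_id == "m1")].index)
        out = ensemble_average_cycles(df)
        row = out[(out.marker_id == "m1") & (out.frame == 2)]
        assert int(row.n_cycles.iloc[0]) == 14


class TestMirror:
    def test_pin_is_fixed_point(self):
        pin = np.array([0.0, 0.0, 5.0])
        cloud = mirror_cloud(pin[None], ["pin"], pin)
        assert np.allclose(cloud.points[1], pin)

    def test_reflection_geometry(self):
        pin = np.zeros(3)
        p = np.array([[3.0, 2.0, 7.0]])
        cloud = mirror_cloud(p, ["a"], pin, plane_normal=(1, 0, 0))
        assert np.allclose(cloud.points[1], [-3.0, 2.0, 7.0])

    def test_involution_is_identity(self):
        # reflecting twice returns every point (to machine precision)
        rng = np.random.default_rng(4)
        pts = rng.normal(0, 20, (50, 3))
        pin = np.array([1.0, 2.0, 3.0])
        once = mirror_cloud(pts, [str(i) for i in range(50)], pin)
        refl = once.points[50:]
        twice = mirror_cloud(refl, [str(i) for i in range(50)], pin)
        assert np.allclose(twice.points[50:], pts, rtol=0, atol=1e-10)

    def test_non_unit_normal_rejected(self):
        with pytest.raises(ValueError):
            mirror_cloud(np.zeros((1, 3)), ["a"], np.zeros(3), plane_normal=(2, 0, 0))

    def test_mirrored_half_lies_on_full_outer_surface(self, geometry65, markers65):
        p = markers65.positions(geometry65)
        cloud = mirror_cloud(p, markers65.ids, markers65.pin_position)
        a, b, cx, cy = outer_surface_params(geometry65, cloud.points[:, 2])
        rho = np.sqrt(
            ((cloud.points[:, 0] - cx) / a) ** 2 + ((cloud.points[:, 1] - cy) / b) ** 2
        )
        # radial distance from the true outer surface
        dist = np.abs(rho - 1.0) * np.maximum(a, b)
        assert dist.max() < 0.2

    @settings(deadline=None, max_examples=30)
    @given(arrays(float, (5, 3), elements=st.floats(-50, 50)))
    def test_reflection_preserves_plane_distance(self, pts):
        pin = np.array([0.0, 1.0, 0.0])
        cloud = mirror_cloud(pts, [str(i) for i in range(5)], pin)
        d0 = (pts - pin) @ cloud.plane_normal
        d1 = (cloud.points[5:] - pin) @ cloud.plane_normal
        assert np.allclose(d1, -d0, atol=1e-9)


class TestCloudToVolume:
    def test_sphere_oracle_both_methods(self):
        rng = np.random.default_rng(0)
        n = 20000
        th = np.arccos(rng.uniform(-1, 1, n))
        ph = rng.uniform(0, 2 * np.pi, n)
        sp = 20 * np.column_stack(
            [np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)]
        )
        sp[:, 2] += 20
        truth = 4 / 3 * np.pi * 8
        assert cloud_to_volume(sp, band_height=2.0) == pytest.approx(truth, rel=0.01)
        assert cloud_to_volume(sp, method="hull") == pytest.approx(truth, rel=0.01)

    @pytest.mark.parametrize("target", [65.0, 31.0])
    def test_phantom_cloud_recovers_cavity_volume(self, geometry65, markers65, target):
        g = deform_to_volume(geometry65, target)
        p = markers65.positions(g)
        cloud = mirror_cloud(p, markers65.ids, markers65.pin_position)
        v = cloud_to_volume(cloud, wall_offset=geometry65.wall_thickness)
        assert v == pytest.approx(target, rel=0.02)

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.arange(30.0), np.arange(30.0), np.linspace(0, 10, 30)])
        with pytest.raises(ValueError):
            cloud_to_volume(pts, band_height=2.0)


@pytest.fixture(scope="module")
def sp_run(geometry65):
    from lvphantom.pipeline import RunConfig, _reconstruct_sp
    from lvphantom.waveform import make_volume_waveform

    cfg = RunConfig(seed=3, marker_noise_px=0.0, n_cycles=1, n_sp_phases=214)
    v = make_volume_waveform(n_samples=214)
    rec = _reconstruct_sp(cfg, geometry65, v)
    return v, rec


class TestEndToEndRecovery:
    """Phantom -> cameras -> LDLT -> triangulation -> mirror -> volume."""

    def test_volume_waveform_recovered_at_all_phases(self, sp_run):
        v, rec = sp_run
        err = np.abs(rec.volumes - v.volumes) / v.edv
        assert err.max() < 0.02

    def test_recovered_ef_close_to_truth(self, sp_run):
        from lvphantom.flow import ejection_fraction

        v, rec = sp_run
        truth_ef = 100 * (v.edv - v.esv) / v.edv
        assert ejection_fraction(rec) == pytest.approx(truth_ef, abs=1.5)
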