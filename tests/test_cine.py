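import numpy as np
import pytest

from lvphantom.cine import (
    SegmentationParams,
    reconstruct_series,
    reject_blurred,
    segment_slice,
    volume_from_masks,
)
from lvphantom.geometry import default_geometry
from lvphantom.motion import make_phase_geometries
from lvphantom.slices import SliceSpec, calibrate_blur_threshold, render_slices
from lvphantom.waveform import make_volume_waveform


def _ellipse_image(a_px, b_px, size=96, lumen=0.85, bg=0.15, noise=0.0, seed=0):
    yy, xx = np.mgrid[:size, :size]
    c = (size - 1) / 2
    img = np.where(((xx - c) / a_px) ** 2 + ((yy - c) / b_px) ** 2 <= 1, lumen, bg)
    if noise > 0:
        img = img + np.random.default_rng(seed).normal(0, noise, img.shape)
    return np.clip(img, 0, 1)


def _dice(a, b):
    return 2 * np.logical_and(a, b).sum() / (a.sum() + b.sum())


class TestSegmentSlice:
    def test_disk_area_oracle(self):
        img = _ellipse_image(20, 20)
        mask, info = segment_slice(img, init="threshold")
        assert mask.sum() == pytest.approx(np.pi * 20**2, rel=0.02)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="no contrast"):
            segment_slice(np.full((64, 64), 0.3))

    def test_background_with_noise_yields_empty_mask(self):
        rng = np.random.default_rng(0)
        img = np.clip(0.15 + rng.normal(0, 0.03, (64, 64)), 0, 1)
        mask, _ = segment_slice(img, init="circle")
        assert mask.sum() == 0

    def test_noisy_ellipse_dice(self):
        truth = _ellipse_image(24, 16) > 0.5
        img = _ellipse_image(24, 16, noise=0.05, seed=3)
        mask, _ = segment_slice(img, init="threshold")
        assert _dice(mask, truth) >= 0.95

    def test_dice_degrades_monotonically_with_noise(self):
        truth = _ellipse_image(24, 16) > 0.5
        dices = []
        for sigma in (0.0, 0.05, 0.1):
            img = _ellipse_image(24, 16, noise=sigma, seed=5)
            mask, _ = segment_slice(img, init="threshold")
            dices.append(_dice(mask, truth))
        assert dices[0] >= dices[1] - 5e-3 and dices[1] >= dices[2] - 5e-3

    @pytest.mark.parametrize("a,b", [(10, 10), (20, 14), (30, 22)])
    def test_area_consistency_across_sizes(self, a, b):
        img = _ellipse_image(a, b)
        mask, _ = segment_slice(img, init="threshold")
        assert mask.sum() == pytest.approx(np.pi * a * b, rel=0.02)

    def test_circle_init_supported(self):
        img = _ellipse_image(22, 22)
        mask, _ = segment_slice(img, init="circle", params=SegmentationParams(max_iter=200))
        assert mask.sum() == pytest.approx(np.pi * 22**2, rel=0.03)

    def test_unknown_init_rejected(self):
        with pytest.raises(ValueError, match="init"):
            segment_slice(_ellipse_image(20, 20), init="blob")


class TestRejectBlurred:
    def test_phantom_flags_seven_of_128(self, cine_stack_full):
        stack = cine_stack_full
        assert stack.blur_flags.sum() == 7
        usable, frac = reject_blurred(stack)
        assert usable.size == 121
        assert round(100 * frac) == 95

    def test_flags_sit_at_peak_systole_and_early_diastole(self, cine_stack_full, waveform128):
        flagged = np.where(cine_stack_full.blur_flags)[0]
        seg = waveform128.segments
        n = waveform128.times.size
        to_phase = lambda t: t / waveform128.period * n
        systole = (to_phase(seg["ejection_onset"]) - 2, to_phase(seg["ejection_end"]) + 2)
        early_diastole = (to_phase(seg["filling_onset"]) - 2, to_phase(seg["filling_onset"]) + 12)
        in_sys = (flagged >= systole[0]) & (flagged <= systole[1])
        in_dia = (flagged >= early_diastole[0]) & (flagged <= early_diastole[1])
        assert np.all(in_sys | in_dia)
        assert in_sys.any() and in_dia.any()

    def test_no_blur_means_all_usable(self, cine_reduced):
        stack = cine_reduced["stacks"][0.03]
        import dataclasses

        quiet = dataclasses.replace(stack, blur_flags=np.zeros(stack.n_phases, bool))
        usable, frac = reject_blurred(quiet)
        assert frac == 1.0

    def test_sharpness_criterion_agrees_with_flags(self, cine_stack_full):
        u_flag, _ = reject_blurred(cine_stack_full, "flag")
        u_sharp, _ = reject_blurred(cine_stack_full, "sharpness")
        assert np.array_equal(u_flag, u_sharp)

    def test_speed_tie_calibration_error(self):
        with pytest.raises(ValueError, match="tie"):
            calibrate_blur_threshold(np.ones(10), n_blurred=3)


class TestVolumeFromMasks:
    def test_slice_summation_arithmetic(self):
        # 15 slices of 4 cm^2 each, 6 mm thick -> 36 mL
        mask = np.zeros((40, 40), bool)
        mask[:20, :20] = True  # 400 px
        masks = [mask] * 15
        assert volume_from_masks(masks, slice_thickness=6.0, pixel_size=1.0) == pytest.approx(36.0)

    def test_empty_masks_give_zero(self):
        masks = [np.zeros((10, 10), bool)] * 5
        assert volume_from_masks(masks, 6.0, 1.2) == 0.0

    def test_missing_slice_errors(self):
        masks = [np.ones((4, 4), bool), None, np.ones((4, 4), bool)]
        with pytest.raises(ValueError, match="missing"):
            volume_from_masks(masks, 6.0, 1.2)


class TestReconstructSeries:
    @pytest.fixture(scope="class")
    def results(self, cine_reduced):
        return {
            sigma: reconstruct_series(stack)
            for sigma, stack in cine_reduced["stacks"].items()
        }

    def test_noiseless_volume_recovery_within_3_percent(self, cine_reduced, results):
        v = cine_reduced["waveform"]
        res = results[0.0]
        truth = v.volumes[res.usable_indices]
        assert np.max(np.abs(res.volumes - truth) / truth) < 0.03

    def test_noisy_volume_recovery_within_5_percent(self, cine_reduced, results):
        v = cine_reduced["waveform"]
        res = results[0.03]
        truth = v.volumes[res.usable_indices]
        assert np.max(np.abs(res.volumes - truth) / truth) < 0.05

    def test_ef_matches_cine_cmr_report(self, results):
        # EDV 65 / ESV 31 phantom: EF printed as 52.3 %
        assert results[0.03].ef_percent == pytest.approx(52.3, abs=1.0)

    def test_gaps_leave_series_short(self, results):
        res = results[0.03]
        assert res.usable_indices.size == res.n_phases - 7
        assert res.volumes.size == res.usable_indices.size

    def test_static_phantom_has_zero_ef(self, geometry65):
        v = make_volume_waveform(n_samples=4)
        geoms = [geometry65] * 4
        stack = render_slices(
            geoms, v.times, wall_speeds=np.zeros(4), blur_threshold=1.0,
            noise_sigma=0.0, period=v.period,
        )
        assert not stack.blur_flags.any()
        res = reconstruct_series(stack)
        # phases differ only in the contour's initialization path
        assert res.ef_percent == pytest.approx(0.0, abs=0.5)

    def test_too_few_usable_phases_error(self, geometry65):
        v = make_volume_waveform(n_samples=4)
        stack = render_slices(
            [geometry65] * 4, v.times, wall_speeds=np.zeros(4), blur_threshold=1.0,
            noise_sigma=0.0, period=v.period,
        )
        import dataclasses

        flags = np.array([False, True, True, True])
        bad = dataclasses.replace(stack, blur_flags=flags)
        with pytest.raises(ValueError, match="fewer than two"):
            reconstruct_series(bad)
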