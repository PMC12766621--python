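"""Registration, coil-bias correction, baseline nulling, spatial filtering."""

import numpy as np
import pytest

from qperf.phantom import PhantomSpec, default_aif_sequence, render_study
from qperf.preprocess import (
    DynamicSeries,
    PreprocessError,
    baseline_correct,
    coil_correct,
    register_translation,
    spatial_filter,
)


def series_from_frames(frames, roles=None, seq=None, rr=1000.0):
    from qperf.phantom import default_myo_sequence

    n = frames.shape[0]
    return DynamicSeries(
        frames=frames,
        trigger_times=rr * np.arange(n),
        frame_roles=roles or tuple("SR" for _ in range(n)),
        seq=seq or default_myo_sequence(),
    )


class TestRegistration:
    def test_motion_free_phantom_zero_displacement(self, clean_study):
        reg = register_translation(clean_study.myocardial_series[0])
        assert np.abs(reg.displacements).max() < 0.05

    def test_integer_shifts_recovered_exactly(self, clean_study):
        ser = clean_study.myocardial_series[0]
        shifted = ser.frames.copy()
        shifted[10] = np.roll(shifted[10], (3, -3), axis=(0, 1))
        shifted[20] = np.roll(shifted[20], (-2, 1), axis=(0, 1))
        reg = register_translation(ser.with_frames(shifted))
        assert reg.displacements[10] == pytest.approx([-3.0, 3.0])
        assert reg.displacements[20] == pytest.approx([2.0, -1.0])

    def test_subpixel_shift_recovered(self, clean_study):
        spec = PhantomSpec(
            matrix=(48, 48), n_frames=30, n_slices=1, lv_radius=6,
            inner_radius=9, outer_radius=14, seed=5,
            motion=tuple(
                (0.6, 0.0) if i == 15 else (0.0, 0.0) for i in range(30)
            ),
        )
        study = render_study(spec)
        reg = register_translation(study.myocardial_series[0])
        assert abs(reg.displacements[15][0] + 0.6) < 0.5

    def test_constant_frame_flagged(self):
        frames = np.random.default_rng(0).random((5, 16, 16))
        frames[2] = 1.0
        reg = register_translation(series_from_frames(frames), reference=0)
        assert 2 in reg.flags
        assert reg.displacements[2] == pytest.approx([0.0, 0.0])

    def test_single_frame_rejected(self):
        with pytest.raises(PreprocessError):
            register_translation(series_from_frames(np.ones((1, 8, 8))))


class TestCoilCorrect:
    def test_uniform_pd_identity(self):
        frames = np.ones((6, 20, 20)) * 3.0
        roles = ("PD", "PD") + ("SR",) * 4
        corrected, bias = coil_correct(series_from_frames(frames, roles))
        assert bias == pytest.approx(np.ones_like(bias))
        assert corrected.frames == pytest.approx(frames)

    def test_known_quadratic_bias_removed_by_surface_fit(self):
        from dataclasses import replace

        # texture-free phantom: the only PD inhomogeneity is the bias
        spec = PhantomSpec(
            matrix=(48, 48), n_frames=40, n_slices=1, lv_radius=6,
            inner_radius=9, outer_radius=14, seed=4, background_texture=0.0,
        )
        study = render_study(spec)
        ser = study.myocardial_series[0]
        corrected, bias = coil_correct(ser, method="surface_fit")
        pd = corrected.pd_frames().mean(axis=0)
        # within each tissue class the corrected PD must be flat to < 2%
        heart = study.ground_truth["myo_mask"] | study.ground_truth["lv_mask"]
        for region in (heart, ~heart):
            vals = pd[region]
            assert (vals.max() - vals.min()) / vals.mean() < 0.02
        # and the estimated field tracks the true bias shape
        true_bias = study.ground_truth["bias"]
        ratio = bias / true_bias
        assert np.ptp(ratio) / ratio.mean() < 0.02

    def test_pixelwise_on_bias_only_images_flattens(self):
        yy, xx = np.mgrid[0:24, 0:24]
        bias = 1.0 + 0.3 * xx / 23 - 0.2 * yy / 23
        frames = np.stack([bias] * 6)
        roles = ("PD",) * 2 + ("SR",) * 4
        corrected, _ = coil_correct(
            series_from_frames(frames, roles), method="pixelwise", smooth_sigma=0.0
        )
        flat = corrected.frames[3]
        assert np.nanstd(flat) / np.nanmean(flat) < 1e-6

    def test_zero_pd_rejected(self):
        frames = np.zeros((4, 8, 8))
        roles = ("PD",) + ("SR",) * 3
        with pytest.raises(PreprocessError):
            coil_correct(series_from_frames(frames, roles))


class TestBaseline:
    def test_constant_offset_nulled(self):
        curves = np.outer(np.ones(10), np.ones(4)) * 10.0
        out = baseline_correct(curves, [0, 1, 2])
        assert out[:3] == pytest.approx(np.zeros((3, 4)))

    def test_zero_baseline_identity(self):
        rng = np.random.default_rng(1)
        c = np.vstack([np.zeros((3, 5)), rng.random((7, 5))])
        assert baseline_correct(c, [0, 1, 2]) == pytest.approx(c)

    def test_multi_frame_mean_reduces_estimator_variance(self):
        """Averaging 4 noisy baseline frames cuts estimator variance ~4x."""
        rng = np.random.default_rng(2)
        n_rep = 4000
        noise = rng.normal(0, 1.0, size=(n_rep, 4))
        est_1 = noise[:, 0]
        est_4 = noise.mean(axis=1)
        ratio = est_1.var() / est_4.var()
        assert ratio == pytest.approx(4.0, rel=0.15)

    def test_series_pd_frames_untouched(self, clean_study):
        ser = clean_study.myocardial_series[0]
        out = baseline_correct(ser, [0, 1, 2])
        assert out.frames[out.pd_indices] == pytest.approx(
            ser.frames[ser.pd_indices]
        )
        sr = out.sr_indices
        assert np.abs(out.frames[sr[:3]].mean(axis=0)).max() < 1e-9

    def test_empty_pre_contrast_rejected(self):
        with pytest.raises(PreprocessError):
            baseline_correct(np.ones((5, 3)), [])


class TestSpatialFilter:
    def test_none_is_identity(self, clean_study):
        ser = clean_study.myocardial_series[0]
        assert spatial_filter(ser, "none").frames is ser.frames

    def test_gaussian_preserves_mass(self):
        frames = np.zeros((4, 31, 31))
        frames[:, 15, 15] = 1.0
        out = spatial_filter(series_from_frames(frames), "gaussian", 2.0)
        assert out.frames[0].sum() == pytest.approx(1.0, abs=1e-6)

    def test_median_removes_single_pixel_outlier(self, clean_study):
        ser = clean_study.myocardial_series[0]
        frames = ser.frames.copy()
        frames[20, 24, 24] += 100.0
        out = spatial_filter(ser.with_frames(frames), "median", 3)
        assert abs(out.frames[20, 24, 24] - ser.frames[20, 24, 24]) < 0.05

    def test_aif_series_refused(self):
        frames = np.ones((4, 8, 8))
        ser = series_from_frames(frames, seq=default_aif_sequence())
        with pytest.raises(PreprocessError):
            spatial_filter(ser, "gaussian", 1.0)


def test_preprocess_chain_restores_clean_render(small_spec):
    """register + coil + baseline on a shifted biased phantom matches the
    unshifted render to within 1 percent (on the SR signal range)."""
    from dataclasses import replace

    moving = replace(
        small_spec,
        motion=tuple(
            (2.0, -1.0) if 10 <= i < 20 else (0.0, 0.0)
            for i in range(small_spec.n_frames)
        ),
    )
    ref_study = render_study(small_spec)
    mov_study = render_study(moving)
    ref = ref_study.myocardial_series[0]
    mov = mov_study.myocardial_series[0]

    reg = register_translation(mov)
    ref_c, _ = coil_correct(ref, method="pixelwise")
    mov_c, _ = coil_correct(reg.corrected, method="pixelwise")
    ref_b = baseline_correct(ref_c, [0, 1, 2])
    mov_b = baseline_correct(mov_c, [0, 1, 2])
    heart = ref_study.ground_truth["myo_mask"]
    sr = ref_b.sr_indices
    diff = np.abs(mov_b.frames[sr][:, heart] - ref_b.frames[sr][:, heart])
    scale = np.ptp(ref_b.frames[sr][:, heart])
    assert diff.max() / scale < 0.01
    # no operation altered the time axis
    assert mov_b.trigger_times == pytest.approx(mov.trigger_times)
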