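import numpy as np
import pytest

from ctslice import (
    IntensityProfile,
    PhantomImage,
    ProfileError,
    StageError,
    SynthParams,
    fwhm,
    generate_phantom,
    mean_profile,
    measure_slice_thickness,
    recrop_window,
)

SPACING = (0.5078125, 0.5078125)


def _profile(values, baseline=0.0, half_mode="baseline"):
    values = np.asarray(values, dtype=float)
    peak = values.max()
    half = baseline + (peak - baseline) / 2 if half_mode == "baseline" else peak / 2
    return IntensityProfile(values, baseline, peak, half)


def brute_force_fwhm(values, half, upsample=1000):
    """Independent oracle: upsample by linear interpolation, count samples."""
    x = np.arange(len(values))
    fine = np.interp(np.arange(0, len(values) - 1 + 1e-9, 1 / upsample), x, values)
    return np.count_nonzero(fine >= half) / upsample


class TestRecropWindow:
    def test_default_30x30(self, default_phantom):
        win = recrop_window(default_phantom, (255.5, 255.5), 30)
        assert win.shape == (30, 30)

    def test_window_shifted_inside_at_border(self, default_phantom):
        win = recrop_window(default_phantom, (2.0, 2.0), 30)
        assert win.shape == (30, 30)

    def test_degenerate_window_rejected(self, default_phantom):
        with pytest.raises(ProfileError):
            recrop_window(default_phantom, (255.5, 255.5), 0)

    def test_foundation_excluded_from_window(self, clean_params):
        # the foundation strip sits > 15 px from the bar center by design
        img = generate_phantom(clean_params)
        mid = img.truth.bar_centers_px[1]
        win = recrop_window(img, mid, 30)
        found_row = mid[0] + (
            clean_params.bar_length_mm / 2
            + clean_params.foundation_thickness_mm / 2
        ) / clean_params.spacing_mm
        r0 = round(mid[0]) - 15
        assert r0 + 30 <= found_row - clean_params.foundation_thickness_mm


class TestMeanProfile:
    def test_rank_one_averaging_identity(self):
        row_profile = np.array([0.0, 5.0, 400.0, 900.0, 400.0, 5.0, 0.0])
        window = PhantomImage(np.outer(row_profile, np.ones(30)), SPACING)
        prof = mean_profile(window)
        assert prof.axis == "rows"
        np.testing.assert_allclose(prof.values, row_profile)

    def test_axis_autodetection_follows_the_bar(self):
        col_profile = np.array([0.0, 0.0, 300.0, 900.0, 300.0, 0.0, 0.0])
        window = PhantomImage(np.outer(np.ones(30), col_profile), SPACING)
        assert mean_profile(window).axis == "columns"

    def test_noise_suppression_by_column_averaging(self):
        # sigma 10 HU averaged over 30 columns -> per-row SEM ~ 1.8 HU
        rng = np.random.default_rng(0)
        bar = np.zeros((30, 30))
        bar[13:18, :] = 900.0
        water_sds = []
        for _ in range(200):
            window = PhantomImage(bar + rng.normal(0.0, 10.0, (30, 30)), SPACING)
            prof = mean_profile(window, axis="rows")
            water_sds.append(np.std(prof.values[:10]))
        assert np.mean(water_sds) == pytest.approx(10.0 / np.sqrt(30), rel=0.15)

    def test_all_zero_window_has_no_bar(self):
        with pytest.raises(ProfileError, match="no bar"):
            mean_profile(PhantomImage(np.zeros((30, 30)), SPACING))

    def test_baseline_is_lowest_quartile_mean(self):
        vals = np.concatenate([np.full(10, 2.0), np.full(30, 500.0)])
        window = PhantomImage(np.outer(vals, np.ones(5)), SPACING)
        prof = mean_profile(window)
        assert prof.baseline == pytest.approx(2.0)
        assert prof.half_level == pytest.approx(2.0 + (500.0 - 2.0) / 2)

    def test_raw_half_mode_is_peak_over_two(self):
        vals = np.concatenate([np.full(10, 100.0), np.full(30, 900.0)])
        window = PhantomImage(np.outer(vals, np.ones(5)), SPACING)
        prof = mean_profile(window, half_mode="raw")
        assert prof.half_level == pytest.approx(450.0)


class TestFwhm:
    def test_symmetric_rect(self):
        assert fwhm(_profile([0, 0, 10, 10, 10, 0, 0])) == pytest.approx(3.0)

    def test_single_sample_peak(self):
        assert fwhm(_profile([0, 1, 0])) == pytest.approx(1.0)

    def test_gaussian_closed_form(self):
        # dense 0.1 px sampling so linear interpolation error is negligible
        step = 0.1
        x = np.arange(0.0, 40.0, step)
        sigma = 2.0
        vals = 100.0 * np.exp(-((x - 20.0) ** 2) / (2 * sigma**2))
        expect = 2 * np.sqrt(2 * np.log(2)) * sigma  # 4.7096 px
        assert fwhm(_profile(vals)) * step == pytest.approx(expect, abs=0.02)

    def test_peak_at_edge_advises_larger_window(self):
        with pytest.raises(ProfileError, match="larger window"):
            fwhm(_profile([0.0, 2.0, 5.0, 9.0, 10.0]))

    def test_crossings_nearest_peak_win(self):
        # secondary bump to the right must not widen the measurement
        vals = [0, 0, 10, 10, 10, 0, 0, 6, 6, 0]
        assert fwhm(_profile(vals)) == pytest.approx(3.0)

    def test_matches_brute_force_on_random_unimodal_profiles(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            sigma_l = rng.uniform(1.5, 6.0)
            sigma_r = rng.uniform(1.5, 6.0)
            center = rng.uniform(12.0, 18.0)
            x = np.arange(31, dtype=float)
            vals = np.where(
                x < center,
                np.exp(-((x - center) ** 2) / (2 * sigma_l**2)),
                np.exp(-((x - center) ** 2) / (2 * sigma_r**2)),
            ) * rng.uniform(100.0, 1000.0)
            prof = _profile(vals)
            assert fwhm(prof) == pytest.approx(
                brute_force_fwhm(vals, prof.half_level), abs=0.02
            )


class TestEndToEnd:
    def test_noise_free_phantom_recovers_truth(self, clean_params):
        img = generate_phantom(clean_params)
        res = measure_slice_thickness(img)
        assert res.fwhm_mm == pytest.approx(img.truth.true_fwhm_mm, abs=0.1)
        assert res.fwhm_mm == pytest.approx(
            res.fwhm_px * img.pixel_spacing_row, rel=1e-9
        )

    def test_four_cm_offset_changes_little(self):
        at_center = measure_slice_thickness(
            generate_phantom(SynthParams(seed=11))
        ).fwhm_mm
        shifted = measure_slice_thickness(
            generate_phantom(SynthParams(seed=11, offset_mm=(-40.0, 0.0)))
        ).fwhm_mm
        assert abs(shifted - at_center) < 0.2

    def test_water_only_image_fails_in_segmentation_stage(self, water_image):
        with pytest.raises(StageError, match="segmentation.*no stair objects"):
            measure_slice_thickness(water_image)

    def test_measured_fwhm_monotone_in_nominal(self):
        vals = [
            measure_slice_thickness(
                generate_phantom(SynthParams(nominal_mm=float(n), seed=13))
            ).fwhm_mm
            for n in (1, 2, 3, 4, 5)
        ]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_fwhm_mm_stable_under_finer_sampling(self):
        # same physical phantom at half the pixel spacing
        coarse = measure_slice_thickness(
            generate_phantom(SynthParams(seed=17, noise_sigma_hu=5.0))
        ).fwhm_mm
        fine = measure_slice_thickness(
            generate_phantom(
                SynthParams(
                    seed=17,
                    noise_sigma_hu=5.0,
                    spacing_mm=260.0 / 1024.0,
                    water_radius_mm=60.0,
                )
            )
        ).fwhm_mm
        assert fine == pytest.approx(coarse, rel=0.02)

    def test_determinism(self):
        a = measure_slice_thickness(generate_phantom(SynthParams(seed=21)))
        b = measure_slice_thickness(generate_phantom(SynthParams(seed=21)))
        assert a == b
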