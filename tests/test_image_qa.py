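"""ROI statistics and the phantom image-quality metrics."""

import numpy as np
import pytest

from cbctqa.errors import (
    ConfigurationError,
    DegenerateDataError,
    GeometryError,
    TooSmallRoiError,
)
from cbctqa.image_qa import (
    ImageVolume,
    RoiCylinder,
    cnr,
    cnr_from_stats,
    cylinder_mask,
    hu_constancy_metric,
    lcd_from_roi_mean_sds,
    low_contrast_detectability,
    noise_metric,
    roi_stats,
    uniformity_metric,
)
from cbctqa.synthetic import add_noise_for_dose


def uniform_volume(hu=50.0, n=40, nz=10, spacing=(1.0, 1.0, 1.0)):
    vox = np.full((nz, n, n), hu)
    origin = (-(n - 1) / 2, -(n - 1) / 2, 0.0)
    return ImageVolume(vox, spacing=spacing, origin=origin)


class TestRoiStats:
    def test_constant_volume(self):
        v = uniform_volume(50.0)
        mean, sd, n = roi_stats(v, RoiCylinder(center=(0, 0, 5), diameter=20, length=6))
        assert (mean, sd) == (50.0, 0.0)
        assert n > 0

    def test_iid_noise_sd_recovered(self, rng):
        v = uniform_volume(0.0, n=60, nz=20)
        v.voxels += rng.normal(0, 20.0, v.voxels.shape)
        _, sd, n = roi_stats(v, RoiCylinder(center=(0, 0, 10), diameter=40, length=16))
        assert n > 10_000
        assert sd == pytest.approx(20.0, rel=0.05)

    def test_roi_outside_volume(self):
        v = uniform_volume()
        with pytest.raises(GeometryError):
            roi_stats(v, RoiCylinder(center=(30, 0, 5), diameter=25, length=4))

    def test_too_small_roi(self):
        v = uniform_volume(spacing=(2.0, 2.0, 2.0))
        with pytest.raises(TooSmallRoiError):
            roi_stats(v, RoiCylinder(center=(0, 0, 8), diameter=1.0, length=2.0))

    def test_half_open_z_interval(self):
        """A cylinder spanning [z0, z0+L) excludes the slice at exactly z0+L."""
        v = uniform_volume(nz=10, spacing=(1.0, 1.0, 1.0))
        roi = RoiCylinder(center=(0, 0, 4), diameter=10, length=4)
        mask, sls = cylinder_mask(v, roi)
        zs = v.axis_coords("z")[sls[0]][mask.any(axis=(1, 2))]
        assert zs.min() >= 2.0 and zs.max() < 6.0


class TestNoiseMetric:
    def test_noiseless_phantom_is_zero(self, clean_phantom, default_config):
        assert noise_metric(clean_phantom, default_config.layout) == 0.0

    def test_recovers_injected_sigma(self, clean_phantom, default_config, rng):
        # sigma = a/sqrt(wCBDI) = 19.5/sqrt(0.32) = 34.5 HU, the scale seen
        # on a standard half-rotation head scan
        noisy = add_noise_for_dose(clean_phantom, 0.32, default_config, rng=rng)
        assert noise_metric(noisy, default_config.layout) == pytest.approx(34.47, rel=0.05)

    def test_linear_in_sigma(self, clean_phantom, default_config, rng):
        """Measured noise vs injected sigma has unit slope (5 levels)."""
        sigmas = np.array([10.0, 17.5, 25.0, 32.5, 40.0])
        measured = []
        for s in sigmas:
            # wcbdi chosen so a/sqrt(w) = s
            w = (default_config.noise_coefficient / s) ** 2
            noisy = add_noise_for_dose(clean_phantom, w, default_config, rng=rng)
            measured.append(noise_metric(noisy, default_config.layout))
        slope = np.polyfit(sigmas, measured, 1)[0]
        assert slope == pytest.approx(1.0, abs=0.05)


class TestUniformity:
    def test_constant_module_is_zero(self, clean_phantom, default_config):
        assert uniformity_metric(clean_phantom, default_config.layout) == 0.0

    def test_constructed_peripheral_offsets(self, clean_phantom, default_config):
        """Peripheral means shifted by (-2, -1, +1, +3) give uniformity 3."""
        v = clean_phantom.copy()
        _, peripherals = default_config.layout.uniformity_rois()
        for roi, offset in zip(peripherals, (-2.0, -1.0, 1.0, 3.0)):
            mask, sls = cylinder_mask(v, roi)
            v.voxels[sls][mask] += offset
        assert uniformity_metric(v, default_config.layout) == pytest.approx(3.0)

    def test_single_peripheral_shift(self, clean_phantom, default_config):
        v = clean_phantom.copy()
        _, peripherals = default_config.layout.uniformity_rois()
        mask, sls = cylinder_mask(v, peripherals[2])
        v.voxels[sls][mask] += 8.3
        assert uniformity_metric(v, default_config.layout) == pytest.approx(8.3)


class TestHuConstancy:
    def test_exact_inserts_give_zero(self, clean_phantom, default_config):
        assert hu_constancy_metric(clean_phantom, default_config.layout) == pytest.approx(0.0, abs=1e-9)

    def test_max_absolute_difference(self, clean_phantom, default_config):
        """Measured (-995, -102, 118) vs (-1000, -100, 120) -> 5."""
        v = clean_phantom.copy()
        for (ins, roi), delta in zip(default_config.layout.sensitometry_rois(), (5.0, -2.0, -2.0)):
            mask, sls = cylinder_mask(v, roi)
            v.voxels[sls][mask] += delta
        assert hu_constancy_metric(v, default_config.layout) == pytest.approx(5.0)

    def test_single_large_deviation(self, clean_phantom, default_config):
        v = clean_phantom.copy()
        ins, roi = default_config.layout.sensitometry_rois()[2]  # acrylic
        mask, sls = cylinder_mask(v, roi)
        v.voxels[sls][mask] += 20.0
        assert hu_constancy_metric(v, default_config.layout) == pytest.approx(20.0)


class TestLowContrastDetectability:
    def test_detection_rule_flips_at_threshold(self):
        """4 x SD <= 10 HU: SD = 2.5 is detected, infinitesimally above is not."""
        assert str(lcd_from_roi_mean_sds({15.0: 2.5})) == "15"
        assert str(lcd_from_roi_mean_sds({15.0: 2.5 + 1e-9})) == ">=15"

    def test_threshold_bracketing_between_diameters(self):
        """SDs 2.4 HU at 5 mm and 2.6 HU at 4 mm detect down to 5 mm only."""
        result = lcd_from_roi_mean_sds({4.0: 2.6, 5.0: 2.4, 15.0: 1.0})
        assert result.detected and result.value_mm == 5.0

    def test_all_failing_returns_sentinel(self):
        result = lcd_from_roi_mean_sds({d: 4.0 for d in (2, 5, 15)})
        assert not result.detected
        assert str(result) == ">=15"

    def test_noiseless_module_detects_everything(self, clean_phantom, default_config):
        result = low_contrast_detectability(clean_phantom, default_config.layout)
        assert result.detected and result.value_mm == 2.0

    def test_monotone_in_noise(self, clean_phantom, default_config, rng):
        """Smallest detected diameter never improves as noise grows."""
        results = []
        for sigma in (5.0, 15.0, 30.0, 60.0, 120.0):
            w = (default_config.noise_coefficient / sigma) ** 2
            noisy = add_noise_for_dose(clean_phantom, w, default_config, rng=rng)
            results.append(low_contrast_detectability(noisy, default_config.layout))
        assert results == sorted(results)
        assert results[0] < results[-1]

    def test_too_few_rois_rejected(self, clean_phantom, default_config):
        import dataclasses

        layout = dataclasses.replace(default_config.layout, lcd_rois_per_row=2)
        with pytest.raises(ConfigurationError):
            low_contrast_detectability(clean_phantom, layout)


def test_layout_json_roundtrip(default_config):
    import json

    from cbctqa.image_qa import PhantomLayout

    layout = default_config.layout
    assert PhantomLayout.from_dict(json.loads(json.dumps(layout.to_dict()))) == layout


class TestCnr:
    def test_hand_formula_from_stats(self):
        assert cnr_from_stats(35.5, 25.5, 10.0) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "roi_mean, bkg_mean, roi_sd, expected",
        [(-61.8, -26.4, 37.3, 0.95), (-28.5, 4.2, 28.1, 1.16)],
    )
    def test_roi_noise_convention_reproduces_patient_values(self, roi_mean, bkg_mean, roi_sd, expected):
        assert round(cnr_from_stats(roi_mean, bkg_mean, roi_sd), 2) == expected

    def test_volume_cnr_matches_voxel_list_oracle(self, rng):
        v = uniform_volume(0.0, n=60, nz=12)
        v.voxels += rng.normal(0, 15.0, v.voxels.shape)
        roi = RoiCylinder(center=(-12, 0, 6), diameter=14, length=8)
        bkg = RoiCylinder(center=(12, 0, 6), diameter=14, length=8)
        m_r, sd_r, _ = roi_stats(v, roi)
        m_b, sd_b, _ = roi_stats(v, bkg)
        assert cnr(v, roi, bkg) == pytest.approx(abs(m_r - m_b) / sd_b, abs=1e-12)
        assert cnr(v, roi, bkg, denominator="roi") == pytest.approx(abs(m_r - m_b) / sd_r, abs=1e-12)

    def test_constant_roi_is_degenerate(self):
        v = uniform_volume(10.0)
        roi = RoiCylinder(center=(-8, 0, 5), diameter=10, length=4)
        bkg = RoiCylinder(center=(8, 0, 5), diameter=10, length=4)
        with pytest.raises(DegenerateDataError):
            cnr(v, roi, bkg)


class TestOffsetInvariance:
    """A global HU offset moves HU constancy only; every other metric is blind to it."""

    def test_metrics_under_global_offset(self, clean_phantom, default_config, rng):
        cfg = default_config
        noisy = add_noise_for_dose(clean_phantom, 1.0, cfg, rng=rng)
        shifted = noisy.copy()
        shifted.voxels += 100.0
        layout = cfg.layout
        assert noise_metric(shifted, layout) == pytest.approx(noise_metric(noisy, layout))
        assert uniformity_metric(shifted, layout) == pytest.approx(uniformity_metric(noisy, layout))
        assert low_contrast_detectability(shifted, layout) == low_contrast_detectability(noisy, layout)
        roi, bkg = layout.cnr_rois()
        assert cnr(shifted, roi, bkg) == pytest.approx(cnr(noisy, roi, bkg))
        # the offset dominates; sign-of-max effects keep it from being exact
        # in noise, but it tracks (noisy value + offset) closely
        assert hu_constancy_metric(shifted, layout) == pytest.approx(
            hu_constancy_metric(noisy, layout) + 100.0, abs=10.0
        )

    def test_hu_constancy_shift_exact_on_clean_phantom(self, clean_phantom, default_config):
        shifted = clean_phantom.copy()
        shifted.voxels += 40.0
        assert hu_constancy_metric(shifted, default_config.layout) == pytest.approx(40.0)
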