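"""Digital phantom generation and dose-conditioned simulation."""

import dataclasses

import numpy as np
import pytest
from scipy.stats import spearmanr

from cbctqa.dosimetry import weighted_cbdi
from cbctqa.errors import GeometryError
from cbctqa.fits import fit_fixed_power
from cbctqa.image_qa import (
    LowContrastInsert,
    cnr,
    low_contrast_detectability,
    noise_metric,
    roi_stats,
)
from cbctqa.protocols import Protocol
from cbctqa.synthetic import (
    SimulationConfig,
    add_noise_for_dose,
    build_digital_phantom,
    build_head_phantom,
    simulate_chamber_readings,
    simulate_cohort_readings,
)


class TestBuildDigitalPhantom:
    def test_noiseless_phantom_is_deterministic(self, default_config, clean_phantom):
        again = build_digital_phantom(default_config)
        assert np.array_equal(again.voxels, clean_phantom.voxels)

    def test_low_contrast_inserts_sit_at_one_percent_contrast(self, default_config, clean_phantom):
        layout = default_config.layout
        roi, bkg = layout.cnr_rois()
        # interior of the 15 mm insert (clear of the partial-volume rim)
        interior = dataclasses.replace(roi, diameter=10.0)
        mean, sd, _ = roi_stats(clean_phantom, interior)
        assert mean == pytest.approx(default_config.background_hu + 10.0, abs=1e-9)
        assert roi_stats(clean_phantom, bkg)[0] == pytest.approx(default_config.background_hu, abs=1e-9)

    def test_overlapping_inserts_rejected(self, default_config):
        layout = default_config.layout
        clash = layout.low_contrast_inserts + (
            LowContrastInsert(diameter=9.0, center=layout.low_contrast_inserts[0].center),
        )
        bad = dataclasses.replace(layout, low_contrast_inserts=clash)
        with pytest.raises(GeometryError):
            build_digital_phantom(dataclasses.replace(default_config, layout=bad))

    def test_head_phantom_materials(self):
        cfg = SimulationConfig()
        v, rois = build_head_phantom(cfg)
        assert roi_stats(v, rois["water"])[0] == pytest.approx(0.0, abs=1e-9)
        assert roi_stats(v, rois["acrylic"])[0] == pytest.approx(120.0, abs=1e-9)
        assert roi_stats(v, rois["background"])[0] == pytest.approx(40.0, abs=1e-9)

    def test_head_phantom_cnr_tracks_dose(self, rng):
        """Higher imaging dose gives higher water-vs-background CNR."""
        cfg = SimulationConfig()
        v, rois = build_head_phantom(cfg)
        low = add_noise_for_dose(v, 0.32, cfg, rng=rng)
        high = add_noise_for_dose(v, 1.18, cfg, rng=rng)
        cnr_low = cnr(low, rois["water"], rois["background"])
        cnr_high = cnr(high, rois["water"], rois["background"])
        assert cnr_high > cnr_low


class TestAddNoise:
    def test_same_seed_is_byte_identical(self, clean_phantom):
        cfg = SimulationConfig(seed=7)
        a = add_noise_for_dose(clean_phantom, 0.5, cfg)
        b = add_noise_for_dose(clean_phantom, 0.5, cfg)
        assert np.array_equal(a.voxels, b.voxels)

    def test_input_volume_unmodified(self, clean_phantom, default_config, rng):
        before = clean_phantom.voxels.copy()
        add_noise_for_dose(clean_phantom, 0.5, default_config, rng=rng)
        assert np.array_equal(clean_phantom.voxels, before)

    def test_rejects_nonpositive_dose(self, clean_phantom, default_config):
        with pytest.raises(ValueError):
            add_noise_for_dose(clean_phantom, 0.0, default_config)

    @pytest.mark.parametrize("wcbdi, expected_sigma", [(1.0, 20.0), (4.0, 10.0)])
    def test_inverse_sqrt_noise_scale(self, wcbdi, expected_sigma, rng):
        """a = 20: sigma is 20 HU at 1 cGy and 10 HU at 4 cGy."""
        cfg = SimulationConfig.noise_study(noise_coefficient=20.0)
        v = build_digital_phantom(cfg)
        noisy = add_noise_for_dose(v, wcbdi, cfg, rng=rng)
        assert noise_metric(noisy, cfg.layout) == pytest.approx(expected_sigma, rel=0.05)


class TestSimulatedReadings:
    def test_target_dose_from_cubic_law(self):
        """c tuned to nCBDI(100 kV) = 0.21 and 150 mAs gives wCBDI = 0.315 cGy."""
        cfg = SimulationConfig(dose_coefficient=0.21 / 100**3, dose_jitter=0.0)
        p = Protocol(name="Head", kvp=100, current=15, trajectory="half", gantry_speed=6.0)
        rs = simulate_chamber_readings(p, cfg)
        assert weighted_cbdi(rs) == pytest.approx(0.315)

    def test_zero_heterogeneity_gives_uniform_readings(self):
        cfg = SimulationConfig(dose_heterogeneity=0.0, dose_jitter=0.0)
        p = Protocol(name="x", kvp=100, current=15)
        rs = simulate_chamber_readings(p, cfg)
        assert rs.d_center == rs.d_12 == rs.d_3 == rs.d_6 == rs.d_9

    def test_heterogeneity_preserves_weighted_index(self):
        for h in (0.0, 0.1, 0.3):
            cfg = SimulationConfig(dose_heterogeneity=h, dose_jitter=0.0)
            p = Protocol(name="x", kvp=125, current=30, trajectory="full")
            target = cfg.dose_coefficient * 125**3 * 540 / 100
            assert weighted_cbdi(simulate_chamber_readings(p, cfg)) == pytest.approx(target)

    def test_noiseless_cohort_recovers_dose_coefficient_exactly(self, reference_protocols):
        from cbctqa.dosimetry import dose_index_table

        cfg = SimulationConfig(dose_jitter=0.0)
        pairs = simulate_cohort_readings(reference_protocols, cfg)
        recs = dose_index_table(pairs)
        fit = fit_fixed_power([r.kvp for r in recs], [r.ncbdi for r in recs], 3.0)
        assert fit.coefficient == pytest.approx(cfg.dose_coefficient, rel=1e-12)
        assert fit.ncc == pytest.approx(1.0)

    def test_lcd_degrades_as_dose_falls(self, default_config, clean_phantom, rng):
        """Spearman correlation between wCBDI and detectability rank is <= 0."""
        wcbdis = [0.09, 0.32, 0.63, 1.27, 3.11]
        ranks = []
        for w in wcbdis:
            noisy = add_noise_for_dose(clean_phantom, w, default_config, rng=rng)
            lcd = low_contrast_detectability(noisy, default_config.layout)
            ranks.append(lcd.value_mm + (100.0 if not lcd.detected else 0.0))
        rho = spearmanr(wcbdis, ranks).statistic
        assert rho <= 0


class TestCohortRecovery:
    def test_noise_coefficient_recovered_across_cohort(self, reference_protocols):
        """Simulated 26-protocol study refits a = 19.5 within 5% (median of seeds)."""
        errors = []
        for seed in range(10):
            cfg = SimulationConfig.noise_study(seed=seed)
            phantom = build_digital_phantom(cfg)
            rng = cfg.rng()
            pairs = simulate_cohort_readings(reference_protocols, cfg, rng=rng)
            w = np.array([weighted_cbdi(r) for _, r in pairs])
            noise = np.array([
                noise_metric(add_noise_for_dose(phantom, wi, cfg, rng=rng), cfg.layout)
                for wi in w
            ])
            fit = fit_fixed_power(w, noise, -0.5)
            errors.append(abs(fit.coefficient / cfg.noise_coefficient - 1))
            assert fit.ncc >= 0.98
        assert np.median(errors) < 0.05
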