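import numpy as np
import pytest

from carnotype.config import CohortCell, default_cohort_config, default_config
from carnotype.spectral import fit_peak, preprocess
from carnotype.synthetic_data import (
    simulate_calibration_table,
    simulate_cohort,
    simulate_fid,
    simulate_measurement_pair,
    simulate_runner_panel,
)
from carnotype.types import PeakSpec, SigmoidModel, VoxelGeometry


class TestSimulateFid:
    def test_metadata_matches_acquisition(self, cfg, acq, unit_voxel):
        s = simulate_fid([PeakSpec(8.0, 1.0, 12.0)], [5.0], unit_voxel, acq)
        assert s.n_points == 1024
        assert s.bandwidth_hz == 1200.0
        assert s.repetition_time_ms == 2000.0
        assert s.echo_time_ms == 30.0
        assert s.n_averages == 128
        assert s.domain == "time"

    def test_null_signal_is_exactly_zero(self, acq, unit_voxel):
        s = simulate_fid([PeakSpec(8.0, 0.0, 12.0)], [5.0], unit_voxel, acq, noise_sd=0.0)
        assert np.all(s.samples == 0)

    def test_parseval_energy_identity(self, acq, unit_voxel):
        """Energy of the FID equals energy of its plain discrete spectrum
        (direct-summation oracle with dt/df weights)."""
        s = simulate_fid([PeakSpec(8.0, 2.0, 12.0)], [5.0], unit_voxel, acq)
        dt = s.dwell_time_s
        df = s.bandwidth_hz / s.n_points
        spec = np.fft.fft(s.samples) * dt
        e_time = np.sum(np.abs(s.samples) ** 2) * dt
        e_freq = np.sum(np.abs(spec) ** 2) * df
        assert e_freq == pytest.approx(e_time, rel=1e-12)

    def test_seeded_determinism(self, acq, unit_voxel):
        a = simulate_fid([PeakSpec(8.0, 1.0, 12.0)], [5.0], unit_voxel, acq, noise_sd=3.0, seed=9)
        b = simulate_fid([PeakSpec(8.0, 1.0, 12.0)], [5.0], unit_voxel, acq, noise_sd=3.0, seed=9)
        assert np.array_equal(a.samples, b.samples)

    def test_peak_outside_bandwidth_named(self, acq, unit_voxel):
        with pytest.raises(ValueError, match="creatine"):
            simulate_fid([PeakSpec(30.0, 1.0, 12.0, "lorentzian", "creatine")], [5.0], unit_voxel, acq)

    def test_negative_noise_rejected(self, acq, unit_voxel):
        with pytest.raises(ValueError):
            simulate_fid([PeakSpec(8.0, 1.0, 12.0)], [5.0], unit_voxel, acq, noise_sd=-1.0)

    def test_area_linear_in_concentration(self, acq, unit_voxel):
        """Noiseless fitted peak area is proportional to concentration
        (10-point grid, R^2 > 0.999)."""
        concs = np.linspace(1.0, 10.0, 10)
        areas = []
        for c in concs:
            s = simulate_fid([PeakSpec(8.0, 1.0, 12.0)], [c], unit_voxel, acq)
            areas.append(fit_peak(preprocess(s), (7.6, 8.4)).area)
        areas = np.array(areas)
        r = np.corrcoef(concs, areas)[0, 1]
        assert r**2 > 0.999
        # slope equals amplitude * volume / 2 (one-sided acquisition)
        slope = np.polyfit(concs, areas, 1)[0]
        assert slope == pytest.approx(0.5, rel=1e-3)


class TestMeasurementPair:
    def test_phantom_self_reference_identity(self, cfg):
        """Phantom truth pushed through the pipeline returns 20 mM."""
        from carnotype.quantify import quantify_pair

        _, phantom = simulate_measurement_pair(5.0, cfg, seed=0, noise=False)
        # quantify the phantom against itself with phantom==muscle settings
        cfg.relaxation.t1_muscle_ms = cfg.relaxation.t1_phantom_ms
        cfg.relaxation.t2_muscle_ms = cfg.relaxation.t2_phantom_ms
        cfg.temperatures.muscle_k = cfg.temperatures.phantom_k
        cfg.simulation.geometry = cfg.phantom.geometry
        res = quantify_pair(phantom, phantom, cfg)
        assert res.concentration_mm == pytest.approx(20.0, rel=1e-9)

    @pytest.mark.parametrize("truth", [2.0, 4.94, 8.0])
    def test_noiseless_roundtrip_within_half_percent(self, cfg, truth):
        from carnotype.quantify import quantify_pair

        muscle, phantom = simulate_measurement_pair(truth, cfg, seed=0, noise=False)
        res = quantify_pair(muscle, phantom, cfg)
        assert res.concentration_mm == pytest.approx(truth, rel=0.005)

    def test_same_seed_identical_spectra(self, cfg):
        m1, p1 = simulate_measurement_pair(4.94, cfg, seed=7)
        m2, p2 = simulate_measurement_pair(4.94, cfg, seed=7)
        assert np.array_equal(m1.samples, m2.samples)
        assert np.array_equal(p1.samples, p2.samples)

    def test_nonpositive_concentration_rejected(self, cfg):
        with pytest.raises(ValueError):
            simulate_measurement_pair(0.0, cfg)


class TestSimulateCohort:
    def test_large_cell_mean_converges(self):
        """Male control cell mean converges to the configured 4.94 mM."""
        config = default_cohort_config()
        config.cells = [CohortCell("male", "control", "control", 8000, 4.94, 1.43)]
        recs = simulate_cohort(config, seed=3)
        vals = np.array([r.carnosine_mean_mm for r in recs])
        mc_se = 1.43 / np.sqrt(len(vals))
        assert abs(vals.mean() - 4.94) < 4 * mc_se
        assert vals.std(ddof=1) == pytest.approx(1.43, rel=0.05)

    def test_zero_measurement_cv_makes_legs_equal(self):
        config = default_cohort_config()
        config.measurement_cv = 0.0
        recs = simulate_cohort(config, seed=1)
        assert all(r.carnosine_left_mm == r.carnosine_right_mm for r in recs)

    def test_male_range_plausible(self):
        """Simulated male concentrations stay within the printed extremes
        (1.68-7.85 mM) allowing measurement-noise spillover."""
        config = default_cohort_config()
        recs = [r for r in simulate_cohort(config, seed=5) if r.sex == "male"]
        vals = np.array([r.carnosine_mean_mm for r in recs])
        assert vals.min() > 0.5
        assert vals.max() < 10.0
        # bulk of the population inside the printed range
        inside = np.mean((vals >= 1.68) & (vals <= 7.85))
        assert inside > 0.9

    def test_default_cohort_has_163_subjects(self):
        assert len(simulate_cohort(default_cohort_config(), seed=0)) == 163

    def test_determinism(self):
        a = simulate_cohort(default_cohort_config(), seed=11)
        b = simulate_cohort(default_cohort_config(), seed=11)
        assert [r.carnosine_left_mm for r in a] == [r.carnosine_left_mm for r in b]


class TestRunnerPanel:
    def test_noise_free_z_equals_sigmoid(self):
        config = default_cohort_config()
        truth = config.sigmoid_truth
        recs = simulate_runner_panel(config, distances_m=[100, 42195], seed=0, noise_sd=0.0)
        assert recs[0].z_score == pytest.approx(float(truth(100.0)))
        assert recs[1].z_score == pytest.approx(float(truth(42195.0)))

    def test_z_at_d50_is_logistic_midpoint(self):
        config = default_cohort_config()
        t = config.sigmoid_truth
        recs = simulate_runner_panel(config, distances_m=[t.d50_m], seed=0, noise_sd=0.0)
        assert recs[0].z_score == pytest.approx((t.top + t.bottom) / 2)

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError):
            simulate_runner_panel(default_cohort_config(), distances_m=[100, -5])


class TestCalibrationTable:
    def test_shape_and_range(self, cfg):
        x, y = simulate_calibration_table(cfg.calibration, seed=4)
        assert len(x) == 12
        assert np.all((x >= 29.0) & (x <= 62.0))
        assert np.all(y > 0)
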