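import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from carnotype.cohort import (
    fit_sigmoid,
    fold_change,
    group_summaries,
    percent_difference,
    predict_z,
    reference_from_records,
    summary_ttest,
    zscore,
)
from carnotype.synthetic_data import simulate_cohort, simulate_runner_panel
from carnotype.config import default_cohort_config
from carnotype.types import ReferenceStats, SigmoidModel, SubjectRecord

MALE_REF = ReferenceStats("male", 4.94, 1.43, 47)


class TestZscore:
    def test_reference_mean_maps_to_zero(self):
        assert zscore(4.94, MALE_REF) == 0.0

    def test_one_sd_above_is_one(self):
        assert zscore(4.94 + 1.43, MALE_REF) == pytest.approx(1.0)

    def test_printed_reference_arithmetic(self):
        assert zscore(6.37, MALE_REF) == pytest.approx(1.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        value=st.floats(min_value=1.0, max_value=9.0),
        shift=st.floats(min_value=-3.0, max_value=3.0),
    )
    def test_affine_equivariance(self, value, shift):
        """Shifting all values and the reference mean together leaves Z
        unchanged."""
        ref2 = ReferenceStats("male", MALE_REF.mean_mm + shift, MALE_REF.sd_mm, 47)
        assert zscore(value + shift, ref2) == pytest.approx(zscore(value, MALE_REF), abs=1e-9)


class TestSummaryTtest:
    def test_ex_athlete_contrast_reproduces_printed_p(self):
        """Ex-sprinters vs ex-endurance: pooled p rounds to 0.012."""
        _, df, p = summary_ttest(7, 5.11, 1.07, 7, 3.61, 0.81)
        assert df == 12
        assert round(p, 3) == 0.012

    def test_talent_contrast_consistent_with_printed_p(self):
        _, _, p = summary_ttest(7, 6.88, 1.83, 8, 4.90, 0.93)
        assert 0.017 <= p <= 0.021

    def test_identical_summaries_null(self):
        t, _, p = summary_ttest(10, 5.0, 1.0, 12, 5.0, 1.2)
        assert t == 0.0
        assert p == 1.0

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            summary_ttest(1, 5.0, 1.0, 7, 4.0, 1.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_matches_raw_sample_ttest(self, seed):
        """Summary-statistic t equals scipy's raw-sample pooled t-test."""
        rng = np.random.default_rng(seed)
        a = rng.normal(5.0, 1.0, size=rng.integers(3, 20))
        b = rng.normal(4.2, 1.4, size=rng.integers(3, 20))
        t_raw, p_raw = stats.ttest_ind(a, b, equal_var=True)
        t, _, p = summary_ttest(
            len(a), a.mean(), a.std(ddof=1), len(b), b.mean(), b.std(ddof=1)
        )
        assert t == pytest.approx(t_raw, rel=1e-9)
        assert p == pytest.approx(p_raw, rel=1e-9)

    def test_welch_df_below_pooled(self):
        _, df_w, _ = summary_ttest(5, 5.0, 2.0, 20, 4.0, 0.5, variant="welch")
        assert df_w < 23


class TestGroupSummaries:
    def test_single_subject_stratum(self):
        rec = [SubjectRecord("a", "male", "elite", "explosive", carnosine_left_mm=6.0)]
        row = group_summaries(rec).iloc[0]
        assert row["n"] == 1
        assert row["mean_mm"] == row["median_mm"] == 6.0
        assert np.isnan(row["sd_mm"])

    def test_quartiles_match_hand_interpolation(self):
        vals = [1.0, 2.0, 3.0, 4.0, 10.0]
        recs = [
            SubjectRecord(f"s{i}", "male", "control", "control", carnosine_left_mm=v)
            for i, v in enumerate(vals)
        ]
        row = group_summaries(recs).iloc[0]
        # linear interpolation: q1 at position 1 -> 2, median 3, q3 at 3 -> 4
        assert row["q1_mm"] == pytest.approx(2.0)
        assert row["median_mm"] == pytest.approx(3.0)
        assert row["q3_mm"] == pytest.approx(4.0)

    def test_unknown_key_rejected(self):
        recs = [SubjectRecord("a", "male", "elite", "explosive", carnosine_left_mm=6.0)]
        with pytest.raises(ValueError, match="stratify"):
            group_summaries(recs, stratify=("shoe_size",))

    def test_default_cohort_reproduces_explosive_mean(self):
        """Large simulated elite-explosive cell lands on 6.58 mM."""
        config = default_cohort_config()
        for c in config.cells:
            c.n = 0
        config.cells[4].n = 4000  # male elite explosive
        recs = simulate_cohort(config, seed=2)
        row = group_summaries(recs).iloc[0]
        assert row["mean_mm"] == pytest.approx(6.58, rel=0.02)


class TestContrastArithmetic:
    def test_explosive_percent_difference(self):
        assert percent_difference(6.58, 4.94) == pytest.approx(33.2, abs=0.05)

    def test_endurance_percent_difference(self):
        assert percent_difference(3.75, 4.94) == pytest.approx(-24.1, abs=0.05)

    def test_equal_means_zero(self):
        assert percent_difference(4.94, 4.94) == 0.0

    def test_reference_must_be_positive(self):
        with pytest.raises(ValueError):
            percent_difference(5.0, 0.0)

    def test_fold_change_cell_means(self):
        assert fold_change(6.58, 3.75) == pytest.approx(1.7547, abs=1e-4)

    def test_fold_change_identity(self):
        assert fold_change(3.3, 3.3) == 1.0

    def test_sprinter_subgroup_fold_change_recovers_truth(self):
        """Simulated sprinter-only vs marathon+triathlete subgroups land
        near the generator's configured ratio."""
        config = default_cohort_config()
        for c in config.cells:
            c.n = 0
        config.cells[4].n = 2000  # male elite explosive (sprinters)
        config.cells[5].n = 2000  # male elite endurance (marathon/triathlon)
        recs = simulate_cohort(config, seed=4)
        expl = np.mean([r.carnosine_mean_mm for r in recs if r.category == "explosive"])
        endu = np.mean([r.carnosine_mean_mm for r in recs if r.category == "endurance"])
        assert fold_change(expl, endu) == pytest.approx(6.58 / 3.75, rel=0.03)


class TestSigmoid:
    TRUTH = SigmoidModel(top=1.5, bottom=-1.2, d50_m=1000.0, hill=3.0)
    DISTANCES = np.array([100.0, 200.0, 400.0, 800.0, 1500.0, 3000.0, 10000.0, 42195.0])

    def test_exact_recovery_noise_free(self):
        fit = fit_sigmoid(self.DISTANCES, self.TRUTH(self.DISTANCES))
        assert fit.converged
        for name in ("top", "bottom", "d50_m", "hill"):
            assert getattr(fit, name) == pytest.approx(getattr(self.TRUTH, name), rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0)

    def test_midpoint_property_of_fit(self):
        fit = fit_sigmoid(self.DISTANCES, self.TRUTH(self.DISTANCES))
        assert predict_z(fit, fit.d50_m) == pytest.approx((fit.top + fit.bottom) / 2, rel=1e-6)

    def test_monotone_decreasing_over_track_distances(self):
        z = predict_z(self.TRUTH, self.DISTANCES)
        assert np.all(np.diff(z) < 0)

    def test_order_invariance(self, rng):
        z = self.TRUTH(self.DISTANCES) + rng.normal(scale=0.1, size=8)
        perm = rng.permutation(8)
        a = fit_sigmoid(self.DISTANCES, z)
        b = fit_sigmoid(self.DISTANCES[perm], z[perm])
        assert a.d50_m == pytest.approx(b.d50_m, rel=1e-6)

    def test_unit_change_km_rescales_d50_only(self, rng):
        z = self.TRUTH(self.DISTANCES) + rng.normal(scale=0.1, size=8)
        a = fit_sigmoid(self.DISTANCES, z)
        b = fit_sigmoid(self.DISTANCES / 1000.0, z)
        assert b.d50_m == pytest.approx(a.d50_m / 1000.0, rel=1e-6)
        assert b.hill == pytest.approx(a.hill, rel=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_sigmoid([100.0, 1000.0, 10000.0, 20000.0], [1.0, 0.5, -0.5, -1.0])

    def test_narrow_distance_span_rejected(self):
        d = [100.0, 120.0, 150.0, 200.0, 300.0]
        with pytest.raises(ValueError, match="decade"):
            fit_sigmoid(d, [1.0, 0.9, 0.8, 0.7, 0.6])

    def test_runner_panel_recovery(self):
        """Noise-free runner panel round-trips through the fit."""
        config = default_cohort_config()
        recs = simulate_runner_panel(config, seed=0, noise_sd=0.0)
        fit = fit_sigmoid([r.best_distance_m for r in recs], [r.z_score for r in recs])
        assert fit.d50_m == pytest.approx(config.sigmoid_truth.d50_m, rel=1e-4)


class TestReferenceFromRecords:
    def test_matches_manual_stats(self):
        recs = simulate_cohort(default_cohort_config(), seed=6)
        ref = reference_from_records(recs, "male")
        vals = [r.carnosine_mean_mm for r in recs if r.sex == "male" and r.group == "control"]
        assert ref.n == 47
        assert ref.mean_mm == pytest.approx(np.mean(vals))
        assert ref.sd_mm == pytest.approx(np.std(vals, ddof=1))
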