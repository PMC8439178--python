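"""Synthetic cohort generator: determinism, marginals, and limiting cases."""

import numpy as np
import pandas as pd
import pytest

from circastress.simulate import (
    ConfigError,
    SimulationConfig,
    generate_cohort,
    generate_daily_surveys,
    generate_hrv_observations,
    generate_weekly_surveys,
    nyc_style_case_curve,
    simulate_all,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("stress_ar1_phi", 1.0),
            ("stress_ar1_phi", -0.1),
            ("daily_response_prob", 1.5),
            ("hrv_obs_per_day_mean", -1.0),
            ("cosinor_amplitude_by_tertial", (1.0, 2.0)),
            ("n_subjects", -3),
        ],
    )
    def test_invalid_field_named_in_error(self, field, value):
        with pytest.raises(ConfigError, match=field):
            SimulationConfig(**{field: value})

    def test_unknown_field_rejected(self):
        with pytest.raises(ConfigError, match="mystery"):
            SimulationConfig.from_dict({"mystery": 1})

    def test_yaml_round_trip(self, tmp_path):
        import yaml

        cfg = SimulationConfig(n_subjects=12, seed=5)
        path = tmp_path / "cfg.yaml"
        path.write_text(yaml.safe_dump(cfg.to_dict()))
        assert SimulationConfig.from_yaml(path) == cfg


class TestCohort:
    def test_empty_cohort(self):
        cfg = SimulationConfig(n_subjects=0)
        assert len(generate_cohort(cfg)) == 0

    def test_default_size_and_determinism(self):
        cfg = SimulationConfig(seed=1)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        assert len(a) == 361
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_score_ranges(self):
        cohort = generate_cohort(SimulationConfig(n_subjects=200, seed=2))
        assert cohort.pss4.between(0, 16).all()
        assert cohort.emotional_support.between(2, 10).all()
        assert cohort.qol.between(2, 10).all()


class TestWeeklySurveys:
    def _residual_lag_pairs(self, phi, n_subjects=900, study_days=90, seed=3):
        """Pooled consecutive-survey residual pairs under a pure-intercept
        generator (all fixed effects zero)."""
        cfg = SimulationConfig(
            n_subjects=n_subjects, study_days=study_days, seed=seed,
            stress_fixed_effects={"intercept": 8.0}, stress_subject_sd=0.0,
            stress_ar1_phi=phi,
        )
        cohort = generate_cohort(cfg)
        weekly = generate_weekly_surveys(cohort, cfg)
        resid = weekly.pss4.astype(float) - weekly.pss4.mean()
        pairs = []
        for _, grp in weekly.groupby("participant_id", sort=False):
            r = resid.loc[grp.index].to_numpy()
            pairs.extend(zip(r[:-1], r[1:]))
        return np.array(pairs)

    def test_independent_limit(self):
        pairs = self._residual_lag_pairs(0.0)
        assert len(pairs) >= 8000
        r = np.corrcoef(pairs[:, 0], pairs[:, 1])[0, 1]
        assert abs(r) < 0.1

    def test_ar1_lag_correlation_matches_generator(self):
        pairs = self._residual_lag_pairs(0.7)
        assert len(pairs) >= 8000
        r = np.corrcoef(pairs[:, 0], pairs[:, 1])[0, 1]
        assert abs(r - 0.7) < 0.05

    def test_cohort_mean_matches_intercept(self):
        cfg = SimulationConfig(
            n_subjects=500, study_days=60, seed=4,
            stress_fixed_effects={"intercept": 5.3},
        )
        weekly = generate_weekly_surveys(generate_cohort(cfg), cfg)
        assert weekly.pss4.mean() == pytest.approx(5.3, abs=0.2)

    def test_survey_gaps_within_configured_range(self):
        cfg = SimulationConfig(n_subjects=50, study_days=60, seed=5)
        weekly = generate_weekly_surveys(generate_cohort(cfg), cfg)
        for _, grp in weekly.groupby("participant_id"):
            d = pd.to_datetime(grp.date).sort_values()
            gaps = d.diff().dt.days.dropna()
            assert gaps.between(5, 10).all()

    def test_scores_within_legal_range(self):
        cfg = SimulationConfig(n_subjects=80, seed=6)
        weekly = generate_weekly_surveys(generate_cohort(cfg), cfg)
        assert weekly.pss4.between(0, 16).all()


class TestDailySurveys:
    def test_full_response(self):
        cfg = SimulationConfig(n_subjects=10, study_days=15, seed=7,
                               daily_response_prob=1.0)
        daily = generate_daily_surveys(generate_cohort(cfg), cfg)
        assert len(daily) == 10 * 15

    def test_no_response(self):
        cfg = SimulationConfig(n_subjects=10, study_days=15, seed=7,
                               daily_response_prob=0.0)
        assert len(generate_daily_surveys(generate_cohort(cfg), cfg)) == 0

    def test_staff_without_clinical_probability_have_no_clinical_days(self):
        cfg = SimulationConfig(n_subjects=120, study_days=20, seed=8)
        assert cfg.clinical_day_prob_by_role["staff_other"] == 0.0
        cohort = generate_cohort(cfg)
        daily = generate_daily_surveys(cohort, cfg)
        staff = set(cohort.loc[cohort.role == "staff_other", "participant_id"])
        staff_days = daily[daily.participant_id.isin(staff)]
        assert not staff_days.care_type.isin(
            ["covid_facing", "noncovid_facing"]
        ).any()


class TestHRVObservations:
    def test_noiseless_values_equal_generating_curve(self):
        """With noise and subject spread at zero, every SDNN value sits on
        the tertial's cosinor curve; at phase zero the value is M + A."""
        cfg = SimulationConfig(
            n_subjects=30, study_days=5, seed=9, hrv_noise_sd=0.0,
            subject_intercept_sd=0.0, cosinor_mesor=40.0,
            cosinor_amplitude_by_tertial=(10.0, 10.0, 10.0),
            cosinor_acrophase_by_tertial=(-2.0, -2.0, -2.0),
        )
        cohort = generate_cohort(cfg)
        hrv = generate_hrv_observations(cohort, cfg)
        ts = pd.to_datetime(hrv.timestamp)
        hours = (ts.dt.hour + ts.dt.minute / 60 + ts.dt.second / 3600
                 + ts.dt.microsecond / 3.6e9)
        expected = 40.0 + 10.0 * np.cos(2 * np.pi * hours / 24.0 - 2.0)
        assert np.allclose(hrv.sdnn_ms, expected, atol=1e-6)
        t_star = 2.0 * 24.0 / (2 * np.pi)  # phase argument equals zero
        curve_at_peak = 40.0 + 10.0 * np.cos(2 * np.pi * t_star / 24.0 - 2.0)
        assert curve_at_peak == pytest.approx(50.0)

    def test_poisson_total_count(self):
        cfg = SimulationConfig(n_subjects=1, study_days=60, seed=10,
                               hrv_obs_per_day_mean=4.0)
        hrv = generate_hrv_observations(generate_cohort(cfg), cfg)
        lam = 240.0
        assert abs(len(hrv) - lam) <= 3 * np.sqrt(lam)

    def test_flat_rhythm_limit(self):
        """Zero amplitudes: regressing SDNN on the cosinor axes gives
        coefficients indistinguishable from zero."""
        import statsmodels.api as sm

        cfg = SimulationConfig(
            n_subjects=60, study_days=20, seed=11,
            cosinor_amplitude_by_tertial=(0.0, 0.0, 0.0),
        )
        cohort = generate_cohort(cfg)
        hrv = generate_hrv_observations(cohort, cfg)
        ts = pd.to_datetime(hrv.timestamp)
        hours = (ts.dt.hour + ts.dt.minute / 60 + ts.dt.second / 3600).to_numpy()
        X = sm.add_constant(
            np.column_stack([np.cos(2 * np.pi * hours / 24),
                             np.sin(2 * np.pi * hours / 24)])
        )
        res = sm.OLS(hrv.sdnn_ms.to_numpy(), X).fit()
        assert abs(res.params[1]) < 3 * res.bse[1]
        assert abs(res.params[2]) < 3 * res.bse[2]

    def test_values_nonnegative(self):
        cfg = SimulationConfig(n_subjects=30, study_days=10, seed=12,
                               cosinor_mesor=5.0, hrv_noise_sd=15.0)
        hrv = generate_hrv_observations(generate_cohort(cfg), cfg)
        assert (hrv.sdnn_ms >= 0).all()


class TestCaseCurve:
    def test_zero_peak_gives_zero_series(self):
        curve = nyc_style_case_curve(SimulationConfig(case_curve_peak=0.0))
        assert (curve.cases == 0).all()

    def test_argmax_at_configured_day(self):
        cfg = SimulationConfig(case_curve_peak_day=20, case_curve_peak=5000)
        curve = nyc_style_case_curve(cfg)
        peak_date = curve.loc[curve.cases.idxmax(), "date"]
        assert (peak_date - cfg.start_date).days == 20

    def test_positive_mass_and_contiguous_dates(self):
        curve = nyc_style_case_curve(SimulationConfig())
        assert curve.cases.sum() > 0
        d = pd.to_datetime(curve.date)
        assert (d.diff().dt.days.dropna() == 1).all()


class TestDeterminism:
    def test_all_tables_byte_identical_across_runs(self):
        cfg = SimulationConfig(n_subjects=25, study_days=20, seed=13)
        a = simulate_all(cfg)
        b = simulate_all(cfg)
        for name in a:
            assert a[name].to_csv(index=False) == b[name].to_csv(index=False), name

    def test_different_seeds_differ(self):
        a = simulate_all(SimulationConfig(n_subjects=25, study_days=20, seed=1))
        b = simulate_all(SimulationConfig(n_subjects=25, study_days=20, seed=2))
        assert a["weekly"].to_csv(index=False) != b["weekly"].to_csv(index=False)
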