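"""Cosinor linearisation, inversion, mixed fit, and bootstrap machinery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import curve_fit

from circastress.cosinor import (
    CosinorMixedModel,
    CosinorParams,
    bootstrap_compare,
    group_marginal_params,
    invert_to_circadian,
    linearize_time,
    predict_daily_curve,
    wrap_phase_difference,
)

from conftest import make_cosinor_sample

OMEGA = 2 * np.pi / 24.0


class TestLinearizeTime:
    @pytest.mark.parametrize(
        "hour,x,z",
        [(0, 1.0, 0.0), (6, 0.0, 1.0), (12, -1.0, 0.0), (18, 0.0, -1.0)],
    )
    def test_quarter_period_values(self, hour, x, z):
        ts = pd.to_datetime([f"2020-05-01 {hour:02d}:00:00"])
        t, cx, sz = linearize_time(ts)
        assert t[0] == pytest.approx(hour)
        assert cx[0] == pytest.approx(x, abs=1e-12)
        assert sz[0] == pytest.approx(z, abs=1e-12)


class TestInversion:
    def test_pure_cosine(self):
        p = invert_to_circadian(10.0, 0.0, 40.0)
        assert p.amplitude == pytest.approx(10.0)
        assert p.acrophase == pytest.approx(0.0, abs=1e-15)

    def test_pure_sine(self):
        p = invert_to_circadian(0.0, 10.0, 40.0)
        assert p.amplitude == pytest.approx(10.0)
        assert p.acrophase == pytest.approx(-np.pi / 2)

    def test_flat_rhythm_flagged_undefined(self):
        p = invert_to_circadian(0.0, 0.0, 40.0)
        assert p.amplitude == 0.0
        assert not p.acrophase_defined
        assert np.isnan(p.acrophase_hours)

    @given(
        amp=st.floats(min_value=1e-6, max_value=1e3),
        phi=st.floats(min_value=-2 * np.pi + 1e-9, max_value=0.0),
        mesor=st.floats(min_value=-100, max_value=100),
    )
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_round_trip_identity(self, amp, phi, mesor):
        """(A, phi) -> (beta, gamma) -> (A, phi) is the identity to 1e-12."""
        beta = amp * np.cos(phi)
        gamma = -amp * np.sin(phi)
        p = invert_to_circadian(beta, gamma, mesor)
        assert p.amplitude == pytest.approx(amp, rel=1e-12, abs=1e-12)
        assert p.amplitude * np.cos(p.acrophase) == pytest.approx(
            beta, rel=1e-9, abs=1e-9
        )
        assert -p.amplitude * np.sin(p.acrophase) == pytest.approx(
            gamma, rel=1e-9, abs=1e-9
        )

    def test_acrophase_difference_wrapping(self):
        assert wrap_phase_difference(np.pi) == pytest.approx(np.pi)
        assert wrap_phase_difference(-np.pi) == pytest.approx(np.pi)
        assert wrap_phase_difference(3 * np.pi / 2) == pytest.approx(-np.pi / 2)
        assert wrap_phase_difference(0.3) == pytest.approx(0.3)


class TestDailyCurve:
    def test_flat_curve(self):
        p = CosinorParams(mesor=40.0, amplitude=0.0, acrophase=float("nan"),
                          acrophase_defined=False)
        _, y = predict_daily_curve(p)
        assert np.allclose(y, 40.0)

    def test_peak_to_trough_is_twice_amplitude(self):
        p = CosinorParams(mesor=40.0, amplitude=10.0, acrophase=-2.0)
        t, y = predict_daily_curve(p, np.linspace(0, 24, 100001))
        assert y.max() == pytest.approx(50.0, abs=1e-4)
        assert y.min() == pytest.approx(30.0, abs=1e-4)

    def test_peak_time_solves_phase_equation(self):
        p = CosinorParams(mesor=40.0, amplitude=10.0, acrophase=-2.0)
        t_star = p.acrophase_hours
        angle = OMEGA * t_star + p.acrophase  # zero modulo 2*pi
        assert np.cos(angle) == pytest.approx(1.0, abs=1e-12)
        assert p.predict(t_star) == pytest.approx(50.0)


class TestMixedCosinorFit:
    def test_noiseless_recovery_exact(self):
        """With no noise and no subject heterogeneity the linearised mixed
        fit interpolates the generating curve."""
        data = make_cosinor_sample(5, 10, mesor=40.0, amplitudes=(8.0,),
                                   acrophases=(-2.0,), subject_sd=0.0,
                                   noise_sd=0.0, seed=1)
        model = CosinorMixedModel(min_obs=5).fit(data)
        p = model.params_["all"]
        assert p.mesor == pytest.approx(40.0, abs=1e-6)
        assert p.amplitude == pytest.approx(8.0, abs=1e-6)
        assert p.acrophase == pytest.approx(-2.0, abs=1e-6)

    def test_linearised_fit_agrees_with_nonlinear_least_squares(self):
        """Single-subject noiseless data: direct NLS on the cosinor form and
        the linearised fit coincide."""
        data = make_cosinor_sample(1, 20, mesor=35.0, amplitudes=(6.0,),
                                   acrophases=(-1.3,), subject_sd=0.0,
                                   noise_sd=0.0, seed=2)
        model = CosinorMixedModel(min_obs=5).fit(data)
        p = model.params_["all"]

        def curve(t, M, A, phi):
            return M + A * np.cos(OMEGA * t + phi)

        popt, _ = curve_fit(curve, data.t_hours, data.sdnn_ms,
                            p0=[30.0, 5.0, -1.0])
        assert p.mesor == pytest.approx(popt[0], abs=1e-8)
        assert p.amplitude == pytest.approx(abs(popt[1]), abs=1e-8)

    def test_amplitude_invariant_to_time_origin_shift(self):
        """Shifting every clock time moves only the acrophase."""
        data = make_cosinor_sample(20, 10, amplitudes=(9.0,),
                                   acrophases=(-2.0,), noise_sd=5.0, seed=3)
        shift = 5.0
        shifted = data.copy()
        shifted["t_hours"] = (shifted.t_hours + shift) % 24.0
        shifted["cos_t"] = np.cos(OMEGA * shifted.t_hours)
        shifted["sin_t"] = np.sin(OMEGA * shifted.t_hours)
        m0 = CosinorMixedModel(min_obs=5).fit(data)
        m1 = CosinorMixedModel(min_obs=5).fit(shifted)
        assert m1.params_["all"].amplitude == pytest.approx(
            m0.params_["all"].amplitude, abs=1e-6
        )
        d = wrap_phase_difference(
            m1.params_["all"].acrophase - m0.params_["all"].acrophase
        )
        assert d == pytest.approx(-OMEGA * shift, abs=1e-6)

    def test_inner_fit_cross_checked_against_statsmodels(self):
        import statsmodels.formula.api as smf

        data = make_cosinor_sample(30, 8, amplitudes=(8.0,), acrophases=(-2.0,),
                                   noise_sd=6.0, subject_sd=4.0, seed=4)
        model = CosinorMixedModel(min_obs=5).fit(data)
        sm = smf.mixedlm("sdnn_ms ~ cos_t + sin_t", data,
                         groups=data.participant_id).fit(reml=True)
        assert np.allclose(model.fit_.coef_.to_numpy(),
                           sm.fe_params.to_numpy(), atol=1e-3)

    def test_min_obs_filter_warns_and_excludes(self):
        data = make_cosinor_sample(10, 10, seed=5)
        few = data[data.participant_id == "S0000"].head(3).assign(
            participant_id="S9999"
        )
        with pytest.warns(UserWarning, match="fewer than"):
            model = CosinorMixedModel(min_obs=10).fit(
                pd.concat([data, few], ignore_index=True)
            )
        assert model.n_subjects_ == 10

    def test_flat_generator_amplitude_not_significant(self):
        data = make_cosinor_sample(40, 10, amplitudes=(0.0,), acrophases=(0.0,),
                                   noise_sd=10.0, seed=6)
        model = CosinorMixedModel(min_obs=5).fit(data)
        p = model.params_["all"]
        se = model.params_se_["all"]["amplitude"]
        assert p.amplitude < 3 * se


class TestGroupsAndBootstrap:
    @pytest.fixture(scope="class")
    def grouped_model(self):
        data = make_cosinor_sample(
            60, 15, amplitudes=(12.0, 6.0), acrophases=(-2.0, -2.6),
            noise_sd=10.0, subject_sd=6.0, seed=7,
            group_labels=["low", "high"],
        )
        return CosinorMixedModel(group="group", min_obs=5).fit(data)

    def test_group_params_recovered(self, grouped_model):
        tab = group_marginal_params(grouped_model)
        assert abs(tab.loc["low", "amplitude"] - 12.0) < 3 * tab.loc[
            "low", "se_amplitude"]
        assert abs(tab.loc["high", "amplitude"] - 6.0) < 3 * tab.loc[
            "high", "se_amplitude"]

    def test_unknown_level_rejected(self, grouped_model):
        with pytest.raises(ValueError, match="unknown group level"):
            group_marginal_params(grouped_model, levels=["missing"])

    def test_single_group_equals_whole_sample_fit(self):
        data = make_cosinor_sample(20, 10, amplitudes=(8.0,),
                                   acrophases=(-2.0,), noise_sd=5.0, seed=8)
        data["group"] = "only"
        m_grp = CosinorMixedModel(group="group", min_obs=5).fit(data)
        m_all = CosinorMixedModel(min_obs=5).fit(data)
        assert m_grp.params_["only"].amplitude == pytest.approx(
            m_all.params_["all"].amplitude, abs=1e-8
        )

    def test_bootstrap_deterministic_under_seed(self, grouped_model):
        c1 = bootstrap_compare(grouped_model, n_boot=100, seed=123)
        c2 = bootstrap_compare(grouped_model, n_boot=100, seed=123)
        for a, b in zip(c1, c2):
            assert a.parameter == b.parameter and a.p == b.p
            assert np.array_equal(a.replicates, b.replicates)

    def test_bootstrap_detects_amplitude_difference(self, grouped_model):
        comps = bootstrap_compare(grouped_model, n_boot=200, seed=5)
        amp = next(c for c in comps if c.parameter == "amplitude")
        assert amp.p < 0.05
        assert amp.observed == pytest.approx(6.0, abs=3.0)

    def test_bootstrap_requires_groups_and_iterations(self):
        data = make_cosinor_sample(10, 10, seed=9)
        m = CosinorMixedModel(min_obs=5).fit(data)
        with pytest.raises(ValueError, match="group"):
            bootstrap_compare(m, n_boot=100, seed=0)

    def test_resample_mode_runs(self, grouped_model):
        comps = bootstrap_compare(grouped_model, n_boot=100, seed=1,
                                  mode="resample")
        assert all(c.n_boot == 100 for c in comps)
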