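import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import whamtherm as wt
from whamtherm.constants import R_KCAL, T_37C
from whamtherm.thermo import ThermoError

from _oracles import TM_CELSIUS_EXPECTED

TEMPS = np.arange(273.0, 334.0, 10.0)


def _profile_from_values(centers, pmf_values, temperature=310.0):
    grid = wt.HistogramGrid(
        float(centers[0] - (centers[1] - centers[0]) / 2),
        float(centers[-1] + (centers[1] - centers[0]) / 2),
        len(centers),
    )
    pmf = np.asarray(pmf_values, float)
    with np.errstate(over="ignore"):
        prob = np.exp(-pmf / (R_KCAL * temperature))
    prob[~np.isfinite(prob)] = 0.0
    prob /= prob.sum()
    return wt.PMFProfile(grid=grid, pmf=pmf, prob=prob, temperature=temperature)


class TestExtractDeltaG:
    def _well_barrier_profile(self, shift=0.0):
        centers = np.arange(0.5, 45.0, 1.0)
        pmf = np.zeros_like(centers)
        pmf[centers < 3] = 10.0
        pmf[np.abs(centers - 6.0) < 1] = -10.0
        pmf[np.abs(centers - 40.0) < 0.6] = 2.0
        pmf[centers > 40.5] = 1.8
        return _profile_from_values(centers, pmf + shift)

    def test_min_minus_max_arithmetic(self):
        dg, xi_min, xi_max = wt.extract_delta_g(self._well_barrier_profile())
        assert dg == pytest.approx(-12.0)
        assert abs(xi_min - 6.0) <= 0.5  # tie within the flat well bottom
        assert abs(xi_max - 40.0) <= 0.5  # tie within the flat barrier top

    def test_invariant_under_additive_shift(self):
        dg0, *_ = wt.extract_delta_g(self._well_barrier_profile())
        dg5, *_ = wt.extract_delta_g(self._well_barrier_profile(shift=5.0))
        assert dg5 == pytest.approx(dg0, abs=1e-12)

    def test_monotone_rising_profile_advises_longer_range(self):
        centers = np.arange(0.5, 20.0, 1.0)
        profile = _profile_from_values(centers, 0.5 * centers)
        with pytest.raises(ThermoError, match="extend the reaction-coordinate"):
            wt.extract_delta_g(profile)

    def test_too_few_finite_bins_rejected(self):
        centers = np.array([0.5, 1.5, 2.5])
        profile = _profile_from_values(centers, [1.0, np.inf, np.inf])
        with pytest.raises(ThermoError, match="finite"):
            wt.extract_delta_g(profile)

    def test_analytic_model_profile_recovers_truth(self, truth):
        # zero-noise limit: evaluate the model surface on a fine grid
        model = wt.thermo_model_pmf(truth, 310.0)
        centers = np.arange(0.025, 45.0, 0.05)
        profile = _profile_from_values(centers, model.value(centers))
        dg, xi_min, xi_max = wt.extract_delta_g(profile)
        assert abs(xi_min - 6.0) < 0.5
        assert dg == pytest.approx(truth.delta_g(310.0), abs=0.01)
        assert abs(xi_max - 30.0) < 0.5


class TestVantHoffFit:
    def test_noise_free_line_recovered_exactly(self):
        series = wt.ThermoSeries("d", TEMPS, -60.0 + 0.160 * TEMPS)
        params = wt.fit_gibbs_temperature(series)
        assert params.dh == pytest.approx(-60.0, abs=1e-9)
        assert params.ds == pytest.approx(-160.0, abs=1e-9)
        assert params.r2 == pytest.approx(1.0, abs=1e-12)
        assert params.dg37 == pytest.approx(-60.0 + 0.160 * T_37C, abs=1e-9)

    def test_dg37_consistency_invariant_enforced(self):
        with pytest.raises(ValueError, match="dG37"):
            wt.ThermoParams(dh=-60.0, ds=-160.0, dg37=0.0, tm=50.0, r2=1.0)

    def test_needs_two_distinct_temperatures(self):
        with pytest.raises(ThermoError, match="distinct"):
            wt.fit_gibbs_temperature(wt.ThermoSeries("d", [300.0, 300.0], [-1.0, -1.1]))

    def test_predict_evaluates_fitted_line(self):
        model = wt.VantHoffModel().fit(TEMPS, -60.0 + 0.160 * TEMPS)
        np.testing.assert_allclose(model.predict([273.0, 373.0]),
                                   [-60.0 + 0.160 * 273.0, -60.0 + 0.160 * 373.0],
                                   atol=1e-9)

    def test_estimator_params_roundtrip(self):
        est = wt.VantHoffModel(ct=2e-5, self_complementary=True)
        clone = wt.VantHoffModel().set_params(**est.get_params())
        assert clone.get_params() == est.get_params()


class TestMeltingTemperature:
    @pytest.mark.parametrize("key,expected", sorted(TM_CELSIUS_EXPECTED.items()))
    def test_matches_frozen_closed_form(self, key, expected):
        dh, ds, ct, m = key
        tm = wt.melting_temperature(dh, ds, ct=ct, self_complementary=(m == 1))
        assert tm == pytest.approx(expected, abs=1e-9)

    @settings(derandomize=True, max_examples=50)
    @given(
        dh=st.floats(-120.0, -20.0),
        ds=st.floats(-320.0, -60.0),
        ct=st.floats(1e-7, 1e-3),
    )
    def test_monotone_increasing_in_concentration(self, dh, ds, ct):
        assert wt.melting_temperature(dh, ds, 2 * ct) > wt.melting_temperature(dh, ds, ct)

    def test_monotone_in_enthalpy_magnitude_at_fixed_dg37(self):
        # at fixed dG37 the sign of dTm/d|dH| is set by dG37 relative to
        # T37*R*ln(Ct/m)/1000 ~ -7.95 kcal/mol at 10 uM: weakly bound
        # duplexes (Tm below 37 C) sharpen upward, strongly bound ones are
        # pulled down toward 37 C
        R = 1.987204
        threshold = T_37C * R * math.log(1e-5 / 4.0) / 1000.0
        for dg37, increasing in ((-5.0, True), (-10.0, False)):
            assert (dg37 > threshold) == increasing
            tms = []
            for dh in (-40.0, -60.0, -80.0, -100.0):
                ds = (dh - dg37) / T_37C * 1000.0
                tms.append(wt.melting_temperature(dh, ds))
            if increasing:
                assert all(a < b for a, b in zip(tms, tms[1:]))
            else:
                assert all(a > b for a, b in zip(tms, tms[1:]))

    def test_molar_concentration_reduces_to_ratio(self):
        # Ct = 4 M with m = 4 cancels the logarithm exactly
        tm = wt.melting_temperature(-60.0, -160.0, ct=4.0)
        assert tm == pytest.approx(1000.0 * -60.0 / -160.0 - 273.15, abs=1e-12)

    def test_never_melting_combination_rejected(self):
        with pytest.raises(ThermoError, match="never melts"):
            wt.melting_temperature(10.0, -50.0)

    def test_near_zero_denominator_rejected(self):
        R = 1.987204
        ds = -R * math.log(1e-5 / 4.0)
        with pytest.raises(ThermoError, match="undefined"):
            wt.melting_temperature(-60.0, ds)


def _params(dh, ds, duplex_id=None):
    return wt.ThermoParams(
        dh=dh, ds=ds, dg37=dh - T_37C * ds / 1000.0,
        tm=wt.melting_temperature(dh, ds), r2=1.0, duplex_id=duplex_id,
    )


COHORT = [_params(dh, ds) for dh, ds in
          [(-40.0, -110.0), (-55.0, -150.0), (-60.0, -160.0),
           (-70.0, -190.0), (-85.0, -230.0)]]


class TestLinearCorrection:
    def test_identity_calibration(self):
        model = wt.calibrate_linear_correction(COHORT, COHORT)
        assert model.slope_dh == pytest.approx(1.0)
        assert model.intercept_dh == pytest.approx(0.0, abs=1e-9)
        assert model.r2_dh == pytest.approx(1.0)
        assert model.slope_ds == pytest.approx(1.0)

    def test_constructed_line_recovered(self):
        exp = [_params(0.5 * p.dh + 3.0, 0.5 * p.ds - 2.0) for p in COHORT]
        model = wt.calibrate_linear_correction(COHORT, exp)
        assert model.slope_dh == pytest.approx(0.5)
        assert model.intercept_dh == pytest.approx(3.0)
        assert model.slope_ds == pytest.approx(0.5)
        assert model.intercept_ds == pytest.approx(-2.0)

    def test_known_affine_map_recovered_within_two_se(self):
        rng = np.random.default_rng(8)
        calc = [_params(dh, ds) for dh, ds in
                zip(rng.uniform(-100, -40, 30), rng.uniform(-260, -110, 30))]
        noise = rng.normal(0, 1.0, 30)
        exp = [_params(0.5 * p.dh + 3.0 + e, 0.5 * p.ds - 2.0 + e)
               for p, e in zip(calc, noise)]
        model = wt.calibrate_linear_correction(calc, exp)
        # analytic standard error of the OLS slope with known noise sd
        x = np.array([p.dh for p in calc])
        se_slope = 1.0 / (x.std(ddof=1) * np.sqrt(len(x) - 1))
        assert abs(model.slope_dh - 0.5) < 2 * se_slope

    def test_pairing_errors(self):
        with pytest.raises(ValueError, match="length"):
            wt.calibrate_linear_correction(COHORT, COHORT[:-1])
        with pytest.raises(ValueError, match="at least 3"):
            wt.calibrate_linear_correction(COHORT[:2], COHORT[:2])
        a = [_params(-40.0, -110.0, "x"), _params(-55.0, -150.0, "y"),
             _params(-60.0, -160.0, "z")]
        b = [_params(-40.0, -110.0, "x"), _params(-55.0, -150.0, "WRONG"),
             _params(-60.0, -160.0, "z")]
        with pytest.raises(ValueError, match="unmatched"):
            wt.calibrate_linear_correction(a, b)


class TestApplyCorrection:
    def test_identity_model_only_sets_flag(self):
        model = wt.calibrate_linear_correction(COHORT, COHORT)
        out = wt.apply_correction(COHORT[0], model)
        assert out.corrected
        assert out.dh == pytest.approx(COHORT[0].dh)
        assert out.ds == pytest.approx(COHORT[0].ds)
        assert out.tm == pytest.approx(COHORT[0].tm)

    def test_derived_quantities_consistent(self):
        exp = [_params(0.6 * p.dh - 1.0, 0.55 * p.ds + 4.0) for p in COHORT]
        model = wt.calibrate_linear_correction(COHORT, exp)
        out = wt.apply_correction(COHORT[2], model)
        assert out.dg37 == pytest.approx(out.dh - T_37C * out.ds / 1000.0, abs=1e-9)
        assert out.tm == pytest.approx(wt.melting_temperature(out.dh, out.ds))

    def test_correction_inverts_known_distortion(self):
        # distorted = (true - b)/a ; calibrating distorted on true and applying
        # must return the true parameters
        distorted = [_params((p.dh - 3.0) / 0.5, (p.ds + 2.0) / 0.5) for p in COHORT]
        model = wt.calibrate_linear_correction(distorted, COHORT)
        out = [wt.apply_correction(p, model) for p in distorted]
        np.testing.assert_allclose([p.dh for p in out], [p.dh for p in COHORT], atol=1e-9)
        np.testing.assert_allclose([p.ds for p in out], [p.ds for p in COHORT], atol=1e-9)

    def test_double_correction_rejected(self):
        model = wt.calibrate_linear_correction(COHORT, COHORT)
        once = wt.apply_correction(COHORT[0], model)
        with pytest.raises(ThermoError, match="already"):
            wt.apply_correction(once, model)


class TestSummarizeErrors:
    def test_perfect_agreement(self):
        s = wt.summarize_errors(COHORT, COHORT)
        assert s.mape_dh == 0.0 and s.mape_ds == 0.0 and s.mape_dg37 == 0.0
        assert s.mae_tm == 0.0
        assert s.r2_dh == pytest.approx(1.0)
        assert s.r2_tm == pytest.approx(1.0)

    def test_ten_percent_overprediction(self):
        exp = [COHORT[0], COHORT[1], COHORT[2]]
        pred = [_params(1.1 * p.dh, 1.1 * p.ds) for p in exp]
        s = wt.summarize_errors(pred, exp)
        assert s.mape_dh == pytest.approx(10.0)
        assert s.mape_ds == pytest.approx(10.0)
        assert s.mape_dg37 == pytest.approx(10.0)

    def test_folded_normal_expectation_for_multiplicative_noise(self):
        # a common multiplicative factor (1+eps), eps ~ N(0, 0.1), keeps the
        # dG37 identity intact and gives MAPE -> 100*0.1*sqrt(2/pi) ~ 7.98 %
        rng = np.random.default_rng(12)
        exp, pred = [], []
        for _ in range(400):
            dh = rng.uniform(-90, -40)
            ds = (dh + 10.0) / 350.0 * 1000.0
            eps = rng.normal(0, 0.1)
            exp.append(_params(dh, ds))
            pred.append(_params(dh * (1 + eps), ds * (1 + eps)))
        s = wt.summarize_errors(pred, exp)
        expected = 100.0 * 0.1 * math.sqrt(2 / math.pi)
        assert s.mape_dh == pytest.approx(expected, abs=1.2)
        assert s.mape_ds == pytest.approx(expected, abs=1.2)
        assert s.mape_dg37 == pytest.approx(expected, abs=1.2)

    def test_zero_denominator_pairs_excluded_with_warning(self):
        zero_dg = _params(-50.0, -50.0 * 1000.0 / T_37C)
        assert zero_dg.dg37 == pytest.approx(0.0, abs=1e-9)
        exp = [COHORT[0], COHORT[1], dataclasses.replace(zero_dg, dg37=0.0)]
        pred = [COHORT[0], COHORT[1], COHORT[2]]
        with pytest.warns(UserWarning, match="excluded"):
            s = wt.summarize_errors(pred, exp)
        assert math.isfinite(s.mape_dg37)
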