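"""Fitter round trips, NCA, and the DDI decision rule."""

import numpy as np
import pytest

from pemosi.calibration import (TimeSeries, ddi_assessment, fit_4pl,
                                fit_egfr_recovery, fit_folate_cytotoxicity,
                                fit_gamma_bim, fit_gamma_egfr,
                                fit_simeoni_control, fit_two_compartment,
                                folate_mini_model, folate_steady_state,
                                four_pl, gamma_egfr_model, nca,
                                simeoni_control_model,
                                two_compartment_profile)

KNG_IN_VITRO = 0.0203          # 1/h, scaled from the in vivo growth rate


class TestEgfrRecovery:
    def test_zero_noise_round_trip(self):
        t = np.array([0.0, 12, 24, 36, 48, 60, 72])
        y = 1.0 - np.exp(-1.5 * t / 24.0)
        fit = fit_egfr_recovery(TimeSeries(t, y))
        assert fit.converged
        assert fit["kout_EGFR"] == pytest.approx(1.5, abs=1e-6)

    def test_half_recovery_at_ln2_over_kout(self):
        kout = 1.5
        t_half = np.log(2.0) / kout * 24.0
        y = 1.0 - np.exp(-kout * np.array([t_half]) / 24.0)
        assert y[0] == pytest.approx(0.5)

    def test_plateau_is_one(self):
        t = np.array([0.0, 24, 48, 2000.0])
        y = 1.0 - np.exp(-1.5 * t / 24.0)
        assert y[-1] == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_flagged(self):
        fit = fit_egfr_recovery(TimeSeries(np.arange(5.0), np.zeros(5)))
        assert not fit.converged and "identifiable" in fit.message


class TestFourPL:
    def test_zero_noise_round_trip(self):
        conc = np.geomspace(0.5, 500.0, 9)
        resp = four_pl(conc, 0.02, 0.98, 14.49, 1.0)
        fit = fit_4pl(conc, resp)
        assert fit["EC50"] == pytest.approx(14.49, rel=1e-4)
        assert fit["hill"] == pytest.approx(1.0, rel=1e-4)

    def test_midpoint_is_half_span(self):
        assert four_pl(np.array([14.49]), 0.1, 0.9, 14.49, 2.0)[0] == \
            pytest.approx(0.5)

    def test_constant_response_flagged(self):
        fit = fit_4pl(np.geomspace(1, 100, 6), np.full(6, 0.4))
        assert not fit.converged and np.isnan(fit["EC50"])


class TestGammaEgfr:
    def test_model_matches_closed_form(self):
        """The treated/control ODE pair has the analytic solution
        TGI%(t) = (1 - exp(kng t (E^g - 1))) * 100."""
        t = np.array([24.0, 48, 72, 96, 120])
        for gamma in (0.3, 0.5, 1.5):
            num = gamma_egfr_model(t, gamma, 0.0967, KNG_IN_VITRO)
            closed = (1.0 - np.exp(KNG_IN_VITRO * t
                                   * (0.0967 ** gamma - 1.0))) * 100.0
            assert np.allclose(num, closed, rtol=1e-6)

    def test_gamma_zero_means_no_inhibition(self):
        t = np.array([24.0, 72, 120])
        assert np.allclose(gamma_egfr_model(t, 0.0, 0.5, KNG_IN_VITRO), 0.0,
                           atol=1e-8)

    def test_zero_noise_round_trip(self):
        t = np.array([24.0, 48, 72, 96, 120])
        data = gamma_egfr_model(t, 0.5, 0.0967, KNG_IN_VITRO)
        fit = fit_gamma_egfr(TimeSeries(t, data), 0.0967, KNG_IN_VITRO)
        assert fit["gamma_EGFR"] == pytest.approx(0.5, rel=1e-4)

    def test_baseline_egfr_not_identifiable(self):
        fit = fit_gamma_egfr(TimeSeries(np.arange(5.0), np.zeros(5)),
                             1.0, KNG_IN_VITRO)
        assert not fit.converged


FIXED_FOLATE = {"kng": KNG_IN_VITRO, "kout_enzyme": 0.12,
                "kout_folate": 0.15, "EC50_pem": 0.47315,
                "EC50_folate": 0.5, "k1": 0.01 / 24.0, "k2": 0.05 / 24.0,
                "gamma_folate": 1.0}
PEM_300NM_MG_L = 0.12822       # 300 nM pemetrexed in mass units


class TestFolateBlock:
    def test_null_effect_gives_zero_tgi(self):
        # k1 = 0: without drug effect or natural transition both arms
        # are the same exponential, so inhibition vanishes identically
        p = dict(FIXED_FOLATE, k1=0.0, Emax_pem=0.0, gamma_enzyme=1.0,
                 Emax_folate=10.0)
        t = np.array([24.0, 48, 72, 96, 120])
        assert np.allclose(folate_mini_model(t, PEM_300NM_MG_L, p), 0.0,
                           atol=1e-6)

    def test_zero_noise_round_trip(self):
        truth = dict(Emax_pem=10.0, gamma_enzyme=1.5, Emax_folate=12.0)
        p = dict(FIXED_FOLATE, **truth)
        t = np.array([24.0, 48, 72, 96, 120])
        data = folate_mini_model(t, PEM_300NM_MG_L, p)
        fit = fit_folate_cytotoxicity(TimeSeries(t, data), PEM_300NM_MG_L,
                                      FIXED_FOLATE)
        for name, value in truth.items():
            assert fit[name] == pytest.approx(value, rel=1e-2), name

    def test_steady_state_matches_algebra(self):
        """Long-run enzyme and folate levels under constant PEM equal
        the algebraic fixed point of the turnover cascade."""
        p = dict(FIXED_FOLATE, Emax_pem=10.0, gamma_enzyme=1.5,
                 Emax_folate=0.0)
        from scipy.integrate import solve_ivp
        stim = p["Emax_pem"] * PEM_300NM_MG_L / (p["EC50_pem"]
                                                 + PEM_300NM_MG_L)

        def f(t, y):
            enz, fol = y
            return [p["kout_enzyme"] * (1 - enz * (1 + stim)),
                    p["kout_folate"] * (enz ** p["gamma_enzyme"] - fol)]

        sol = solve_ivp(f, (0, 500.0), [1.0, 1.0], rtol=1e-10, atol=1e-12)
        enz_ss, fol_ss = folate_steady_state(PEM_300NM_MG_L, p["Emax_pem"],
                                             p["EC50_pem"],
                                             p["gamma_enzyme"])
        assert sol.y[0, -1] == pytest.approx(enz_ss, abs=1e-6)
        assert sol.y[1, -1] == pytest.approx(fol_ss, abs=1e-6)

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="fewer time points"):
            fit_folate_cytotoxicity(TimeSeries([24.0], [5.0]),
                                    PEM_300NM_MG_L, FIXED_FOLATE)


class TestGammaBim:
    def test_exact_power_law(self):
        x = np.linspace(0.1, 0.9, 8)
        y = 2.5 * x ** 0.4
        fit = fit_gamma_bim(x, y)
        assert fit["gamma_bim"] == pytest.approx(0.4, rel=1e-9)
        assert fit["gain"] == pytest.approx(2.5, rel=1e-9)

    def test_flat_when_gamma_zero(self):
        x = np.linspace(0.1, 0.9, 8)
        fit = fit_gamma_bim(x, np.full(8, 3.0))
        assert fit["gamma_bim"] == pytest.approx(0.0, abs=1e-12)

    def test_noisy_recovery_within_15pct(self):
        rng = np.random.default_rng(7)
        x = np.linspace(0.1, 0.9, 8)
        y = 2.0 * x ** 0.6 * np.exp(rng.normal(0, 0.1, 8))
        fit = fit_gamma_bim(x, y)
        assert fit["gamma_bim"] == pytest.approx(0.6, rel=0.15)

    def test_nonpositive_points_excluded(self):
        with pytest.warns(UserWarning, match="non-positive"):
            fit = fit_gamma_bim([0.0, 0.2, 0.5, 0.8], [1, 1.2, 1.5, 1.7])
        assert fit.converged


class TestSimeoniControl:
    def test_zero_noise_round_trip(self):
        t = np.arange(0.0, 22.0, 3.0) * 24.0
        v = simeoni_control_model(t, 0.1032, 51.08, 200.0)
        fit = fit_simeoni_control(TimeSeries(t, v), V0=200.0)
        assert fit["lambda0"] == pytest.approx(0.1032, rel=1e-2)
        assert fit["lambda1"] == pytest.approx(51.08, rel=1e-2)

    def test_exponential_segment_log_slope(self):
        t = np.linspace(0.0, 96.0, 9)
        v = simeoni_control_model(t, 0.1032, 51.08, 10.0)  # deep exp phase
        slope = np.polyfit(t / 24.0, np.log(v), 1)[0]
        assert slope == pytest.approx(0.1032, rel=1e-3)

    def test_linear_regime_slope_is_lambda1(self):
        t = np.linspace(0.0, 240.0, 11)
        v = simeoni_control_model(t, 0.1032, 51.08, 5000.0)
        dv = np.diff(v) / np.diff(t / 24.0)
        assert np.allclose(dv, 51.08, rtol=1e-3)


PK_TRUTH = dict(ka=6.0, V1=0.5, k12=0.2, k21=3.0, kel=1.3)


class TestTwoCompartment:
    def test_zero_noise_round_trip(self):
        t = np.array([0.083, 0.25, 0.5, 0.75, 1, 1.5, 2, 3, 4, 6, 8])
        c = two_compartment_profile(t, 35.0, **PK_TRUTH)
        fit = fit_two_compartment(TimeSeries(t, c), dose=35.0, route="ip")
        for name, value in PK_TRUTH.items():
            assert fit[name] == pytest.approx(value, rel=1e-2), name

    def test_iv_without_distribution_is_monoexponential(self):
        t = np.linspace(0.1, 6.0, 12)
        c = two_compartment_profile(t, 10.0, ka=0.0, V1=1.0, k12=1e-12,
                                    k21=1.0, kel=0.7, route="iv")
        slope = np.polyfit(t, np.log(c), 1)[0]
        assert slope == pytest.approx(-0.7, rel=1e-6)

    def test_fit_reproduces_nca_auc(self):
        """Fitted micro-constants imply AUCinf = dose/(V1 kel), matching
        the trapezoid + extrapolation estimate on the same profile."""
        t = np.geomspace(0.05, 12.0, 40)
        c = two_compartment_profile(t, 35.0, **PK_TRUTH)
        fit = fit_two_compartment(TimeSeries(t, c), dose=35.0, route="ip")
        auc_model = 35.0 / (fit["V1"] * fit["kel"])
        auc_nca = nca(TimeSeries(t, c)).AUCinf
        assert auc_nca == pytest.approx(auc_model, rel=0.02)

    def test_flat_profile_flagged(self):
        fit = fit_two_compartment(TimeSeries(np.arange(6.0), np.ones(6)),
                                  dose=1.0)
        assert not fit.converged


class TestNCA:
    def test_exponential_auc(self):
        t = np.linspace(0.0, 20.0, 400)
        c = 8.0 * np.exp(-0.5 * t)
        res = nca(TimeSeries(t, c))
        assert res.AUCinf == pytest.approx(8.0 / 0.5, rel=1e-2)
        assert res.t_half == pytest.approx(np.log(2) / 0.5, rel=1e-2)

    def test_single_point_errors(self):
        with pytest.raises(ValueError):
            nca(TimeSeries([1.0], [2.0]))

    def test_two_compartment_closed_form_auc(self):
        t = np.geomspace(0.02, 30.0, 200)
        c = two_compartment_profile(t, 35.0, **PK_TRUTH)
        res = nca(TimeSeries(t, c))
        assert res.AUCinf == pytest.approx(
            35.0 / (PK_TRUTH["V1"] * PK_TRUTH["kel"]), rel=1e-2)

    def test_auclast_stable_under_interpolation(self):
        """Inserting points on a log-linear segment leaves the
        log-trapezoid AUC essentially unchanged."""
        t = np.array([0.0, 1, 2, 4, 8.0])
        c = 5.0 * np.exp(-0.4 * t)
        base = nca(TimeSeries(t, c)).AUClast
        t2 = np.sort(np.concatenate([t, [1.5, 3.0, 6.0]]))
        dense = nca(TimeSeries(t2, 5.0 * np.exp(-0.4 * t2))).AUClast
        assert dense == pytest.approx(base, rel=1e-3)


class TestDDI:
    def _res(self, cmax, auc):
        from pemosi.calibration import NCAResult
        return NCAResult(Cmax=cmax, Tmax=1.0, AUClast=auc, AUCinf=auc,
                         t_half=1.0, lambda_z=0.7)

    def test_unity_ratio_no_ddi(self):
        out = ddi_assessment(self._res(10, 50), self._res(10, 50))
        assert out["no_meaningful_ddi"]

    def test_observed_1p31_auc_flagged(self):
        # a 1.31-fold AUC ratio falls outside the 0.8-1.25 window
        out = ddi_assessment(self._res(10, 65.5), self._res(10, 50))
        assert not out["no_meaningful_ddi"]
        assert out["ratios"]["AUClast"] == pytest.approx(1.31)

    def test_boundary_1p25_inside_closed_window(self):
        out = ddi_assessment(self._res(12.5, 62.5), self._res(10, 50))
        assert out["no_meaningful_ddi"]

    def test_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            ddi_assessment(self._res(10, 50), self._res(0.0, 50))
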