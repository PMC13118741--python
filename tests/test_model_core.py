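"""Core ODE system: concentrations, fluxes, simulation and metrics."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.linalg import expm

import pemosi
from pemosi import engine
from pemosi.engine import IDX, N_STATE
from pemosi.params import ModelParams, pack
from pemosi.regimen import DoseEvent, Regimen, build_regimen


def state_with(params, **components) -> np.ndarray:
    y = engine.initial_state(params.tgi.V0, n=1)[0]
    for name, value in components.items():
        y[IDX[name]] = value
    return y


class TestPlasmaConcentrations:
    def test_empty_compartment(self, params):
        cpem, cosi = pemosi.plasma_concentrations(
            state_with(params, Xpem_1=0.0), params)
        assert cpem == 0.0

    def test_division_by_volume(self, params):
        p = params.with_updates(V1_pem=0.1)
        cpem, _ = pemosi.plasma_concentrations(state_with(p, Xpem_1=1.0), p)
        assert cpem == pytest.approx(10.0)      # 1 mg/kg over 0.1 L/kg

    def test_osi_apparent_volume_scale(self, params):
        _, cosi = pemosi.plasma_concentrations(
            state_with(params, Xosi_1=1.0), params)
        expected = 1.0 / (params.osi.V1_osi / params.osi.Fa_osi) * 1000.0
        assert cosi == pytest.approx(expected)  # ug/L

    def test_nonfinite_state_names_component(self, params):
        y = state_with(params, Xosi_2=np.nan)
        with pytest.raises(ValueError, match="Xosi_2"):
            pemosi.plasma_concentrations(y, params)

    def test_bolus_limit_matches_analytic_two_compartment(self, params):
        """With ka -> infinity the i.p. dose behaves as a central bolus;
        Cmax at t=0+ is dose/V1 and the profile follows the closed-form
        bi-exponential solution."""
        dose = 35.0
        p = params.with_updates(ka_pem=1e4)
        reg = Regimen(events=(DoseEvent(0.0, "PEM", dose),),
                      strategy_label="custom")
        grid = np.linspace(0.005, 8.0, 60)
        traj = pemosi.simulate(reg, p, t_end=8.0, output_grid=grid)
        cpem = traj.concentrations()[0]
        # independent closed-form bolus oracle on the 2x2 linear system
        pk = p.pem
        A = np.array([[-(pk.k12_pem + pk.kel_pem), pk.k21_pem],
                      [pk.k12_pem, -pk.k21_pem]])
        oracle = np.array(
            [(expm(A * t) @ [dose, 0.0])[0] / pk.V1_pem for t in grid])
        assert np.allclose(cpem, oracle, rtol=2e-3)
        assert cpem[0] == pytest.approx(dose / pk.V1_pem, rel=2e-2)


class TestRHS:
    def test_drug_free_homeostasis(self, params):
        """Enzyme, folate and EGFR are stationary at baseline 1 without
        drug, and a pure-X1 tumor only grows."""
        y = engine.initial_state(params.tgi.V0, n=1)
        dy = engine.rhs(0.0, y, pack(params))[0]
        for name in ("Enzyme", "Folate", "EGFR"):
            assert dy[IDX[name]] == pytest.approx(0.0, abs=1e-12)

    def test_half_maximal_osi_inhibition(self, params):
        """At Cosi = EC50 with gamma 1 the EGFR loss multiplier is
        1 + Imax/2, read off the EGFR derivative."""
        eg = params.egfr
        amount = eg.EC50_osi / 1000.0 * (params.osi.V1_osi
                                         / params.osi.Fa_osi)
        y = engine.initial_state(params.tgi.V0, n=1)
        y[0, IDX["Xosi_1"]] = amount
        dy = engine.rhs(0.0, y, pack(params))[0]
        kout_h = eg.kout_EGFR / 24.0
        expected = kout_h - kout_h * (1.0 + eg.Imax_osi / 2.0)
        assert dy[IDX["EGFR"]] == pytest.approx(expected, rel=1e-9)

    def test_no_bim_amplification_at_baseline_egfr(self, params):
        """With EGFR exactly 1 the damaged-cell transit runs at the
        natural rate k2."""
        y = engine.initial_state(params.tgi.V0, n=1)
        y[0, IDX["X2"]] = 50.0
        dy = engine.rhs(0.0, y, pack(params))[0]
        k2_h = params.tgi.k2 / 24.0
        assert dy[IDX["X3"]] == pytest.approx(k2_h * 50.0, rel=1e-12)

    def test_flux_symmetry_x1_to_x2(self, params):
        """X1 outflow and X2 inflow use one shared expression: with the
        transit disabled the X2 gain equals the non-growth X1 loss."""
        p = params.with_updates(k2=1e-9)
        y = engine.initial_state(params.tgi.V0, n=1)
        y[0, IDX["Folate"]] = 0.2     # active folate-deficit kill
        P = pack(p)
        dy = engine.rhs(0.0, y, P)[0]
        lam0_h = p.tgi.lambda0 / 24.0
        X = p.tgi.V0
        growth = (lam0_h * X
                  / (1.0 + (lam0_h / (p.tgi.lambda1 / 24.0) * X)
                     ** p.tgi.psi) ** (1.0 / p.tgi.psi))
        assert dy[IDX["X2"]] == pytest.approx(growth - dy[IDX["X1"]],
                                              rel=1e-12)


class TestSimulate:
    def test_control_matches_linear_system_oracle(self, params):
        """Deep in the exponential regime the drug-free system is
        linear; the four-compartment matrix exponential is an
        independent closed-form oracle."""
        # feedback off so the drug-free system is exactly linear
        p = params.with_updates(V0=1.0, k_feedback=0.0)
        reg = build_regimen("control", n_cycles=1)
        grid = np.linspace(0.0, 168.0, 22)
        traj = pemosi.simulate(reg, p, t_end=168.0, output_grid=grid)
        lam0, k1, k2 = (p.tgi.lambda0 / 24, p.tgi.k1 / 24, p.tgi.k2 / 24)
        A = np.array([[lam0 - k1, 0, 0, 0],
                      [k1, -k2, 0, 0],
                      [0, k2, -k2, 0],
                      [0, 0, k2, -k2]])
        oracle = np.array([(expm(A * t) @ [1.0, 0, 0, 0]).sum()
                           for t in grid])
        assert np.allclose(traj.volume, oracle, rtol=1e-3)

    def test_null_drug_effect_reduces_to_control(self, params):
        """Emax_pem = Imax_osi = 0: dosing both drugs leaves the
        PD/tumor trajectory identical to control."""
        p = params.with_updates(Emax_pem=0.0, Imax_osi=0.0)
        treated = pemosi.simulate(
            build_regimen("concurrent", n_cycles=1), p, engine_name="rk4")
        control = pemosi.simulate(build_regimen("control", n_cycles=1), p,
                                  engine_name="rk4")
        for name in ("Enzyme", "Folate", "EGFR", "X1", "X2", "X3", "X4",
                     "CumDead"):
            assert np.array_equal(treated.states[:, IDX[name]],
                                  control.states[:, IDX[name]]), name

    def test_mass_balance(self, params, one_cycle_sequential):
        """X + CumDead - V0 - integral of growth vanishes (relative to
        X) along a treated trajectory; growth is accumulated as an
        auxiliary quadrature state."""
        P = pack(params)

        def f_aug(t, y):
            Y = y[:N_STATE].reshape(1, N_STATE)
            dy = engine.rhs(t, Y, P)[0]
            lam0_h = P[23]
            x1 = Y[0, IDX["X1"]]
            X = Y[0, 9:13].sum()
            growth = (lam0_h * x1 * max(Y[0, IDX["EGFR"]], 0.0) ** P[31]
                      / (1.0 + (lam0_h / P[24] * X) ** P[25])
                      ** (1.0 / P[25]))
            return np.concatenate([dy, [growth]])

        y0 = np.concatenate([engine.initial_state(params.tgi.V0)[0], [0.0]])
        t = 0.0
        for event in list(one_cycle_sequential.events) + [None]:
            t1 = event.time if event is not None else 168.0
            if t1 > t:
                sol = solve_ivp(f_aug, (t, t1), y0, rtol=1e-9, atol=1e-12,
                                method="LSODA")
                y0 = sol.y[:, -1]
                t = t1
            if event is not None:
                idx = IDX["Xpem_a"] if event.drug == "PEM" else IDX["Xosi_a"]
                y0[idx] += event.amount
        X = y0[9:13].sum()
        residual = X + y0[IDX["CumDead"]] - params.tgi.V0 - y0[-1]
        assert abs(residual) / X < 1e-4

    def test_positivity_and_cumdead_monotone(self, sequential_trajectory):
        s = sequential_trajectory.states
        assert s.min() >= -1e-9 * max(1.0, abs(s).max())
        assert np.all(np.diff(sequential_trajectory.cum_dead) >= -1e-12)

    def test_baseline_fixed_point_long_horizon(self, params):
        # no damage feedback: the (1,1,1) PD state is an exact fixed point
        p = params.with_updates(k_feedback=0.0)
        reg = Regimen(events=(), strategy_label="control",
                      n_cycles=1, cycle_length_days=1000 / 24)
        traj = pemosi.simulate(reg, p, t_end=1000.0,
                               output_grid=np.linspace(0, 1000, 11))
        for name in ("Enzyme", "Folate", "EGFR"):
            assert np.allclose(traj.states[:, IDX[name]], 1.0, atol=1e-5)

    def test_engines_agree(self, params, one_cycle_sequential):
        a = pemosi.simulate(one_cycle_sequential, params,
                            engine_name="lsoda")
        b = pemosi.simulate(one_cycle_sequential, params, engine_name="rk4")
        assert np.allclose(a.volume, b.volume, rtol=5e-3)

    def test_rejects_events_beyond_horizon(self, params):
        reg = Regimen(events=(DoseEvent(100.0, "PEM", 35.0),))
        with pytest.raises(ValueError, match="beyond"):
            pemosi.simulate(reg, params, t_end=50.0)


class TestBuildRegimen:
    def test_sequential_first_osi_at_interval(self):
        reg = build_regimen("sequential", interval_h=48.0, n_cycles=1)
        osi = [e.time for e in reg.events if e.drug == "OSI"]
        assert osi[0] == 48.0
        assert np.allclose(np.diff(osi), 24.0)

    def test_concurrent_first_osi_at_zero(self):
        reg = build_regimen("concurrent", n_cycles=1)
        assert min(e.time for e in reg.events if e.drug == "OSI") == 0.0

    def test_control_is_empty(self):
        assert build_regimen("control").events == ()

    def test_pem_tid_two_days_per_cycle(self):
        reg = build_regimen("PEM", n_cycles=2)
        pem = [e.time for e in reg.events if e.drug == "PEM"]
        assert pem == [0.0, 4.0, 8.0, 24.0, 28.0, 32.0,
                       168.0, 172.0, 176.0, 192.0, 196.0, 200.0]

    def test_unknown_strategy(self):
        with pytest.raises(ValueError, match="unknown strategy"):
            build_regimen("tid")

    def test_events_sorted_and_frame_round_trip(self):
        reg = build_regimen("sequential", interval_h=24.0, n_cycles=2)
        times = [e.time for e in reg.events]
        assert times == sorted(times)
        back = Regimen.from_frame(reg.to_frame())
        assert [e.time for e in back.events] == times


class TestDerivedMetrics:
    def _traj(self, params, x1, x2, x3, x4, n_t=3):
        states = np.zeros((n_t, N_STATE))
        states[:, IDX["X1"]] = x1
        states[:, IDX["X2"]] = x2
        states[:, IDX["X3"]] = x3
        states[:, IDX["X4"]] = x4
        return pemosi.Trajectory(times=np.arange(n_t, dtype=float),
                                 states=states, params=params,
                                 regimen=build_regimen("control"))

    def test_pure_proliferating(self, params):
        t = self._traj(params, 100, 0, 0, 0)
        m = pemosi.derived_metrics(t, t)
        assert np.all(m["DamagedPct"] == 0.0)
        assert np.all(m["X1Pct"] == 100.0)

    def test_equal_compartments_damaged_75(self, params):
        t = self._traj(params, 25, 25, 25, 25)
        m = pemosi.derived_metrics(t, t)
        assert np.allclose(m["DamagedPct"], 75.0)

    def test_identical_arms_zero_tgi(self, params):
        t = self._traj(params, 50, 10, 5, 1)
        m = pemosi.derived_metrics(t, t)
        assert np.allclose(m["TGIPct"], 0.0)

    def test_grid_mismatch_raises(self, params):
        a = self._traj(params, 50, 0, 0, 0, n_t=3)
        b = self._traj(params, 50, 0, 0, 0, n_t=4)
        with pytest.raises(ValueError, match="time grid"):
            pemosi.derived_metrics(a, b)


def test_parameter_validation_lists_all_problems():
    with pytest.raises(ValueError) as err:
        pemosi.TGIParams(lambda0=-1.0, EC50_folate=2.0)
    assert "lambda0" in str(err.value) and "EC50_folate" in str(err.value)


def test_with_updates_rejects_unknown_names(params):
    with pytest.raises(KeyError):
        params.with_updates(not_a_parameter=1.0)
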