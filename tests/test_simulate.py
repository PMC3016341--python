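"""Forward integration: steady states, conservation, convergence, oracles."""

import numpy as np
import pytest

from mousemetab import (
    CHOW,
    ActivitySchedule,
    BodyState,
    IntakeSchedule,
    ModelParameters,
    SimulationError,
    alpha,
    maintenance_EI,
    simulate,
)
from mousemetab._fastsim import simulate_states
from mousemetab.simulate import TRAJECTORY_COLUMNS


def constant_chow(EI: float) -> IntakeSchedule:
    return IntakeSchedule(np.array([0.0]), np.array([EI]), (CHOW,), baseline_EI=EI)


QUIET = ActivitySchedule(switches=())


class TestSteadyState:
    def test_maintenance_intake_holds_composition(self, params, init_state):
        EI = maintenance_EI(init_state, 0.22, params)
        traj = simulate(init_state, constant_chow(EI), QUIET, params, horizon=50.0)
        assert np.max(np.abs(traj["FM_g"] - init_state.FM)) < 1e-6
        assert np.max(np.abs(traj["FFM_g"] - init_state.FFM)) < 1e-6

    def test_small_overfeed_slope_matches_closed_form(self, params, init_state):
        """One extra kcal/d above maintenance (beta = 0, lambda fixed) gains
        fat at 1/(rho_FM + a*rho_FFM + eta_FM + a*eta_FFM) g/d initially."""
        p0 = params.replace(beta=0.0)
        EI = maintenance_EI(init_state, 0.22, p0) + 1.0
        traj = simulate(init_state, constant_chow(EI), QUIET, p0, horizon=5.0,
                        dt_out=0.5)
        a = alpha(init_state.FM, p0)
        pred = 1.0 / (p0.rho_FM + a * p0.rho_FFM + p0.eta_FM + a * p0.eta_FFM)
        slope = (traj["FM_g"][2] - traj["FM_g"][0]) / 1.0
        assert slope == pytest.approx(pred, rel=0.05)
        assert np.all(np.diff(traj["FM_g"]) > 0)


class TestConservationAndIdentities:
    def test_pointwise_balance_identity(self, params, init_state,
                                        hf_episode_intake, two_switch_activity):
        traj = simulate(init_state, hf_episode_intake, two_switch_activity,
                        params, horizon=100.0)
        lhs = traj["EI_kcal_d"] - traj["EE_kcal_d"]
        rhs = (params.rho_FM * traj["dFM_dt_g_d"]
               + params.rho_FFM * traj["dFFM_dt_g_d"])
        assert np.max(np.abs(lhs - rhs)) < 1e-9

    def test_partition_coupling_by_finite_differences(self, params, init_state,
                                                      hf_episode_intake,
                                                      two_switch_activity):
        traj = simulate(init_state, hf_episode_intake, two_switch_activity,
                        params, horizon=100.0, dt_out=0.1)
        fm, ffm, t = traj["FM_g"], traj["FFM_g"], traj["t_d"]
        dfm = np.gradient(fm, t)
        dffm = np.gradient(ffm, t)
        mid = slice(5, -5)
        expected = alpha(fm[mid], params) * dfm[mid]
        assert np.max(np.abs(dffm[mid] - expected)) < 2e-3

    def test_component_columns_sum_to_ee(self, params, init_state,
                                         hf_episode_intake, two_switch_activity):
        traj = simulate(init_state, hf_episode_intake, two_switch_activity,
                        params, horizon=100.0)
        total = sum(
            traj[c] for c in (
                "ee_basal", "ee_ffm_metab", "ee_fm_metab", "ee_activity",
                "ee_dit", "ee_deposition",
            )
        )
        assert np.max(np.abs(total - traj["EE_kcal_d"])) < 1e-9


class TestSolverQuality:
    def test_tolerance_halving_convergence(self, params, init_state,
                                           hf_episode_intake, two_switch_activity):
        kw = dict(horizon=100.0, dt_out=100.0)
        a = simulate(init_state, hf_episode_intake, two_switch_activity, params,
                     rtol=1e-8, atol=1e-10, **kw)
        b = simulate(init_state, hf_episode_intake, two_switch_activity, params,
                     rtol=5e-9, atol=5e-11, **kw)
        assert abs(a["FM_g"][-1] - b["FM_g"][-1]) < 1e-4

    def test_fixed_step_euler_oracle(self, params, init_state,
                                     hf_episode_intake, two_switch_activity):
        """Explicit Euler at dt = 0.001 d, written independently of the
        solver, reproduces the adaptive terminal fat mass."""
        from mousemetab.expenditure import lambda_at, resolve_energy_balance

        horizon, dt = 70.0, 1e-3
        edges = np.unique(np.concatenate(
            [[0.0, horizon],
             hf_episode_intake.times[(hf_episode_intake.times > 0)
                                     & (hf_episode_intake.times < horizon)],
             two_switch_activity.switch_times()]
        ))
        fm, ffm = init_state.FM, init_state.FFM
        for a, b in zip(edges[:-1], edges[1:]):
            n = int(round((b - a) / dt))
            h = (b - a) / n
            t = a
            for _ in range(n):
                EI = float(hf_episode_intake.EI_at(t))
                dEI = EI - hf_episode_intake.baseline_EI
                lam = lambda_at(t, two_switch_activity)
                r = resolve_energy_balance(BodyState(fm, ffm), EI, dEI, lam, params)
                fm += h * r.dFM_dt
                ffm += h * r.dFFM_dt
                t += h
        traj = simulate(init_state, hf_episode_intake, two_switch_activity,
                        params, horizon=horizon, dt_out=horizon)
        assert abs(traj["FM_g"][-1] - fm) < 1e-3

    def test_fast_fixed_step_path_matches_adaptive(self, params, init_state,
                                                   hf_episode_intake,
                                                   two_switch_activity):
        t_eval = np.arange(0.0, 101.0, 7.0)
        FM, FFM = simulate_states(init_state, hf_episode_intake,
                                  two_switch_activity, params, t_eval, dt=1.0)
        traj = simulate(init_state, hf_episode_intake, two_switch_activity,
                        params, horizon=100.0)
        fm_ref = np.interp(t_eval, traj["t_d"], traj["FM_g"])
        ffm_ref = np.interp(t_eval, traj["t_d"], traj["FFM_g"])
        assert np.max(np.abs(FM - fm_ref)) < 1e-4
        assert np.max(np.abs(FFM - ffm_ref)) < 1e-4


class TestMonotonicityAndErrors:
    def test_uniformly_larger_intake_dominates(self, params, init_state,
                                               hf_episode_intake,
                                               two_switch_activity):
        richer = IntakeSchedule(
            hf_episode_intake.times, hf_episode_intake.EI + 0.5,
            hf_episode_intake.diets, baseline_EI=hf_episode_intake.baseline_EI,
        )
        lo = simulate(init_state, hf_episode_intake, two_switch_activity,
                      params, horizon=100.0)
        hi = simulate(init_state, richer, two_switch_activity, params,
                      horizon=100.0)
        assert np.all(hi["FM_g"] >= lo["FM_g"] - 1e-12)

    def test_domain_exit_names_time(self, params, init_state):
        starved = constant_chow(0.0)
        with pytest.raises(SimulationError, match=r"t="):
            simulate(init_state, starved, QUIET, params, horizon=200.0)

    def test_output_columns_and_csv_roundtrip(self, tmp_path, params, init_state,
                                              hf_episode_intake,
                                              two_switch_activity):
        from mousemetab import Trajectory

        traj = simulate(init_state, hf_episode_intake, two_switch_activity,
                        params, horizon=30.0)
        assert list(traj.data.columns) == TRAJECTORY_COLUMNS
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        back = Trajectory.from_csv(path)
        assert np.allclose(back["FM_g"], traj["FM_g"])
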