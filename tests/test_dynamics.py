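import math

import numpy as np
import pytest

from bombusdeb.dynamics import (
    ColonyState,
    SeasonEvent,
    Trajectory,
    euler_step,
    extinction_time,
    reproductive_jump,
    run_growth_phase,
    run_multi_year,
)
from bombusdeb.fluxes import compute_fluxes
from bombusdeb.foraging import compute_distribution
from bombusdeb.landscape import ProductionSchedule, build_grid
from bombusdeb.params import DebParams
from bombusdeb.scenarios import build_scenario, run_scenario


class TestDerivatives:
    def test_quiescent_state(self, grid5, params):
        from bombusdeb.dynamics import derivatives

        state = ColonyState(N=0.0, P=0.0, V=0.0, R=1.0, n_max=0.0)
        alloc = compute_distribution(0, 0, 0, grid5, params)
        fx = compute_fluxes(0, 0, 0, 0, alloc, grid5, params)
        theta_free = params.replace(theta=0.0)
        assert derivatives(state, fx, theta_free) == (0.0, 0.0, 0.0)

    def test_starvation_death_rate(self, grid5, params):
        """With empty nectar reserves the per-capita death rate is 1.05/day."""
        from bombusdeb.dynamics import derivatives

        state = ColonyState(N=0.0, P=0.0, V=100.0, R=1.0, n_max=100.0)
        alloc = compute_distribution(0, 0, 100.0, grid5, params)
        fx = compute_fluxes(0, 0, 100.0, 100.0, alloc, grid5, params)
        _, _, dV = derivatives(state, fx, params)
        # no ingestion (empty landscape), no growth: pure death
        assert dV == pytest.approx(-(0.05 + 1.0) * 100.0)

        rich = ColonyState(N=1e6, P=0.0, V=100.0, R=1.0, n_max=100.0)
        fx2 = compute_fluxes(1e6, 0, 100.0, 100.0, alloc, grid5, params)
        _, _, dV2 = derivatives(rich, fx2, params.replace(theta=0.0))
        assert dV2 == pytest.approx(-0.05 * 100.0)


class TestEulerStep:
    def test_matches_independent_hand_calculation(self):
        """One step agrees with a from-scratch evaluation of the equations."""
        p = DebParams()
        grid = build_grid(3, 1.0)
        stocks_n = np.linspace(5.0, 45.0, 9)
        stocks_p = np.linspace(40.0, 8.0, 9)
        grid.nectar[:] = stocks_n
        grid.pollen[:] = stocks_p
        state = ColonyState(t=3.0, N=2.0, P=1.0, V=10.0, R=1.0, n_max=12.0)
        schedule = ProductionSchedule(9, background_nectar=0.3,
                                      background_pollen=0.2)

        # --- independent oracle, plain numpy -------------------------------
        d = grid.distances
        n_t = p.alpha * state.V
        w_n = p.lam * (state.P + p.eps_p)
        w_p = state.N + p.eps_n
        n_n = n_t * w_n / (w_n + w_p)
        n_p = n_t - n_n
        g_n = stocks_n * p.c_x_n / (stocks_n + p.c_x_n * n_n) - p.c_c * d
        w = np.exp((g_n - g_n.max()) / p.temperature)
        rho_n = w / w.sum()
        d_max = d.max()
        g_p = (stocks_p * p.c_x_p / (stocks_p + p.c_x_p * n_p)
               - p.c_x_p * d / d_max)
        w = np.exp((g_p - g_p.max()) / p.temperature)
        rho_p = w / w.sum()
        a_n = p.c_x_n * n_n * rho_n
        u_n = a_n * stocks_n / (stocks_n + a_n)
        a_p = p.c_x_p * n_p * rho_p
        u_p = a_p * stocks_p / (stocks_p + a_p)
        maint_n = p.c_m1_n * p.alpha * state.V
        maint_p = p.c_m1_p * p.alpha * state.V + p.c_m2_p * p.beta * state.V
        p_h = p.c_h * state.n_max
        p_c = p.c_c * np.sum((n_n * rho_n + n_p * rho_p) * d)
        root_v = math.sqrt(state.V)
        p_g = (p.kappa * state.P / (state.P + root_v * p.eps_p)
               * state.N / (state.N + root_v * p.eps_n))
        dN = u_n.sum() - maint_n - p_h - p_c - p.theta * state.N
        dP = u_p.sum() - maint_p - p_g
        death = p.delta_0 + p.delta_n * math.exp(-state.N / p.eps_n)
        dV = (state.R / p.e_g) * p_g - death * state.V
        exp_N = max(0.0, state.N + 0.1 * dN)
        exp_P = max(0.0, state.P + 0.1 * dP)
        exp_V = max(0.0, state.V + 0.1 * dV)
        exp_stock_n = np.maximum(
            stocks_n + 0.1 * (0.3 - u_n - p.gamma_n * stocks_n**2), 0.0
        )
        # -------------------------------------------------------------------

        new_state, _, _ = euler_step(state, grid, schedule, p, dt=0.1)
        assert new_state.N == pytest.approx(exp_N, rel=1e-12)
        assert new_state.P == pytest.approx(exp_P, rel=1e-12)
        assert new_state.V == pytest.approx(exp_V, rel=1e-12)
        assert new_state.t == pytest.approx(3.1)
        assert new_state.n_max == max(12.0, p.alpha * exp_V)
        assert grid.nectar == pytest.approx(exp_stock_n, rel=1e-12)

    def test_extinct_colony_is_inert_but_landscape_accrues(self, grid5, params):
        state = ColonyState(N=0.0, P=0.0, V=0.0, R=1.0, n_max=0.0)
        schedule = ProductionSchedule(25, background_nectar=1.0)
        new_state, _, _ = euler_step(state, grid5, schedule, params, dt=0.1)
        assert (new_state.N, new_state.P, new_state.V) == (0.0, 0.0, 0.0)
        assert np.all(grid5.nectar > 0)

    def test_extinction_absorbing_even_with_reserves(self, grid5, params):
        # a dead colony with leftover reserves must not resurrect
        state = ColonyState(N=50.0, P=50.0, V=0.0, R=1.0, n_max=100.0)
        schedule = ProductionSchedule(25)
        for _ in range(20):
            state, _, _ = euler_step(state, grid5, schedule, params, dt=0.1)
        assert state.V == 0.0

    def test_nonfinite_state_raises(self, grid5, params):
        bad = ColonyState(N=float("nan"), P=0.0, V=1.0, R=1.0)
        with pytest.raises(FloatingPointError):
            euler_step(bad, grid5, ProductionSchedule(25), params, dt=0.1)


class TestRunGrowthPhase:
    def test_step_count_and_final_time(self, grid5, params):
        state = ColonyState(V=1.0, R=1.0)
        schedule = ProductionSchedule(25, background_nectar=0.5,
                                      background_pollen=0.5)
        end, traj = run_growth_phase(state, grid5, schedule, params,
                                     season_length=150.0, dt=0.1,
                                     record_stride=1)
        assert len(traj) == 1501  # 1500 steps + final sample
        assert end.t == pytest.approx(150.0)
        times = traj.to_dataframe()["t"].to_numpy()
        assert np.all(np.diff(times) > 0)

    def test_zero_production_decays_to_extinction(self, grid5, params):
        state = ColonyState(V=50.0, R=1.0)
        end, traj = run_growth_phase(state, grid5, ProductionSchedule(25),
                                     params, season_length=30.0, dt=0.1)
        df = traj.to_dataframe()
        assert end.V < 1e-3
        assert np.all(df[["N", "P", "V"]].to_numpy() >= 0.0)
        assert np.all(df["n_max"].to_numpy() >= params.alpha * df["V"].to_numpy())

    def test_rich_landscape_reaches_growth_plateau(self, params):
        """A well-fed colony rises to a characteristic maximum size."""
        trajs, _ = run_scenario(build_scenario("fig4a"), params,
                                record_stride=10)
        df = trajs[0].to_dataframe()
        v_final = df["V"].iloc[-1]
        assert v_final > 100.0
        # near-plateau over the final 30 days
        v_120 = df.loc[(df["t"] - 120).abs().idxmin(), "V"]
        assert abs(v_final - v_120) / v_final < 0.05

    def test_shortage_event_empties_stocks(self, grid5, params):
        state = ColonyState(V=1.0, R=1.0)
        schedule = ProductionSchedule(25, background_pollen=1.0)
        grid5.nectar[:] = 100.0
        _, traj = run_growth_phase(
            state, grid5, schedule, params, season_length=10.0, dt=0.1,
            events=(SeasonEvent(5.0, "clear_nectar"),),
        )
        df = traj.to_dataframe()
        assert df.loc[(df["t"] - 4.9).abs().idxmin(), "sum_F_N"] > 0
        assert df.loc[(df["t"] - 5.1).abs().idxmin(), "sum_F_N"] == 0.0


class TestReproductiveJump:
    def test_undersized_colony_only_suffers_mortality(self, params):
        state = ColonyState(t=150.0, N=3.0, P=4.0, V=1.0, R=1.0)
        after = reproductive_jump(state, params)
        assert after.R == pytest.approx(0.88)  # (1 - delta_R) R
        assert after.N == 0.0 and after.P == 0.0
        assert after.V == pytest.approx(params.eps_v * after.R)

    def test_large_colony_multiplies(self, params):
        state = ColonyState(t=150.0, V=170.0, R=1.0)
        after = reproductive_jump(state, params)
        expected_flux = 5.0 * math.atan((170.0 - 100.0) * 0.2)
        assert after.R == pytest.approx(1.0 + expected_flux - 0.12)
        assert after.V == pytest.approx(params.eps_v * after.R)

    def test_zero_colonies_stay_zero(self, params):
        after = reproductive_jump(ColonyState(V=0.0, R=0.0), params)
        assert after.R == 0.0 and after.V == 0.0


class TestMultiYear:
    def test_one_year_equals_growth_plus_jump(self, params):
        config = build_scenario("fig4a")
        grid, schedule, events, crop = config.realize()
        trajs, summary = run_multi_year(grid, schedule, params, years=1)
        grid2, schedule2, _, _ = config.realize()
        state = ColonyState(V=params.eps_v, R=1.0)
        end, traj = run_growth_phase(state, grid2, schedule2, params)
        assert summary.loc[0, "V_pre_impulse"] == end.V
        assert summary.loc[0, "R_pre_impulse"] == end.R
        assert len(summary) == 1

    def test_multi_year_colony_number_grows_then_stays_bounded(self, params):
        trajs, summary = run_scenario(
            build_scenario("fig8", level="low", years=6), params,
            record_stride=150,
        )
        r = summary["R_pre_impulse"].to_numpy()
        assert r[1] > r[0]  # early growth
        assert np.all(r > 0) and np.all(np.isfinite(r))
        assert len(trajs) == 6

    def test_identical_runs_are_bit_identical(self, params):
        config = build_scenario("fig5a")
        runs = []
        for _ in range(2):
            trajs, _ = run_scenario(config, params, record_stride=10)
            runs.append(trajs[0].to_dataframe())
        assert runs[0].equals(runs[1])


class TestExtinctionTime:
    @staticmethod
    def _traj_from(times, values):
        traj = Trajectory()
        for t, v in zip(times, values):
            traj.append({"t": t, "V": v})
        return traj

    def test_no_crossing_returns_none(self):
        traj = self._traj_from([0, 1, 2], [10.0, 9.0, 8.0])
        assert extinction_time(traj, threshold=1.0) is None

    def test_exponential_decay_crossing(self):
        times = np.arange(0, 8, 0.5)
        traj = self._traj_from(times, 100.0 * np.exp(-times))
        # V < 1 first happens after t = ln(100) ~ 4.61 -> first sample at 5.0
        assert extinction_time(traj, threshold=1.0) == 5.0

    def test_invalid_threshold(self):
        traj = self._traj_from([0.0], [1.0])
        with pytest.raises(ValueError):
            extinction_time(traj, threshold=0.0)
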