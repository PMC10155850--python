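"""Transient solver tests: equilibria, maximum principle, oracles."""

import numpy as np
import pytest

from scartherm import (
    BioheatSolver,
    DoseParams,
    GridSpec,
    SolverError,
    SolverSpec,
    TemperatureField,
    build_domain,
    grid_convergence_report,
    solve_transient,
)


@pytest.fixture(scope="module")
def small_grid():
    _, grid = build_domain("hps", GridSpec(dr_mm=0.5, dz_mm=0.2))
    return grid


class TestEquilibriaAndBounds:
    def test_body_temperature_is_a_fixed_point(self, small_grid):
        # T = T_art = boundaries with Q = 0 and an ambient clamped to 37
        spec = SolverSpec(t_end=0.5, bc_top="dirichlet", T_boundary=37.0)
        solver = BioheatSolver(small_grid, spec)
        out = solver.run()
        np.testing.assert_allclose(out.T_final, 37.0, atol=1e-9)

    def test_fixed_point_with_convective_top_is_near_body_temperature(self, small_grid):
        # with h = 10 W/(m^2 K) to 25 degC ambient the surface dips only
        # slightly below 37 over one second
        out = BioheatSolver(small_grid, SolverSpec(t_end=1.0)).run()
        assert out.T_final.max() <= 37.0 + 1e-9
        assert out.T_final.min() > 36.5

    def test_maximum_principle_without_source(self, small_grid):
        T0 = np.full((small_grid.nz, small_grid.nr), 37.0)
        T0[10:20, 0:10] = 50.0
        solver = BioheatSolver(small_grid, SolverSpec(t_end=1.0, bc_top="dirichlet"))
        state = TemperatureField(T0.copy(), 0.0)
        prev_max = 50.0
        for _ in range(40):
            state = solver.step(state, 2.5e-2)
            assert state.T.max() <= prev_max + 1e-9
            assert state.T.min() >= 37.0 - 1e-9
            prev_max = state.T.max()
        # hot spot strictly relaxes (mm-scale blocks cool over ~10 s,
        # so only partial decay is expected within one second)
        assert 37.0 < state.T.max() < 50.0

    def test_unphysical_temperatures_abort(self, small_grid):
        solver = BioheatSolver(small_grid, SolverSpec())
        hot = TemperatureField(np.full((small_grid.nz, small_grid.nr), 37.0), 0.0)
        blowup = np.full((small_grid.nz, small_grid.nr), 1e8)  # W/m^3, sustained
        with pytest.raises(SolverError, match="sanity"):
            state = hot
            for _ in range(100):
                state = solver.step(state, 0.05, blowup)


class TestPerfusionODEOracle:
    def test_uniform_source_follows_closed_form_perfusion_ode(self):
        # uniform Q, insulated boundaries, no vessel: every cell obeys
        # rho c dT/dt = rho_b c_b w_b (Tart - T) + Q exactly
        _, grid = build_domain("hps", GridSpec(dr_mm=0.5, dz_mm=0.2), vessel_radius=0.0)
        spec = SolverSpec(t_end=1.0, dt=1e-3, bc_top="insulated",
                          bc_bottom="insulated", bc_outer="insulated")
        solver = BioheatSolver(grid, spec)
        Q = 5e5  # W/m^3
        out = solver.run(extra_source=lambda t0, t1: np.full((grid.nz, grid.nr), Q))
        mat = grid.tissue
        perf = mat.perfusion_coefficient
        exact = 37.0 + Q / perf * (1.0 - np.exp(-perf * 1.0 / mat.rho_c))
        np.testing.assert_allclose(out.T_final, exact, rtol=5e-3)
        # and the field never develops a spatial gradient
        assert np.ptp(out.T_final) < 1e-9


class TestSchemes:
    def test_explicit_refuses_unstable_step(self, small_grid):
        spec = SolverSpec(scheme="explicit", dt=1.0, t_end=2.0)
        solver = BioheatSolver(small_grid, spec)
        state = TemperatureField(np.full((small_grid.nz, small_grid.nr), 37.0), 0.0)
        with pytest.raises(SolverError, match="stability"):
            solver.step(state, 1.0)

    def test_explicit_and_implicit_agree_on_relaxation(self, small_grid):
        T0 = np.full((small_grid.nz, small_grid.nr), 37.0)
        T0[5:15, :5] = 45.0
        imp = BioheatSolver(small_grid, SolverSpec(dt=1e-3, t_end=0.05, bc_top="dirichlet"))
        bound = imp.explicit_stable_dt()
        dt = min(1e-3, 0.5 * bound)
        exp = BioheatSolver(small_grid, SolverSpec(scheme="explicit", dt=dt, t_end=0.05,
                                                   bc_top="dirichlet"))
        out_i = imp.run(T_init=T0)
        out_e = exp.run(T_init=T0)
        np.testing.assert_allclose(out_i.T_final, out_e.T_final, atol=0.05)


class TestTransientRuns:
    def test_probe_sits_on_axis_surface_and_peaks_during_pulse(self, coarse_grid, fast_solver):
        _, grid = build_domain("hps", coarse_grid)
        res = solve_transient(grid, DoseParams(7.5, 4.0, 7.0), fast_solver)
        assert res.probe_index < 5  # hottest axis cell is at/near the surface
        assert 0 < res.t_peak < 0.02
        assert res.peak_T > 40.0
        assert res.probe_at(1.0) < res.peak_T

    def test_temperature_rise_is_linear_in_energy_density(self, coarse_grid, fast_solver):
        # the laser-induced rise is linear in q; the baseline to subtract
        # is the zero-dose field (the ambient boundary cools the surface
        # slightly regardless of dose)
        _, grid = build_domain("hps", coarse_grid)
        base = solve_transient(grid, DoseParams(1e-9, 4.0, 7.0), fast_solver)
        lo = solve_transient(grid, DoseParams(4.0, 4.0, 7.0), fast_solver)
        hi = solve_transient(grid, DoseParams(8.0, 4.0, 7.0), fast_solver)
        np.testing.assert_allclose(
            hi.T_final - base.T_final, 2.0 * (lo.T_final - base.T_final),
            rtol=1e-6, atol=1e-9,
        )

    def test_snapshots_recorded_at_requested_times(self, coarse_grid):
        _, grid = build_domain("hps", coarse_grid)
        spec = SolverSpec(pulse_steps=60, snapshot_times=(0.01, 0.5))
        res = solve_transient(grid, DoseParams(7.5, 4.0, 7.0), spec)
        assert set(res.snapshots) == {0.01, 0.5}

    def test_convergence_report_has_shrinking_deltas(self):
        resolutions = [GridSpec(dr_mm=1.0, nz=20, dz0_mm=0.02),
                       GridSpec(dr_mm=0.5, nz=40, dz0_mm=0.01),
                       GridSpec(dr_mm=0.25, nz=80, dz0_mm=0.005)]
        spec = SolverSpec(t_end=0.05, pulse_steps=80)
        df = grid_convergence_report("hps", DoseParams(7.5, 4.0, 7.0), resolutions, spec)
        deltas = df["delta_peak"].dropna().values
        assert len(df) == 3
        assert deltas[-1] < deltas[0]
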