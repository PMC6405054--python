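"""Spectral solver: transforms, initial conditions, stepping, steadiness."""

import numpy as np
import pytest

from gtpatterns import models, solver


class _DiffusionOnly:
    """Stub model: pure diffusion with coefficient D (heat equation)."""

    variables = ("u",)
    n_gtpases, n_gaps = 1, 0
    gap_targets = {}
    mass_conserved_gtpase = True
    params: dict = {}

    def __init__(self, D=1.0):
        self.D = D

    def diffusion_coeffs(self):
        return {"u": self.D}

    def reaction_terms(self, point):
        return {"u": np.zeros_like(point["u"])}


class TestGrid:
    def test_rejects_odd_or_tiny_grids(self):
        with pytest.raises(ValueError):
            solver.Grid(W=10, H=10, nx=33, ny=32)
        with pytest.raises(ValueError):
            solver.Grid(W=10, H=10, nx=8, ny=32)

    def test_warns_on_anisotropic_spacing(self):
        with pytest.warns(UserWarning, match="spacing"):
            solver.Grid(W=100.0, H=10.0, nx=32, ny=32)

    def test_cell_centred_y_for_noflux(self):
        g = solver.Grid(W=10, H=10, nx=32, ny=32, bc_y="noflux")
        assert g.y[0] == pytest.approx(g.dy / 2)


class TestStep:
    @pytest.mark.parametrize("bc_y", ["periodic", "noflux"])
    def test_single_mode_decays_at_exact_implicit_rate(self, bc_y):
        D = 2.0
        g = solver.Grid(W=2 * np.pi, H=4.0, nx=32, ny=32, bc_y=bc_y)
        Y = g.y[:, None]
        ky = (2 * np.pi / g.H) if bc_y == "periodic" else (np.pi / g.H)
        f0 = np.cos(ky * Y) * np.ones((1, g.nx))
        st = solver.FieldState(0.0, {"u": f0.copy()})
        dt = 0.01
        out = solver.step(_DiffusionOnly(D), g, st, dt)
        factor = 1.0 / (1.0 + dt * D * ky**2)  # implicit Euler eigenmode decay
        assert np.abs(out.fields["u"] - f0 * factor).max() < 1e-13

    def test_equilibrium_is_a_fixed_point(self, small_noflux_grid):
        m = models.make_model("WP")
        st = solver.initial_condition(m, small_noflux_grid, noise_sd=0.0)
        out = solver.step(m, small_noflux_grid, st, 0.01)
        drift = max(
            np.abs(out.fields[v] - st.fields[v]).max() for v in m.variables
        )
        assert drift < 1e-12

    def test_full_step_matches_finite_difference_oracle(self, rng):
        # oracle: explicit 5-point finite differences at 100x smaller dt
        m = models.make_model("WP")
        g = solver.Grid(W=20.0, H=20.0, nx=32, ny=32, bc_y="periodic")
        hss = models.homogeneous_steady_state(m).values

        def smooth_field():
            f = rng.normal(0, 1, g.shape)
            fh = np.fft.rfft2(f)
            kx = np.arange(fh.shape[1])[None, :]
            ky = np.fft.fftfreq(g.ny)[:, None] * g.ny
            fh *= np.exp(-(kx**2 + ky**2) / 18.0)
            return 0.1 * np.fft.irfft2(fh, s=g.shape)

        st = solver.FieldState(0.0, {
            "u": hss["u"] + smooth_field(), "v": hss["v"] + smooth_field(),
        })
        dt = 1e-3
        out = solver.step(m, g, st, dt, scheme="imex2")

        def lap(f):
            return (
                (np.roll(f, 1, 1) - 2 * f + np.roll(f, -1, 1)) / g.dx**2
                + (np.roll(f, 1, 0) - 2 * f + np.roll(f, -1, 0)) / g.dy**2
            )

        u, v = st.fields["u"].copy(), st.fields["v"].copy()
        for _ in range(100):
            r = models.reaction_rates(m, {"u": u, "v": v}, validate=False)
            u = u + dt / 100 * (r["u"] + lap(u))
            v = v + dt / 100 * (r["v"] + 100.0 * lap(v))
        rel = np.abs(out.fields["u"] - u).max() / np.abs(u).max()
        assert rel < 1e-4

    def test_finite_horizon_match_to_oracle_within_tolerance(self, rng):
        m = models.make_model("WP")
        g = solver.Grid(W=20.0, H=20.0, nx=32, ny=32, bc_y="periodic")
        traj = solver.simulate(m, g, t_end=5.0, dt=0.005, seed=11, scheme="imex2")
        st = solver.initial_condition(m, g, noise_sd=1e-6, seed=11)

        def lap(f):
            return (
                (np.roll(f, 1, 1) - 2 * f + np.roll(f, -1, 1)) / g.dx**2
                + (np.roll(f, 1, 0) - 2 * f + np.roll(f, -1, 0)) / g.dy**2
            )

        u, v = st.fields["u"].copy(), st.fields["v"].copy()
        dt = 0.0005  # explicit stability needs dt < dx^2/(4*Dv)
        for _ in range(10000):
            r = models.reaction_rates(m, {"u": u, "v": v}, validate=False)
            u = u + dt * (r["u"] + lap(u))
            v = v + dt * (r["v"] + 100.0 * lap(v))
        num = np.linalg.norm(traj.final_state.fields["u"] - u)
        den = np.linalg.norm(u)
        assert num / den < 1e-3

    def test_nonfinite_fields_abort(self, small_periodic_grid):
        m = models.make_model("WP")
        bad = solver.FieldState(0.0, {
            "u": np.full(small_periodic_grid.shape, np.nan),
            "v": np.ones(small_periodic_grid.shape),
        })
        with pytest.raises(FloatingPointError):
            solver.step(m, small_periodic_grid, bad, 0.01)


class TestInitialCondition:
    def test_zero_noise_reproduces_homogeneous_state(self, small_noflux_grid):
        m = models.make_model("WPGAP")
        hss = models.homogeneous_steady_state(m).values
        st = solver.initial_condition(m, small_noflux_grid, noise_sd=0.0)
        for v in m.variables:
            assert np.all(st.fields[v] == hss[v])

    def test_per_pixel_totals_exact(self):
        m = models.make_model("WPGAP")
        g = solver.Grid(W=20, H=20, nx=128, ny=128)
        st = solver.initial_condition(m, g, noise_sd=1e-6, seed=7)
        T, Tg = m.params["T"], m.params["Tg"]
        assert np.abs(st.fields["u"] + st.fields["v"] - T).max() < 1e-12 * T
        assert np.abs(st.fields["G"] + st.fields["g"] - Tg).max() < 1e-12 * Tg

    def test_mean_noise_within_standard_error(self):
        m = models.make_model("WP")
        g = solver.Grid(W=20, H=20, nx=128, ny=128)
        hss = models.homogeneous_steady_state(m).values
        st = solver.initial_condition(m, g, noise_sd=1e-6, seed=1)
        assert abs(st.fields["u"].mean() - hss["u"]) <= 1e-7


class TestSimulate:
    def test_zero_noise_trajectory_is_constant(self, small_noflux_grid):
        m = models.make_model("WP")
        sch = solver.Schedule(noise_sd=0.0)
        traj = solver.simulate(m, small_noflux_grid, t_end=1.0, dt=0.01,
                               schedule=sch, snapshot_stride=0.2)
        first, last = traj.states[0], traj.states[-1]
        for v in m.variables:
            assert np.abs(last.fields[v] - first.fields[v]).max() < 1e-10

    @pytest.mark.parametrize("mid", ["WP", "WPGAP"])
    def test_mass_conserved_to_tolerance_over_patterning_run(self, mid):
        m = models.make_model(mid)
        g = solver.Grid(W=20.0, H=20.0, nx=48, ny=48, bc_y="noflux")
        traj = solver.simulate(m, g, t_end=50.0, dt=0.02, seed=5)
        t0 = models.conserved_totals(m, traj.states[0])
        t1 = models.conserved_totals(m, traj.final_state)
        for key in t0:
            assert abs(t1[key] - t0[key]) < 1e-6 * abs(t0[key])

    def test_no_flux_contract_at_y_boundaries(self):
        m = models.make_model("WP", {"T": 1.6})
        g = solver.Grid(W=30.0, H=30.0, nx=64, ny=64, bc_y="noflux")
        traj = solver.simulate(m, g, t_end=400.0, dt=0.05, seed=5)
        u = traj.final_state.fields["u"]
        rng_u = u.max() - u.min()
        assert rng_u > 0.1  # a pattern actually formed
        # one-sided derivative at the walls, normalised by field range
        d_lo = np.abs(u[1] - u[0]).max() / g.dy / rng_u
        d_hi = np.abs(u[-1] - u[-2]).max() / g.dy / rng_u
        # cosine basis: boundary-normal derivative vanishes to grid accuracy
        assert d_lo < 0.05 and d_hi < 0.05

    def test_invalid_schedule_override_rejected_before_start(self, small_noflux_grid):
        m = models.make_model("WP")
        sch = solver.Schedule(changes=[(1.0, {"sigma": 0.5})])
        with pytest.raises(ValueError, match="sigma"):
            solver.simulate(m, small_noflux_grid, t_end=2.0, dt=0.01, schedule=sch)

    def test_schedule_total_change_adjusts_inactive_pool(self, small_noflux_grid):
        m = models.make_model("WP")
        sch = solver.Schedule(changes=[(0.5, {"T": 2.0})], noise_sd=0.0)
        traj = solver.simulate(m, small_noflux_grid, t_end=1.0, dt=0.01,
                               schedule=sch, snapshot_stride=0.1)
        tot = models.conserved_totals(
            models.make_model("WP", {"T": 2.0}), traj.final_state
        )
        assert tot["T"] == pytest.approx(2.0, abs=1e-9)

    def test_snapshot_times_strictly_increasing(self, small_noflux_grid):
        m = models.make_model("WP")
        traj = solver.simulate(m, small_noflux_grid, t_end=1.0, dt=0.01,
                               snapshot_stride=0.25)
        assert np.all(np.diff(traj.times) > 0)

    def test_save_load_round_trip(self, tmp_path, small_noflux_grid):
        m = models.make_model("WP")
        traj = solver.simulate(m, small_noflux_grid, t_end=0.5, dt=0.01,
                               snapshot_stride=0.1, seed=3)
        path = tmp_path / "run.h5"
        traj.save(path)
        back = solver.Trajectory.load(path)
        assert back.times == traj.times
        assert np.allclose(back.final_state.fields["u"], traj.final_state.fields["u"])
        assert back.params == traj.params


class TestSteadyStateDetection:
    def _make_traj(self, grid, fields_list, stride=10.0):
        states = [solver.FieldState(i * stride, {"u": f}) for i, f in enumerate(fields_list)]
        return solver.Trajectory(
            times=[s.t for s in states], states=states, model_id="WP",
            params={}, grid=grid,
        )

    def test_constant_trajectory_is_steady_with_zero_drift(self, small_periodic_grid):
        f = np.random.default_rng(0).uniform(0, 1, small_periodic_grid.shape)
        traj = self._make_traj(small_periodic_grid, [f] * 5)
        res = solver.detect_steady_state(traj, window=100.0, tol=1e-6)
        assert res["steady"] and res["drift_velocity"] == 0.0

    def test_uniform_cyclic_drift_counts_as_steady(self, small_periodic_grid):
        g = small_periodic_grid
        X = g.x[None, :]
        Y = g.y[:, None]
        base = np.exp(-((X - 10) ** 2 + (Y - 10) ** 2) / 4.0)
        frames = [np.roll(base, shift, axis=1) for shift in range(5)]
        traj = self._make_traj(g, frames, stride=2.0)
        res = solver.detect_steady_state(traj, window=100.0, tol=1e-6)
        assert res["steady"]
        assert res["drift_velocity"] == pytest.approx(g.dx / 2.0)

    def test_growing_transient_is_not_steady(self, small_periodic_grid):
        f = np.random.default_rng(1).uniform(0, 1, small_periodic_grid.shape)
        frames = [(1 + 0.5 * i) * f for i in range(5)]
        traj = self._make_traj(small_periodic_grid, frames)
        assert not solver.detect_steady_state(traj, window=100.0, tol=1e-6)["steady"]

    def test_too_few_snapshots_rejected(self, small_periodic_grid):
        f = np.zeros(small_periodic_grid.shape)
        traj = self._make_traj(small_periodic_grid, [f, f])
        with pytest.raises(ValueError):
            solver.detect_steady_state(traj, window=100.0, tol=1e-6)


class TestResolutionRobustness:
    def test_cluster_count_unchanged_on_finer_grid(self):
        # same physical domain and noise realisation, double the resolution
        from gtpatterns import metrics

        m = models.make_model("WPT")
        coarse = solver.Grid(W=40.0, H=40.0, nx=48, ny=48, bc_y="noflux")
        fine = solver.Grid(W=40.0, H=40.0, nx=96, ny=96, bc_y="noflux")
        ic_c = solver.initial_condition(m, coarse, noise_sd=1e-6, seed=9)
        # interpolate the coarse noise onto the fine grid (nearest pixel)
        ic_f = solver.FieldState(0.0, {
            v: np.repeat(np.repeat(ic_c.fields[v], 2, axis=0), 2, axis=1)
            for v in m.variables
        })
        n = {}
        for grid, ic in (("coarse", (coarse, ic_c)), ("fine", (fine, ic_f))):
            g, state = ic
            traj = solver.simulate(m, g, t_end=1500.0, dt=0.05,
                                   initial_state=state, seed=9)
            n[grid] = metrics.count_clusters(traj.final_state.fields["u"], g)
        assert n["coarse"] == n["fine"]
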