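"""Cluster-competition ODE models: derivatives, ratio dynamics, survivors."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gtpatterns import cluster_ode as co


@pytest.fixture
def five_cluster():
    return co.five_cluster_preset()


class TestRightHandSides:
    def test_empty_clusters_are_inert(self, five_cluster):
        params, _ = five_cluster
        st = co.ClusterState(h_c=np.zeros(5), h_p=0.0)
        dh, dp = co.basic_rhs(st, params)
        assert np.all(dh == 0) and dp == 0

    def test_basic_rhs_direct_evaluation(self, five_cluster):
        # dh1/dt = alpha*h1*hp - beta*h1^eta - delta*h1 = 6 - 1 - 5 = 0
        params, state = five_cluster
        dh, dp = co.basic_rhs(state, params)
        assert dh[0] == pytest.approx(0.0, abs=1e-12)
        assert dh[0] + 0 == 1 * 1 * 6 - 1 * 1**0.5 - 5 * 1

    @pytest.mark.parametrize("variant", ["basic", "gap"])
    def test_conservation_by_construction(self, variant, rng):
        params = co.ClusterParams()
        for _ in range(20):
            h = rng.uniform(0.01, 5, 5)
            if variant == "basic":
                st = co.ClusterState(h_c=h, h_p=float(rng.uniform(0, 10)))
                dh, dp = co.basic_rhs(st, params)
                assert dh.sum() + dp == pytest.approx(0.0, abs=1e-12)
            else:
                st = co.ClusterState(
                    h_c=h, h_p=float(rng.uniform(0, 10)),
                    G_c=rng.uniform(0, 2, 5), G_p=float(rng.uniform(0, 10)),
                )
                dh, dp, dG, dGp = co.gap_rhs(st, params)
                assert dh.sum() + dp == pytest.approx(0.0, abs=1e-12)
                assert dG.sum() + dGp == pytest.approx(0.0, abs=1e-12)

    def test_compartment_totals_conserved_without_turnover_and_exchange(self, rng):
        params = co.ClusterParams(phi=0.0)
        h = rng.uniform(0.1, 5, 4)
        p = rng.uniform(0.1, 5, 4)
        st = co.ClusterState(h_c=h, h_p=p)
        dh, dp = co.compartment_rhs(st, params)
        assert np.allclose(dh + dp, 0.0, atol=1e-12)

    def test_equal_pools_have_no_exchange_flux(self):
        params = co.ClusterParams(phi=0.7)
        st = co.ClusterState(h_c=np.array([1.0, 2.0]), h_p=np.array([3.0, 3.0]))
        _, dp = co.compartment_rhs(st, params)
        params0 = co.ClusterParams(phi=0.0)
        _, dp0 = co.compartment_rhs(st, params0)
        assert np.allclose(dp, dp0)

    def test_gap_rhs_reduces_to_basic_without_gap(self, five_cluster):
        params, state = five_cluster
        st = co.ClusterState(h_c=state.h_c, h_p=6.0, G_c=np.zeros(5), G_p=0.0)
        dh_g, dp_g, dG, dGp = co.gap_rhs(st, params)
        dh_b, dp_b = co.basic_rhs(state, params)
        assert np.allclose(dh_g, dh_b) and dp_g == pytest.approx(dp_b)
        assert np.all(dG == 0) and dGp == 0

    def test_single_compartment_equilibrium_matches_relaxation_oracle(self):
        # root of the one-compartment turnover system vs long integration
        from scipy.optimize import root

        params = co.ClusterParams(sigma=1.0, xi=0.1, phi=0.0)

        def f(x):
            st = co.ClusterState(h_c=np.array([x[0]]), h_p=np.array([x[1]]))
            dh, dp = co.compartment_rhs(st, params)
            return [dh[0], dp[0]]

        sol = root(f, [5.0, 5.0], tol=1e-12)
        assert sol.success
        st0 = co.ClusterState(h_c=np.array([2.0]), h_p=np.array([6.0]))
        traj = co.simulate_clusters("compartment", st0, params, t_end=2000.0)
        assert np.allclose(traj.final_state.h_c[0], sol.x[0], atol=1e-6)
        assert np.allclose(float(traj.final_state.h_p[0]), sol.x[1], atol=1e-6)

    def test_negative_state_rejected(self, five_cluster):
        params, _ = five_cluster
        with pytest.raises(ValueError):
            co.ClusterState(h_c=np.array([-1.0, 2.0]), h_p=1.0)


class TestRatioDynamics:
    def test_equal_clusters_have_zero_ratio_rate(self, five_cluster):
        params, _ = five_cluster
        assert co.ratio_rate(1.5, 1.5, params) == 0.0

    def test_direct_evaluation(self):
        params = co.ClusterParams(beta=1.0, eta=0.5)
        # beta*h_k^(eta-1)*(r - r^eta) = 1*1*(2 - sqrt(2))
        assert co.ratio_rate(2.0, 1.0, params) == pytest.approx(2 - np.sqrt(2))

    @given(
        eta=st.floats(0.01, 0.99),
        beta=st.floats(0.01, 10.0),
        h_big=st.floats(1e-3, 10.0),
        frac=st.floats(1e-3, 0.999),
    )
    @settings(max_examples=300, derandomize=True, deadline=None)
    def test_sign_property(self, eta, beta, h_big, frac):
        # larger/smaller ratio always grows; smaller/larger always shrinks
        h_small = h_big * frac
        p = co.ClusterParams(beta=beta, eta=eta)
        assert co.ratio_rate(h_big, h_small, p) > 0
        assert co.ratio_rate(h_small, h_big, p) < 0

    def test_zero_reference_cluster_rejected(self, five_cluster):
        params, _ = five_cluster
        with pytest.raises(ValueError):
            co.ratio_rate(1.0, 0.0, params)

    def test_ratio_rate_matches_trajectory_differencing(self, five_cluster):
        params, state = five_cluster
        traj = co.simulate_clusters("basic", state, params, t_end=2.0, n_out=2001)
        h = traj.h_c_series()
        t = traj.times
        i, k = 4, 2
        ratios = h[:, i] / h[:, k]
        mid = len(t) // 2
        slope = (ratios[mid + 1] - ratios[mid - 1]) / (t[mid + 1] - t[mid - 1])
        st = traj.states[mid]
        predicted = co.ratio_rate(
            float(st.h_c[i]), float(st.h_c[k]), params,
        )
        assert slope == pytest.approx(predicted, rel=1e-4)

    def test_gap_ratio_rate_matches_trajectory_differencing(self, five_cluster):
        params, state = five_cluster
        st0 = co.ClusterState(h_c=state.h_c, h_p=6.0, G_c=np.zeros(5), G_p=10.0)
        traj = co.simulate_clusters("gap", st0, params, t_end=2.0, n_out=2001)
        t = traj.times
        i, k = 4, 2
        h = traj.h_c_series()
        ratios = h[:, i] / h[:, k]
        mid = len(t) // 2
        slope = (ratios[mid + 1] - ratios[mid - 1]) / (t[mid + 1] - t[mid - 1])
        st = traj.states[mid]
        predicted = co.ratio_rate(
            float(st.h_c[i]), float(st.h_c[k]), params,
            G_i=float(st.G_c[i]), G_k=float(st.G_c[k]),
        )
        assert slope == pytest.approx(predicted, rel=1e-3)


class TestGapQSS:
    def test_reduces_to_plain_ratio_rate_without_gap(self, five_cluster):
        params, _ = five_cluster
        h = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        full = co.ratio_rate(h[3], h[1], params)
        assert co.gap_qss_ratio_rate(h, 3, 1, params, Tg=0.0) == pytest.approx(full)

    def test_equal_clusters_give_zero(self, five_cluster):
        params, _ = five_cluster
        h = np.full(4, 2.0)
        assert co.gap_qss_ratio_rate(h, 0, 3, params, Tg=7.0) == 0.0

    def test_qss_term_always_opposes_size_differences(self, rng, five_cluster):
        params, _ = five_cluster
        for _ in range(200):
            h = np.sort(rng.uniform(0.05, 8.0, 5))
            with_gap = co.gap_qss_ratio_rate(h, 4, 0, params, Tg=5.0)
            without = co.gap_qss_ratio_rate(h, 4, 0, params, Tg=0.0)
            assert with_gap < without

    def test_fast_gap_kinetics_converge_to_qss(self):
        # speeding up GAP turnover 100x makes the full ratio rate approach
        # the quasi-steady-state expression along a trajectory
        import dataclasses

        base = co.ClusterParams()
        fast = dataclasses.replace(
            base, gamma_g=base.gamma_g * 100, delta_g=base.delta_g * 100,
            zeta=base.zeta * 100,
        )
        Tg = 5.0
        st0 = co.ClusterState(
            h_c=np.array([1.0, 2.0, 3.0, 4.0, 5.0]), h_p=6.0,
            G_c=np.zeros(5), G_p=Tg,
        )
        traj = co.simulate_clusters("gap", st0, fast, t_end=1.0, n_out=101)
        st = traj.states[50]  # past the fast GAP transient
        i, k = 4, 1
        full = co.ratio_rate(
            float(st.h_c[i]), float(st.h_c[k]), fast,
            G_i=float(st.G_c[i]), G_k=float(st.G_c[k]),
        )
        qss = co.gap_qss_ratio_rate(st.h_c, i, k, fast, Tg=Tg)
        assert full == pytest.approx(qss, rel=0.01)


class TestCompetitionOutcomes:
    def test_basic_model_single_winner_is_initially_largest(self, five_cluster):
        params, state = five_cluster
        traj = co.simulate_clusters("basic", state, params, t_end=2000.0)
        assert co.surviving_clusters(traj) == 1
        assert int(np.argmax(traj.final_state.h_c)) == 4
        assert traj.final_state.total_gtpase == pytest.approx(21.0, rel=1e-9)

    def test_isolated_compartments_all_persist(self, five_cluster):
        params, _ = five_cluster
        st = co.ClusterState(h_c=np.array([1.0, 2, 3, 4, 5]), h_p=np.full(5, 6.0))
        traj = co.simulate_clusters("compartment", st, params, t_end=2000.0)
        assert co.surviving_clusters(traj) == 5

    def test_exchange_restores_winner_takes_all(self, five_cluster):
        import dataclasses

        params, _ = five_cluster
        p = dataclasses.replace(params, phi=0.1)
        st = co.ClusterState(h_c=np.array([1.0, 2, 3, 4, 5]), h_p=np.full(5, 6.0))
        traj = co.simulate_clusters("compartment", st, p, t_end=5000.0)
        assert co.surviving_clusters(traj) == 1

    def test_turnover_stabilises_coexistence(self, five_cluster):
        import dataclasses

        params, _ = five_cluster
        p = dataclasses.replace(params, phi=0.1, sigma=1.0, xi=0.1)
        st = co.ClusterState(h_c=np.array([1.0, 2, 3, 4, 5]), h_p=np.full(5, 6.0))
        traj = co.simulate_clusters("compartment", st, p, t_end=5000.0)
        assert co.surviving_clusters(traj) == 5

    def test_survivors_non_decreasing_in_total_gap(self, five_cluster):
        params, state = five_cluster
        counts = []
        for Tg in (0.0, 2.0, 5.0, 10.0):
            st = co.ClusterState(h_c=state.h_c, h_p=6.0, G_c=np.zeros(5), G_p=Tg)
            traj = co.simulate_clusters("gap", st, params, t_end=5000.0)
            counts.append(co.surviving_clusters(traj))
        assert counts == sorted(counts)
        assert counts[-1] > 1  # large GAP pool sustains several clusters

    def test_gap_trajectory_conserves_both_totals(self, five_cluster):
        params, state = five_cluster
        st = co.ClusterState(h_c=state.h_c, h_p=6.0, G_c=np.zeros(5), G_p=10.0)
        traj = co.simulate_clusters("gap", st, params, t_end=5000.0)
        for s in traj.states[:: len(traj.states) // 10]:
            assert s.total_gtpase == pytest.approx(21.0, rel=1e-9)
            assert s.total_gap == pytest.approx(10.0, rel=1e-9)

    def test_pool_only_degradation_grows_without_bound(self, five_cluster):
        import dataclasses

        params, _ = five_cluster
        p = dataclasses.replace(params, phi=0.1, sigma=1.0, xi=0.0, xi_p=0.1)
        st = co.ClusterState(h_c=np.array([1.0, 2, 3, 4, 5]), h_p=np.full(5, 6.0))
        traj = co.simulate_clusters(
            "compartment", st, p, t_end=3000.0, rtol=1e-8, atol=1e-8
        )
        h = traj.h_c_series()
        assert traj.final_state.h_c.max() > 1e3
        # still growing at the end: no bounded steady state
        assert h[-1].max() > h[-2].max()

    def test_all_zero_state_has_no_survivors(self, five_cluster):
        params, _ = five_cluster
        st = co.ClusterState(h_c=np.zeros(3), h_p=5.0)
        traj = co.simulate_clusters("basic", st, params, t_end=10.0)
        assert co.surviving_clusters(traj) == 0
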