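"""ODE right-hand side and integration contract.

Hand-derived derivative values, conservation of taxon totals under
conjugation, a closed-form logistic oracle, and a fixed-step RK4 reference
integrator on small systems.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hgtstab import Community, ModelParams, State, integrate, rhs
from hgtstab.dynamics import _rhs_vec


def single_taxon(r=0.1, s=0.1, c=0.0, gamma=0.0):
    return Community(
        A=np.zeros((1, 1)),
        s_vec=np.array([s]),
        r_vec=np.array([r]),
        Gamma=np.array([[gamma]]),
        c=c,
        focal=0,
    )


def random_community(rng, N=4):
    A = rng.normal(0, 0.01, (N, N))
    np.fill_diagonal(A, 0.0)
    s = np.full(N, 0.1)
    return Community(
        A=A, s_vec=s, r_vec=s - A.sum(axis=1),
        Gamma=np.abs(rng.normal(5e-4, 5e-5, (N, N))), c=0.0, focal=0,
    )


class TestRhs:
    def test_calibrated_equilibrium_has_zero_derivative(self, noninteracting_community, noninteracting_params):
        state = State(X_s=np.ones(10), X_r=np.zeros(10))
        d = rhs(state, 0.0, noninteracting_community, noninteracting_params)
        assert np.allclose(d.X_s, 0.0) and np.allclose(d.X_r, 0.0)

    def test_stressor_kill_term_hand_value(self):
        # X_s=1 at carrying capacity: dX_s/dt = 1*(0.1-0.1) - 1*0.1*1 = -0.1
        comm = single_taxon()
        params = ModelParams(N=1, beta_s=1.0)
        d = rhs(State(np.array([1.0]), np.array([0.0])), 0.1, comm, params)
        assert d.X_s[0] == pytest.approx(-0.1)

    def test_transfer_term_moves_cells_between_compartments(self):
        comm = single_taxon(gamma=1e-3)
        params = ModelParams(N=1)
        state = State(np.array([0.5]), np.array([0.5]))
        d = rhs(state, 0.0, comm, params)
        transfer = 1e-3 * 0.5 * 0.5  # gamma * X_s * X_r = 2.5e-4
        # growth is identical in both compartments (c=0); the difference in
        # derivatives is exactly twice the transfer flux
        assert (d.X_r[0] - d.X_s[0]) == pytest.approx(2 * transfer)
        # totals follow pure growth: (Xs+Xr)(r - s*(Xs+Xr)) = 1*(0.1-0.1) = 0
        assert (d.X_s[0] + d.X_r[0]) == pytest.approx(0.0, abs=1e-15)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_conjugation_conserves_taxon_totals(self, seed):
        # with c = 0, delta = 0, D = 0 the taxon totals' derivative is
        # independent of the conjugation matrix
        rng = np.random.default_rng(seed)
        comm = random_community(rng)
        params = ModelParams(N=4)
        y = rng.uniform(0, 2, size=8)
        d_with = _rhs_vec(0.0, y, 0.0, comm, params)
        from dataclasses import replace
        d_without = _rhs_vec(0.0, y, 0.0, replace(comm, Gamma=np.zeros((4, 4))), params)
        total_with = d_with[:4] + d_with[4:]
        total_without = d_without[:4] + d_without[4:]
        assert np.allclose(total_with, total_without, atol=1e-14)

    def test_dose_weakly_decreases_all_totals(self):
        rng = np.random.default_rng(5)
        comm = random_community(rng)
        params = ModelParams(N=4)
        y = rng.uniform(0.1, 1.5, size=8)
        lo = _rhs_vec(0.0, y, 0.05, comm, params)
        hi = _rhs_vec(0.0, y, 0.2, comm, params)
        assert np.all((hi[:4] + hi[4:]) <= (lo[:4] + lo[4:]) + 1e-15)

    def test_dimension_mismatch_raises(self, noninteracting_community, noninteracting_params):
        with pytest.raises(ValueError):
            _rhs_vec(0.0, np.ones(6), 0.0, noninteracting_community, noninteracting_params)

    def test_segregation_modes(self):
        params_ret = ModelParams(N=1, delta=0.01, segregation_mode="return")
        params_loss = ModelParams(N=1, delta=0.01, segregation_mode="loss")
        comm = single_taxon()
        state = State(np.array([0.3]), np.array([0.4]))
        d_ret = rhs(state, 0.0, comm, params_ret)
        d_loss = rhs(state, 0.0, comm, params_loss)
        # both remove delta*X_r from the resistant compartment
        assert d_ret.X_r[0] == pytest.approx(d_loss.X_r[0])
        # only the return mode credits it to the susceptible compartment
        assert d_ret.X_s[0] - d_loss.X_s[0] == pytest.approx(0.01 * 0.4)


class TestIntegrate:
    def test_equilibrium_is_held(self, noninteracting_community, noninteracting_params):
        state = State(np.ones(10), np.zeros(10))
        traj = integrate(noninteracting_community, state, (0.0, 500.0), 0.0, noninteracting_params)
        assert np.allclose(traj.total[-1], 1.0, atol=1e-6)

    def test_logistic_closed_form(self):
        # r = s = 0.1, X0 = 0.01: X(t) = K / (1 + (K/X0 - 1) exp(-r t)), K=1
        comm = single_taxon()
        params = ModelParams(N=1)
        times = np.linspace(0.0, 200.0, 21)
        traj = integrate(
            comm, State(np.array([0.01]), np.array([0.0])), (0.0, 200.0),
            0.0, params, report_times=times,
        )
        expected = 1.0 / (1.0 + (1.0 / 0.01 - 1.0) * np.exp(-0.1 * times))
        assert np.allclose(traj.X_s[:, 0], expected, rtol=1e-6, atol=1e-9)

    def test_resistant_free_subspace_is_invariant(self, noninteracting_params):
        # background taxa started plasmid-free stay plasmid-free when the
        # focal compartment is also empty and delta = 0
        from hgtstab import generate_ensemble

        comm = generate_ensemble(noninteracting_params, 1, 2)[0]
        traj = integrate(
            comm, State(np.full(10, 0.1), np.zeros(10)), (0.0, 500.0),
            0.0, noninteracting_params,
        )
        assert np.all(traj.X_r == 0)

    def test_reported_abundances_nonnegative(self, community, params):
        state = State(np.full(10, 0.1), np.zeros(10))
        traj = integrate(community, state, (0.0, 500.0), params.D_perturb, params,
                         report_times=np.linspace(0, 500, 101))
        assert np.all(traj.X_s >= 0) and np.all(traj.X_r >= 0)

    def test_resistant_fraction_rises_under_stressor(self):
        # beta_r * D < beta_s * D - c: resistance is net-beneficial
        comm = single_taxon(c=0.005)
        params = ModelParams(N=1)
        state = State(np.array([0.5]), np.array([0.5]))
        traj = integrate(comm, state, (0.0, 25.0), 0.1, params)
        frac0 = 0.5
        frac1 = traj.X_r[-1, 0] / traj.total[-1, 0]
        assert frac1 > frac0

    def test_agrees_with_fixed_step_rk4(self):
        # independent reference: classical RK4 at step 1e-3 on a 2-taxon system
        rng = np.random.default_rng(8)
        A = np.array([[0.0, -0.02], [0.01, 0.0]])
        s = np.full(2, 0.1)
        comm = Community(
            A=A, s_vec=s, r_vec=s - A.sum(axis=1),
            Gamma=np.full((2, 2), 1e-3), c=0.005, focal=0,
        )
        params = ModelParams(N=2)
        y0 = np.array([0.1, 0.1, 0.05, 0.0])
        t_end, h = 50.0, 1e-3

        y = y0.copy()
        nsteps = int(round(t_end / h))
        for _ in range(nsteps):
            k1 = _rhs_vec(0, y, 0.05, comm, params)
            k2 = _rhs_vec(0, y + h / 2 * k1, 0.05, comm, params)
            k3 = _rhs_vec(0, y + h / 2 * k2, 0.05, comm, params)
            k4 = _rhs_vec(0, y + h * k3, 0.05, comm, params)
            y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)

        traj = integrate(
            comm, State(y0[:2], y0[2:]), (0.0, t_end), 0.05, params
        )
        adaptive = np.concatenate([traj.X_s[-1], traj.X_r[-1]])
        assert np.allclose(adaptive, y, rtol=1e-6, atol=1e-12)

    def test_halving_tolerances_changes_little(self, community, params):
        state = State(np.full(10, 0.1), np.zeros(10))
        a = integrate(community, state, (0.0, 500.0), 0.0, params)
        tight = params.replace(rtol=params.rtol / 2, atol=params.atol / 2)
        b = integrate(community, state, (0.0, 500.0), 0.0, tight)
        assert np.allclose(a.total[-1], b.total[-1], rtol=1e-3)

    def test_empty_span_rejected(self, community, params):
        with pytest.raises(ValueError):
            integrate(community, State(np.ones(10), np.zeros(10)), (5.0, 5.0), 0.0, params)

    def test_trajectory_concat_and_tidy_export(self, noninteracting_community, noninteracting_params):
        state = State(np.full(10, 0.1), np.zeros(10))
        t1 = integrate(noninteracting_community, state, (0.0, 10.0), 0.0,
                       noninteracting_params, report_times=np.linspace(0, 10, 11))
        t2 = integrate(noninteracting_community, t1.state_at(-1), (10.0, 20.0), 0.1,
                       noninteracting_params, report_times=np.linspace(10, 20, 11))
        joined = t1.concat(t2)
        assert joined.times.shape == (21,)
        assert np.all(np.diff(joined.times) > 0)
        assert joined.D_profile == [(0.0, 10.0, 0.0), (10.0, 20.0, 0.1)]
        df = joined.to_dataframe()
        assert set(df.columns) == {"time", "taxon", "compartment", "abundance"}
        assert len(df) == 21 * 10 * 2
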