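"""Steady-state solver tests, including the full three-population ODE oracle."""

import numpy as np
import pytest

from conftest import random_small_state
from neurobulb.dynamics import (
    context_drive,
    gc_activity,
    solve_steady_state,
    steady_states_batch,
)
from neurobulb.model_core import (
    ModelParams,
    NetworkState,
    Stimulus,
    cc_sigmoid,
    initial_state,
    rectify,
)


def ode_oracle(S, C_ext, state, p, alpha, w_gc, tau_G=1.0, dt=0.01,
               t_max=1e4, tol=1e-9):
    """Brute-force forward integration of all three populations (tau_G finite).

    Independent of the production solver: integrates G as a dynamical variable
    rather than eliminating it algebraically.
    """
    W_MG = state.W_MG.astype(float)
    M = np.full(p.N_MC, p.M_sp)
    G = np.zeros(state.N_G)
    C = np.zeros(p.N_CC)
    off = 1.0 - np.eye(p.N_CC)
    t = 0.0
    while t < t_max:
        sig = cc_sigmoid(C, p)
        dM = (-M + S + p.M_sp - state.g * W_MG @ rectify(G - p.G_th)) / p.tau_M
        dG = (-G + W_MG.T @ rectify(M) + w_gc * state.W_GC @ sig) / tau_G
        dC = (-C + p.w_CM * state.W_CM @ rectify(M)
              + (alpha * state.W_CC) @ sig - p.w_inh * (off @ sig)
              + C_ext) / p.tau_C
        if max(np.abs(dM).max(), np.abs(dG).max(initial=0.0),
               np.abs(dC).max()) < tol:
            break
        M += dt * dM
        G += dt * dG
        C += dt * dC
        t += dt
    return M, G, C


class TestGcActivity:
    def test_sum_of_inputs(self, tiny_params):
        st = initial_state(tiny_params)
        st.W_MG = np.array([[1], [1], [0], [0]], dtype=np.int8)
        st.W_GC = np.zeros((1, tiny_params.N_CC), dtype=np.int8)
        st.W_GC[0, 0] = 1
        st.G = np.zeros(1)
        M = np.array([1.0, 2.0, 5.0, -1.0])
        C = np.full(tiny_params.N_CC, -100.0)  # sigma ~ 0
        g = gc_activity(M, C, st, tiny_params, w_gc=0.0)
        assert g[0] == pytest.approx(3.0)

    def test_default_parameter_value(self, params):
        # 16 MCs at M_sp plus two CC partners at sigma(0):
        # 16*0.2 + 3*2*0.354344 = 5.326
        st = initial_state(params)
        st.W_MG = np.zeros((params.N_MC, 1), dtype=np.int8)
        st.W_MG[:16, 0] = 1
        st.W_GC = np.zeros((1, params.N_CC), dtype=np.int8)
        st.W_GC[0, :2] = 1
        st.G = np.zeros(1)
        M = np.full(params.N_MC, params.M_sp)
        C = np.zeros(params.N_CC)
        assert gc_activity(M, C, st, params)[0] == pytest.approx(5.326, abs=1e-3)

    def test_dimension_mismatch(self, tiny_params):
        st = initial_state(tiny_params)
        with pytest.raises(ValueError):
            gc_activity(np.zeros(3), np.zeros(tiny_params.N_CC), st, tiny_params)


class TestSolveSteadyState:
    def test_no_inhibition_gives_stimulus_plus_spontaneous(self, tiny_params):
        p = tiny_params.replace(w_CM=0.0)
        st = initial_state(p)
        S = np.array([1.0, 0.5, 0.0, 2.0])
        res = solve_steady_state(Stimulus(S), st, p)
        assert res.converged
        np.testing.assert_allclose(res.M, S + p.M_sp, atol=1e-5)

    def test_toy_fixed_point(self):
        # 1 MC, 1 GC, reciprocal synapse, g=1, G_th=0, M_sp=0, S=2:
        # M = 2 - [M]+  =>  M = 1, G = 1
        p = ModelParams(N_MC=1, N_CC_odor=1, N_CC_context=2, n_contexts=2,
                        N_conn_MG=1, N_conn_GC=1, N_GC_aim=1, N_new_G=0,
                        M_sp=0.0, G_th=0.0, g_init=1.0)
        st = initial_state(p)
        st.W_MG = np.ones((1, 1), dtype=np.int8)
        st.W_GC = np.zeros((1, 3), dtype=np.int8)
        st.W_GC[0, 1] = 1
        st.G = np.zeros(1)
        res = solve_steady_state(Stimulus(np.array([2.0])), st, p, w_gc=0.0)
        assert res.M[0] == pytest.approx(1.0, abs=1e-4)
        assert res.G[0] == pytest.approx(1.0, abs=1e-4)

    def test_fixed_point_conditions_hold(self, tiny_params):
        rng = np.random.default_rng(3)
        st = random_small_state(tiny_params, rng, n_g=3)
        stim = Stimulus(rng.uniform(0, 2, tiny_params.N_MC), context_id=0)
        res = solve_steady_state(stim, st, tiny_params)
        # re-evaluate the right-hand sides at the returned state
        sig = cc_sigmoid(res.C, tiny_params)
        rhs_M = (-res.M + stim.S + tiny_params.M_sp
                 - st.g * st.W_MG @ rectify(res.G - tiny_params.G_th))
        assert np.abs(rhs_M).max() <= 10 * tiny_params.steady_tol
        np.testing.assert_allclose(
            res.G, gc_activity(res.M, res.C, st, tiny_params), atol=1e-9)

    def test_batch_matches_individual_solves(self, tiny_params):
        rng = np.random.default_rng(7)
        st = random_small_state(tiny_params, rng, n_g=4)
        stims = [Stimulus(rng.uniform(0, 2, tiny_params.N_MC)),
                 Stimulus(np.zeros(tiny_params.N_MC), context_id=1)]
        M, G, C = steady_states_batch(stims, st, tiny_params)
        for j, s in enumerate(stims):
            r = solve_steady_state(s, st, tiny_params)
            np.testing.assert_allclose(M[:, j], r.M, atol=1e-6)
            np.testing.assert_allclose(C[:, j], r.C, atol=1e-6)


class TestOdeOracle:
    @pytest.mark.parametrize("seed", range(4))
    def test_matches_full_three_population_integration(self, seed):
        """Reduced (tau_G = 0) fixed points equal the tau_G = 1 ODE limit."""
        p = ModelParams(N_MC=3, N_CC_odor=3, N_CC_context=2, n_contexts=2,
                        N_conn_MG=2, N_conn_GC=1, N_GC_aim=3, N_new_G=0,
                        g_init=0.5)
        rng = np.random.default_rng(seed)
        st = random_small_state(p, rng, n_g=rng.integers(0, 4))
        stim = Stimulus(rng.uniform(0, 1.5, p.N_MC),
                        context_id=int(rng.integers(0, 2)))
        res = solve_steady_state(stim, st, p)
        M, G, C = ode_oracle(stim.S, context_drive(stim, p), st, p,
                             alpha=p.alpha_recall, w_gc=p.w_GC)
        np.testing.assert_allclose(res.M, M, atol=1e-4)
        np.testing.assert_allclose(res.C, C, atol=1e-4)
        if st.N_G:
            np.testing.assert_allclose(res.G, G, atol=1e-4)

    def test_increasing_g_lowers_mc_rates_single_gc(self):
        """With one shared GC, stronger reciprocal inhibition can only lower
        MC activity.  (With several GCs sharing MCs this is false in general:
        suppressing one MC can silence a GC and so disinhibit another MC.)"""
        p = ModelParams(N_MC=4, N_CC_odor=4, N_CC_context=2, n_contexts=2,
                        N_conn_MG=2, N_conn_GC=1, N_GC_aim=4, N_new_G=0,
                        w_CM=0.0, G_th=1.0)
        rng = np.random.default_rng(11)
        st = random_small_state(p, rng, n_g=1)
        stim = Stimulus(rng.uniform(0.5, 2, p.N_MC))
        prev = None
        for g in (1e-9, 0.3, 0.8, 1.5):
            st.g = g
            M = solve_steady_state(stim, st, p).M
            if prev is not None:
                assert (M <= prev + 1e-5).all()
            prev = M

    def test_zero_g_recovers_uninhibited_bulb(self, tiny_params):
        p = tiny_params.replace(w_CM=0.0)
        rng = np.random.default_rng(5)
        st = random_small_state(p, rng, n_g=3)
        st.g = 1e-12
        S = rng.uniform(0, 2, p.N_MC)
        res = solve_steady_state(Stimulus(S), st, p)
        np.testing.assert_allclose(res.M, S + p.M_sp, atol=1e-4)
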