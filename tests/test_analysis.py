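import numpy as np
import pytest
from scipy.optimize import minimize

from conftest import random_small_state
from neurobulb.analysis import (
    connectivity_selectivity,
    effective_connectivity,
    fisher_nonopt,
    fisher_opt,
    odor_mc_sets,
    pattern_correlation,
    receptive_field_matching,
)
from neurobulb.model_core import ModelParams, initial_state


def triple_loop_effective(state):
    """Explicit element-by-element evaluation of the disynaptic counts."""
    n_mc = state.W_MG.shape[0]
    n_g = state.N_G
    n_cc = state.W_GC.shape[1]
    W_MM = np.zeros((n_mc, n_mc), dtype=int)
    W_MC = np.zeros((n_mc, n_cc), dtype=int)
    for i in range(n_mc):
        for j in range(n_mc):
            for k in range(n_g):
                W_MM[i, j] += state.W_MG[i, k] * state.W_MG[j, k]
        for c in range(n_cc):
            for k in range(n_g):
                W_MC[i, c] += state.W_MG[i, k] * state.W_GC[k, c]
    return W_MM, W_MC


class TestEffectiveConnectivity:
    def test_no_gcs_all_zero(self, tiny_params):
        eff = effective_connectivity(initial_state(tiny_params))
        assert (eff.W_MM == 0).all() and (eff.W_MC == 0).all()

    def test_hand_example(self, tiny_params):
        # GC1 on MCs {0,1}, GC2 on MCs {1,2}
        st = initial_state(tiny_params)
        st.W_MG = np.array([[1, 0], [1, 1], [0, 1], [0, 0]], dtype=np.int8)
        st.W_GC = np.zeros((2, tiny_params.N_CC), dtype=np.int8)
        st.W_GC[0, 0] = st.W_GC[1, 1] = 1
        st.G = np.zeros(2)
        eff = effective_connectivity(st)
        assert eff.W_MM[0, 1] == eff.W_MM[1, 0] == 1
        assert eff.W_MM[1, 2] == eff.W_MM[2, 1] == 1
        assert eff.W_MM[0, 2] == 0
        np.testing.assert_array_equal(np.diag(eff.W_MM), [1, 2, 1, 0])
        assert eff.W_MC[1, 0] == 1 and eff.W_MC[1, 1] == 1

    def test_diagonal_is_gc_degree_and_zeroing(self, params):
        rng = np.random.default_rng(0)
        st = random_small_state(params, rng, n_g=40)
        eff = effective_connectivity(st)
        np.testing.assert_array_equal(np.diag(eff.W_MM), st.W_MG.sum(axis=1))
        effz = effective_connectivity(st, diag_zeroed=True)
        assert np.diag(effz.W_MM).max() == 0

    def test_matches_triple_loop_oracle(self, tiny_params):
        rng = np.random.default_rng(5)
        st = random_small_state(tiny_params, rng, n_g=7)
        W_MM, W_MC = triple_loop_effective(st)
        eff = effective_connectivity(st)
        np.testing.assert_array_equal(eff.W_MM, W_MM)
        np.testing.assert_array_equal(eff.W_MC, W_MC)
        assert (eff.W_MM == eff.W_MM.T).all()


class TestFisherOpt:
    def test_identical_patterns(self):
        assert fisher_opt(np.array([1.0, 2.0]), np.array([1.0, 2.0])) == 0.0

    def test_hand_value(self):
        assert fisher_opt(np.array([2.0, 0, 1]),
                          np.array([0, 2.0, 1])) == pytest.approx(4.0)

    def test_homogeneous_of_degree_one(self):
        rng = np.random.default_rng(0)
        m1, m2 = rng.uniform(0, 2, 8), rng.uniform(0, 2, 8)
        for c in (0.5, 3.0):
            assert fisher_opt(c * m1, c * m2) == pytest.approx(
                c * fisher_opt(m1, m2))

    def test_silent_channels_dropped(self):
        m1 = np.array([1.0, 0.0, -0.5])
        m2 = np.array([0.0, 0.0, -1.0])
        assert fisher_opt(m1, m2) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_is_supremum_of_random_readout(self, seed):
        """F_opt equals the numerically maximized F_random over weights."""
        rng = np.random.default_rng(seed)
        m1, m2 = rng.uniform(0.1, 2, 5), rng.uniform(0.1, 2, 5)
        d, s = m1 - m2, m1 + m2

        def neg_f(w):
            num = (w @ d) ** 2
            den = (w * w) @ s
            return -num / den

        best = -np.inf
        for _ in range(10):
            res = minimize(neg_f, rng.uniform(-1, 1, 5), method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-12,
                                    "maxiter": 5000})
            best = max(best, -res.fun)
        assert best == pytest.approx(fisher_opt(m1, m2), rel=1e-4)


class TestFisherNonopt:
    def test_identical_patterns_zero(self):
        m = np.array([1.0, 0.5])
        assert fisher_nonopt(m, m, 100, np.random.default_rng(0)) == 0.0

    def test_single_channel_equals_optimum(self):
        """With one informative MC the weights cancel out of the ratio."""
        m1, m2 = np.array([2.0]), np.array([0.5])
        rng = np.random.default_rng(1)
        assert fisher_nonopt(m1, m2, 50, rng) == pytest.approx(
            fisher_opt(m1, m2))

    def test_matches_high_repetition_oracle(self):
        rng = np.random.default_rng(2)
        m1, m2 = rng.uniform(0, 2, 6), rng.uniform(0, 2, 6)
        d, s = m1 - m2, m1 + m2
        w = np.random.default_rng(3).uniform(-1, 1, (10**6, 6))
        oracle_vals = (w @ d) ** 2 / ((w * w) @ s)
        oracle = oracle_vals.mean()
        se = oracle_vals.std() / 1000
        est = fisher_nonopt(m1, m2, 5000, np.random.default_rng(4))
        assert abs(est - oracle) < 3 * (se + oracle_vals.std() / np.sqrt(5000))

    def test_standard_error_shrinks_with_readouts(self):
        rng = np.random.default_rng(5)
        m1, m2 = rng.uniform(0, 2, 6), rng.uniform(0, 2, 6)

        def spread(n, reps=30):
            vals = [fisher_nonopt(m1, m2, n, np.random.default_rng(1000 + r))
                    for r in range(reps)]
            return np.std(vals)

        s_small, s_big = spread(200), spread(3200)
        assert s_big < s_small / 2.5  # expect ~1/4 from 16x readouts


class TestPatternCorrelation:
    def test_perfect_and_anti(self):
        a = np.array([0.1, 0.5, 1.0])
        assert pattern_correlation(a, a) == pytest.approx(1.0)
        assert pattern_correlation(a, -a + 2, rectified=False) == pytest.approx(-1.0)

    def test_zero_variance_flagged(self):
        with pytest.raises(ValueError):
            pattern_correlation(np.ones(4), np.array([1.0, 2, 3, 4]))

    def test_rectification_default(self):
        a = np.array([-1.0, 2.0, -3.0, 4.0])
        b = np.array([0.5, 2.0, 0.1, 4.0])
        got = pattern_correlation(a, b)
        assert got == pytest.approx(
            np.corrcoef(np.maximum(a, 0), b)[0, 1])


class TestSelectivity:
    def test_block_diagonal_scores_one(self):
        W = np.zeros((6, 6))
        sets = {"a": np.array([0, 1, 2]), "b": np.array([3, 4, 5])}
        W[np.ix_(sets["a"], sets["a"])] = 2
        W[np.ix_(sets["b"], sets["b"])] = 2
        assert connectivity_selectivity(W, sets, sets) == pytest.approx(1.0)

    def test_constant_matrix_scores_zero(self):
        W = np.full((6, 6), 3.0)
        sets = {"a": np.array([0, 1, 2]), "b": np.array([3, 4, 5])}
        assert connectivity_selectivity(W, sets, sets) == pytest.approx(0.0)

    def test_empty_set_rejected(self):
        W = np.zeros((4, 4))
        with pytest.raises(ValueError):
            connectivity_selectivity(W, {"a": np.array([0]),
                                         "b": np.array([], dtype=int)},
                                     {"a": np.array([0]),
                                      "b": np.array([], dtype=int)})

    def test_odor_mc_sets_disjoint_and_centered(self):
        from neurobulb.stimuli import build_scene
        p = ModelParams()
        sc = build_scene("two_odors", p)
        sets = odor_mc_sets(sc.odors)
        assert set(sets["O1"]).isdisjoint(sets["O2"])
        assert int(np.argmax(sc.odors["O1"])) in sets["O1"]


class TestReceptiveFieldMatching:
    def test_aligned_wiring_gives_positive_correlation(self, tiny_params):
        st = initial_state(tiny_params)
        # GC0 listens to MCs {0,1} and CC 0; GC1 to MCs {2,3} and CC 2
        st.W_MG = np.array([[1, 0], [1, 0], [0, 1], [0, 1]], dtype=np.int8)
        st.W_GC = np.zeros((2, tiny_params.N_CC), dtype=np.int8)
        st.W_GC[0, 0] = 1
        st.W_GC[1, 2] = 1
        st.G = np.zeros(2)
        # odor A drives MCs {0,1} and CC 0; odor B drives MCs {2,3} and CC 2
        M = np.array([[2.0, 0], [2.0, 0], [0, 2.0], [0, 2.0]])
        C = np.zeros((tiny_params.N_CC, 2))
        C[0, 0] = 1.0
        C[2, 1] = 1.0
        r = receptive_field_matching(st, M, C)
        np.testing.assert_allclose(r, [1.0, 1.0])
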