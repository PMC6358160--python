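import numpy as np
import pytest
from hypothesis import settings

from neurobulb.model_core import ModelParams, NetworkState, initial_state

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def params() -> ModelParams:
    return ModelParams()


@pytest.fixture
def tiny_params() -> ModelParams:
    """A hand-checkable network: 4 MCs, 4 odor CCs + 2 contextual CCs."""
    return ModelParams(N_MC=4, N_CC_odor=4, N_CC_context=2, n_contexts=2,
                       N_conn_MG=2, N_conn_GC=1, N_GC_aim=4, N_new_G=2)


def random_small_state(p: ModelParams, rng: np.random.Generator,
                       n_g: int) -> NetworkState:
    """Random wiring respecting all degree constraints, with random W_CC."""
    st = initial_state(p)
    W_MG = np.zeros((p.N_MC, n_g), dtype=np.int8)
    W_GC = np.zeros((n_g, p.N_CC), dtype=np.int8)
    for k in range(n_g):
        W_MG[rng.choice(p.N_MC, p.N_conn_MG, replace=False), k] = 1
        W_GC[k, rng.choice(p.N_CC, p.N_conn_GC, replace=False)] = 1
    st.W_MG, st.W_GC = W_MG, W_GC
    st.G = np.zeros(n_g)
    W_CC = rng.uniform(0, p.W_max_CC, size=(p.N_CC, p.N_CC))
    np.fill_diagonal(W_CC, 0.0)
    st.W_CC = W_CC
    return st
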