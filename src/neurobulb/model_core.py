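"""Domain types, nonlinearities and structural invariants of the cortico-bulbar model.

The network has three firing-rate populations: mitral/tufted cells (MCs), the
excitatory principal neurons of the olfactory bulb; granule cells (GCs), axonless
inhibitory interneurons that form reciprocal dendrodendritic synapses with MCs and
turn over by adult neurogenesis; and cortical cells (CCs), an effective associative
cortical population with plastic recurrent excitation, global inhibition and
top-down projections onto the GCs.

Connectivity conventions
------------------------
Only the MC-side matrix ``W_MG`` (N_MC x N_G) of the reciprocal MC-GC synapses is
stored; the GC-side matrix is its transpose by definition.  ``W_GC`` (N_G x N_CC)
holds the top-down projections, ``W_CM`` (N_CC x N_MC) the bulb-to-cortex
feedforward map (identity on the odor-CC block by default), and ``W_CC``
(N_CC x N_CC, zero diagonal) the plastic recurrent cortical excitation.  All
binary matrices have {0,1} entries; each GC has exactly ``N_conn_MG`` MC partners
and ``N_conn_GC`` CC partners.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

__all__ = [
    "ModelParams",
    "NetworkState",
    "Stimulus",
    "Environment",
    "rectify",
    "cc_sigmoid",
    "validate_state",
    "initial_state",
    "context_cc_indices",
    "load_params",
    "save_state",
    "load_state",
]


@dataclass
class ModelParams:
    """All model, solver and controller parameters.

    Activities are dimensionless rates and time is measured in units of the MC
    time constant.  The GC time constant is fixed to zero (steady-state
    reduction), so GC rates are an algebraic function of MC and CC rates.
    """

    # time constants (a.u.)
    tau_M: float = 1.0
    tau_C: float = 1.0

    # bulb
    M_sp: float = 0.2          # spontaneous MC drive
    G_th: float = 3.0          # GC activation threshold
    N_MC: int = 110

    # couplings
    w_GC: float = 3.0          # top-down CC->GC weight
    w_CM: float = 1.25         # MC->CC feedforward weight
    w_inh: float = 0.05        # all-to-all cortical inhibition
    alpha_learn: float = 0.05  # recurrent-excitation scale during learning
    alpha_recall: float = 1.0  # ... during recall/probing

    # CC sigmoid
    gamma_C: float = 3.0
    C_th: float = 0.2
    C_max: float = 1.0

    # Hebbian rule
    eta: float = 10.0
    Omega: float = 0.2
    kappa: float = 0.1
    W_max_CC: float = 0.06

    # neurogenesis
    N_conn_MG: int = 16        # MC partners per new GC
    N_conn_GC: int = 2         # CC partners per new GC
    N_GC_aim: int = 500        # homeostatic target GC count (working scale)
    N_new_G: Optional[int] = None   # GCs added per step; default round(0.1*N_GC_aim)
    N_CC_context: int = 48
    n_contexts: int = 2        # contextual CCs are split evenly among contexts
    N_CC_odor: Optional[int] = None  # default N_MC (identity W_CM)

    # survival sigmoid
    gamma_R: float = 5.0
    R_0: float = 3.0

    # solver
    dt: Optional[float] = None      # default 0.05*min(tau_M, tau_C)
    steady_tol: float = 1e-6
    t_max: float = 1e3

    # inhibition-strength controller; g_init starts near the desk-scale
    # equilibrium to shorten burn-in (the steady state is set by the band)
    g_init: float = 0.02
    g_gain: float = 0.01
    g_band: float = 0.05

    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.N_CC_odor is None:
            self.N_CC_odor = self.N_MC
        if self.N_new_G is None:
            self.N_new_G = int(round(0.1 * self.N_GC_aim))
        if self.dt is None:
            self.dt = 0.05 * min(self.tau_M, self.tau_C)
        for name in ("N_MC", "N_conn_MG", "N_conn_GC", "N_GC_aim",
                     "N_CC_context", "N_CC_odor", "n_contexts"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if self.N_new_G < 0:
            raise ValueError("N_new_G must be >= 0")
        if self.N_conn_MG > self.N_MC:
            raise ValueError("N_conn_MG cannot exceed N_MC")
        if self.N_conn_GC > self.N_CC:
            raise ValueError("N_conn_GC cannot exceed the number of CCs")
        if self.N_CC_context % self.n_contexts:
            raise ValueError("N_CC_context must divide evenly among contexts")

    @property
    def N_CC(self) -> int:
        return int(self.N_CC_odor) + int(self.N_CC_context)

    def replace(self, **kwargs) -> "ModelParams":
        """Return a copy with the given fields overridden."""
        return dataclasses.replace(self, **kwargs)


@dataclass
class NetworkState:
    """Activities, connectivity and inhibition strength of the full network."""

    M: np.ndarray          # (N_MC,) MC rates
    G: np.ndarray          # (N_G,) GC rates
    C: np.ndarray          # (N_CC,) CC rates
    W_MG: np.ndarray       # (N_MC, N_G) binary, reciprocal MC<->GC synapses
    W_GC: np.ndarray       # (N_G, N_CC) binary, top-down projections
    W_CM: np.ndarray       # (N_CC, N_MC) binary, bulb->cortex
    W_CC: np.ndarray       # (N_CC, N_CC) plastic recurrent excitation
    g: float               # reciprocal-inhibition strength

    @property
    def N_G(self) -> int:
        return self.W_MG.shape[1]

    def copy(self) -> "NetworkState":
        return NetworkState(
            M=self.M.copy(), G=self.G.copy(), C=self.C.copy(),
            W_MG=self.W_MG.copy(), W_GC=self.W_GC.copy(),
            W_CM=self.W_CM.copy(), W_CC=self.W_CC.copy(), g=float(self.g),
        )


@dataclass
class Stimulus:
    """An odor drive over MCs, optionally paired with a contextual drive.

    ``context_id`` selects a contiguous block of contextual CCs that receive
    the constant additive drive ``A_context``.
    """

    S: np.ndarray
    context_id: Optional[int] = None
    A_context: float = 2.0
    name: str = ""

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        if np.any(self.S < 0):
            raise ValueError("odor drive must be nonnegative")


@dataclass
class Environment:
    """Ordered set of training stimuli (each carrying its context, if any)."""

    training_pairs: Sequence[Stimulus] = field(default_factory=list)

    @property
    def N_s(self) -> int:
        return len(self.training_pairs)


def rectify(x: np.ndarray) -> np.ndarray:
    """Threshold-linear nonlinearity [x]_+ = max(x, 0), elementwise."""
    return np.maximum(np.asarray(x, dtype=float), 0.0)


def cc_sigmoid(C: np.ndarray, params: ModelParams) -> np.ndarray:
    """Saturating CC nonlinearity sigma(C) = C_max / (1 + exp(-gamma_C (C - C_th)))."""
    C = np.asarray(C, dtype=float)
    z = np.clip(params.gamma_C * (C - params.C_th), -700.0, 700.0)
    return params.C_max / (1.0 + np.exp(-z))


def context_cc_indices(context_id: int, params: ModelParams) -> np.ndarray:
    """CC indices of the contiguous contextual block assigned to ``context_id``.

    Contexts are numbered from 0; the ``N_CC_context`` contextual cells sit
    after the odor CCs and are split evenly among ``n_contexts`` contexts.
    """
    if not 0 <= context_id < params.n_contexts:
        raise ValueError(f"unknown context {context_id}")
    block = params.N_CC_context // params.n_contexts
    start = params.N_CC_odor + context_id * block
    return np.arange(start, start + block)


def initial_state(params: ModelParams) -> NetworkState:
    """Network before any neurogenesis: no GCs, untrained cortex.

    ``W_CM`` is the identity on the odor-CC block (each odor CC listens to one
    MC); contextual CCs receive no bulbar input.
    """
    n_cc = params.N_CC
    W_CM = np.zeros((n_cc, params.N_MC), dtype=np.int8)
    k = min(params.N_CC_odor, params.N_MC)
    W_CM[np.arange(k), np.arange(k)] = 1
    return NetworkState(
        M=np.full(params.N_MC, params.M_sp),
        G=np.zeros(0),
        C=np.zeros(n_cc),
        W_MG=np.zeros((params.N_MC, 0), dtype=np.int8),
        W_GC=np.zeros((0, n_cc), dtype=np.int8),
        W_CM=W_CM,
        W_CC=np.zeros((n_cc, n_cc)),
        g=params.g_init,
    )


def validate_state(state: NetworkState, params: ModelParams) -> list[str]:
    """Check every structural invariant; return a list of violation messages."""
    v: list[str] = []
    n_g = state.N_G
    if state.M.shape != (params.N_MC,):
        v.append(f"M has shape {state.M.shape}, expected ({params.N_MC},)")
    if state.G.shape != (n_g,):
        v.append(f"G has shape {state.G.shape}, expected ({n_g},)")
    if state.C.shape != (params.N_CC,):
        v.append(f"C has shape {state.C.shape}, expected ({params.N_CC},)")
    if state.W_GC.shape != (n_g, params.N_CC):
        v.append(f"W_GC has shape {state.W_GC.shape}, expected ({n_g}, {params.N_CC})")
    if state.W_CM.shape != (params.N_CC, params.N_MC):
        v.append(f"W_CM has shape {state.W_CM.shape}")
    if state.W_CC.shape != (params.N_CC, params.N_CC):
        v.append(f"W_CC has shape {state.W_CC.shape}")
    for name in ("W_MG", "W_GC", "W_CM"):
        m = getattr(state, name)
        bad = ~np.isin(m, (0, 1))
        if bad.any():
            idx = tuple(int(i) for i in np.argwhere(bad)[0])
            v.append(f"{name} has non-binary entry at {idx}")
    if state.W_MG.shape[1] == n_g:
        deg = state.W_MG.sum(axis=0)
        for i in np.nonzero(deg != params.N_conn_MG)[0]:
            v.append(f"GC {int(i)} has MC degree {int(deg[i])}, expected {params.N_conn_MG}")
    if state.W_GC.shape == (n_g, params.N_CC):
        deg = state.W_GC.sum(axis=1)
        for i in np.nonzero(deg != params.N_conn_GC)[0]:
            v.append(f"GC {int(i)} has CC degree {int(deg[i])}, expected {params.N_conn_GC}")
    if state.W_CC.shape == (params.N_CC, params.N_CC):
        eps = 1e-12
        bad = (state.W_CC < -eps) | (state.W_CC > params.W_max_CC + eps)
        for i, j in np.argwhere(bad)[:10]:
            v.append(f"W_CC[{int(i)},{int(j)}]={state.W_CC[i, j]:.4g} outside [0, W_max_CC]")
        d = np.abs(np.diag(state.W_CC))
        for i in np.nonzero(d > eps)[0]:
            v.append(f"W_CC diagonal nonzero at {int(i)}")
    if not state.g > 0:
        v.append(f"g={state.g} must be positive")
    return v


# ---------------------------------------------------------------------------
# parameter files and state snapshots

def load_params(path: str | Path, **overrides) -> ModelParams:
    """Read a flat YAML/JSON mapping of parameter names; unset keys keep defaults."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    data = dict(data or {})
    data.update(overrides)
    names = {f.name for f in dataclasses.fields(ModelParams)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    return ModelParams(**data)


def save_state(state: NetworkState, path: str | Path) -> None:
    """Write a snapshot archive (npz): five matrices, three activity vectors, g."""
    np.savez_compressed(
        path,
        M=state.M, G=state.G, C=state.C,
        W_MG=state.W_MG.astype(np.int8), W_GC=state.W_GC.astype(np.int8),
        W_CM=state.W_CM.astype(np.int8), W_CC=state.W_CC, g=np.float64(state.g),
    )


def load_state(path: str | Path) -> NetworkState:
    with np.load(path) as z:
        return NetworkState(
            M=z["M"], G=z["G"], C=z["C"],
            W_MG=z["W_MG"], W_GC=z["W_GC"], W_CM=z["W_CM"], W_CC=z["W_CC"],
            g=float(z["g"]),
        )
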