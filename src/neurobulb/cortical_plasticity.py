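"""Hebbian learning, freezing and extinction of the recurrent cortical weights.

The recurrent excitatory weights among CCs are learned once, at the start of a
simulation, by repeatedly presenting each training scene (odor together with
its associated context), letting the network relax to its steady state with the
reduced learning-phase recurrence scale ``alpha_learn``, and applying

    W_ij -> clip( W_ij + eta * [ (sigma(C_i) - Omega) sigma(C_j) - kappa ],
                  0, W_max_CC ),        i != j.

``Omega`` is the potentiation threshold and ``kappa`` a uniform decay.  With
the default rates the rule is effectively one-shot: weights between co-active
CCs saturate at ``W_max_CC`` within a couple of presentations and all others
decay to zero.  During the subsequent neurogenic evolution the learned weights
are held fixed; memory extinction removes the associative weights among a
chosen set of CCs without touching the rest of the matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Set

import numpy as np

from .dynamics import solve_steady_state
from .model_core import (
    Environment,
    ModelParams,
    NetworkState,
    Stimulus,
    cc_sigmoid,
)

__all__ = ["PlasticityConfig", "hebbian_update", "train_cortex",
           "extinguish_memory", "responsive_cc_set",
           "export_cortical_weights", "import_cortical_weights"]


@dataclass
class PlasticityConfig:
    n_epochs: int = 50
    convergence_tol: Optional[float] = None  # default 1e-4 * W_max_CC

    def __post_init__(self) -> None:
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")


def hebbian_update(W_CC: np.ndarray, C_steady: np.ndarray,
                   params: ModelParams) -> np.ndarray:
    """One Hebbian step from the steady-state CC activities; returns a new matrix."""
    sig = cc_sigmoid(C_steady, params)
    delta = params.eta * ((sig[:, None] - params.Omega) * sig[None, :] - params.kappa)
    W = np.clip(W_CC + delta, 0.0, params.W_max_CC)
    np.fill_diagonal(W, 0.0)
    return W


def train_cortex(
    env: Environment,
    state: NetworkState,
    params: ModelParams,
    cfg: Optional[PlasticityConfig] = None,
    history: Optional[list] = None,
) -> NetworkState:
    """Learn ``W_CC`` from the training environment; bulbar wiring is untouched.

    Each epoch presents every training scene once (odor jointly with its
    context), solves the steady state at ``alpha_learn`` for the current
    weights, and applies one Hebbian update.  Stops early once the largest
    weight change in an epoch falls below the convergence tolerance.  If a
    ``history`` list is given, one ``{"epoch", "max_dw"}`` entry is appended
    per epoch.
    """
    cfg = cfg or PlasticityConfig()
    tol = cfg.convergence_tol
    if tol is None:
        tol = 1e-4 * params.W_max_CC
    out = state.copy()
    for _ in range(cfg.n_epochs):
        # Accumulate the increments of all scenes before clipping: the decay
        # term eta*kappa exceeds W_max_CC, so applying scenes one at a time
        # would erase every block not co-active in the current scene and leave
        # only the last-presented memory.  Summing within the epoch keeps all
        # memories and makes the result independent of presentation order.
        delta = np.zeros_like(out.W_CC)
        for stim in env.training_pairs:
            res = solve_steady_state(stim, out, params, alpha=params.alpha_learn)
            sig = cc_sigmoid(res.C, params)
            delta += params.eta * ((sig[:, None] - params.Omega) * sig[None, :]
                                   - params.kappa)
        W_new = np.clip(out.W_CC + delta, 0.0, params.W_max_CC)
        np.fill_diagonal(W_new, 0.0)
        max_dw = float(np.abs(W_new - out.W_CC).max(initial=0.0))
        out.W_CC = W_new
        if history is not None:
            history.append({"epoch": len(history), "max_dw": max_dw})
        if max_dw < tol:
            break
    return out


def export_cortical_weights(state: NetworkState, path, alpha: float,
                            history: Optional[list] = None) -> None:
    """Write ``W_CC`` as a dense CSV plus a JSON sidecar (alpha, history)."""
    import json
    from pathlib import Path

    path = Path(path)
    np.savetxt(path, state.W_CC, delimiter=",")
    sidecar = {"alpha": float(alpha), "history": history or []}
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2))


def import_cortical_weights(path) -> tuple[np.ndarray, dict]:
    """Read a dense ``W_CC`` CSV and its JSON sidecar."""
    import json
    from pathlib import Path

    path = Path(path)
    W = np.loadtxt(path, delimiter=",")
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return W, meta


def extinguish_memory(state: NetworkState, cc_indices: Iterable[int]) -> NetworkState:
    """Zero the associative weights among ``cc_indices`` (both directions).

    Models extinction of the cortical memory of the odors represented by those
    CCs; weights involving any CC outside the set are untouched.
    """
    idx = np.asarray(sorted(set(int(i) for i in cc_indices)), dtype=int)
    out = state.copy()
    if idx.size == 0:
        warnings.warn("extinguish_memory called with an empty CC set; no-op")
        return out
    if idx.min() < 0 or idx.max() >= state.W_CC.shape[0]:
        raise ValueError("cc_indices outside the CC index range")
    out.W_CC[np.ix_(idx, idx)] = 0.0
    return out


def responsive_cc_set(
    state: NetworkState,
    stimulus: Stimulus,
    params: ModelParams,
    threshold: float,
) -> Set[int]:
    """CCs whose steady-state output sigma(C) to the stimulus exceeds threshold."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    res = solve_steady_state(stimulus, state, params, alpha=params.alpha_recall)
    sig = cc_sigmoid(res.C, params)
    return set(int(i) for i in np.nonzero(sig > threshold)[0])
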