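"""Steady-state activities of the three-population rate model.

With the GC time constant set to zero the GC rates are an algebraic function
of the MC and CC rates, and only the MC and CC equations are integrated:

    tau_M dM_i/dt = -M_i + S_i + M_sp - g sum_j W^(MG)_ij [G_j - G_th]_+
            G_i   =  sum_j W^(GM)_ij [M_j]_+ + w_GC sum_j W^(GC)_ij sigma(C_j)
    tau_C dC_i/dt = -C_i + w_CM sum_j W^(CM)_ij [M_j]_+
                    + sum_{j != i} (alpha W^(CC)_ij - w_inh) sigma(C_j) + I^ext_i

where I^ext is the constant contextual drive (A_context on the contextual CCs
of the stimulus' context, zero elsewhere).  The fixed point is found by
explicit Euler integration from a cold start (M = M_sp, C = 0); the step size
starts at dt = 0.05 min(tau_M, tau_C) and is halved whenever the residual
fails to decrease, which keeps the scheme stable when the disynaptic
inhibition loop gain is large.  The returned state satisfies both differential
equations to ``steady_tol`` regardless of the path taken.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .model_core import (
    ModelParams,
    NetworkState,
    Stimulus,
    cc_sigmoid,
    context_cc_indices,
    rectify,
)

__all__ = ["SteadyStateResult", "ConvergenceError", "gc_activity",
           "solve_steady_state", "steady_states_batch", "context_drive",
           "steady_state_to_csv"]


class ConvergenceError(RuntimeError):
    """No fixed point reached within t_max (runaway/bistable cortical network)."""


@dataclass
class SteadyStateResult:
    M: np.ndarray
    G: np.ndarray
    C: np.ndarray
    residual: float
    converged: bool
    iterations: int


def context_drive(stimulus: Stimulus, params: ModelParams) -> np.ndarray:
    """Constant external current onto the CCs encoding the stimulus' context."""
    drive = np.zeros(params.N_CC)
    if stimulus.context_id is not None:
        drive[context_cc_indices(stimulus.context_id, params)] = stimulus.A_context
    return drive


def gc_activity(
    M: np.ndarray,
    C: np.ndarray,
    state: NetworkState,
    params: ModelParams,
    w_gc: Optional[float] = None,
) -> np.ndarray:
    """Algebraic GC rates for given MC and CC rates (zero GC time constant)."""
    M = np.asarray(M, dtype=float)
    C = np.asarray(C, dtype=float)
    if M.shape[0] != state.W_MG.shape[0]:
        raise ValueError(f"M has length {M.shape[0]}, wiring expects {state.W_MG.shape[0]}")
    if C.shape[0] != state.W_GC.shape[1]:
        raise ValueError(f"C has length {C.shape[0]}, wiring expects {state.W_GC.shape[1]}")
    if w_gc is None:
        w_gc = params.w_GC
    return state.W_MG.T @ rectify(M) + w_gc * (state.W_GC @ cc_sigmoid(C, params))


def steady_state_to_csv(result: SteadyStateResult, path) -> None:
    """Write a steady state as CSV rows (cell index, population, rate)."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["index", "population", "rate"])
        for name, vec in (("MC", result.M), ("GC", result.G),
                          ("CC", result.C)):
            for i, r in enumerate(vec):
                w.writerow([i, name, repr(float(r))])


def _rest_cc_potential(params: ModelParams) -> float:
    """Uniform cortical rest potential: the fixed point of
    c = -w_inh (N_CC - 1) sigma(c) with no sensory, recurrent or context drive.

    Used as the initial condition for every steady-state solve: starting from
    C = 0 would mean sigma(0) = C_max/(1+e^{gamma_C C_th}), a transient
    cortical output far above rest that can tip the bulb into a spuriously
    collapsed branch when the network is multistable.
    """
    from scipy.optimize import brentq

    k = params.w_inh * (params.N_CC - 1)

    def f(c: float) -> float:
        sig = params.C_max / (1.0 + np.exp(-params.gamma_C * (c - params.C_th)))
        return c + k * sig

    return float(brentq(f, -k * params.C_max - 1.0, 0.0, xtol=1e-12))


def _euler_fixed_point(
    S: np.ndarray,
    C_ext: np.ndarray,
    state: NetworkState,
    params: ModelParams,
    alpha: float,
    w_gc: float,
):
    """Batched Euler relaxation; columns of S / C_ext are independent scenes."""
    n_mc, batch = S.shape
    W_MG = state.W_MG.astype(float)
    W_GM = W_MG.T
    W_GC = state.W_GC.astype(float)
    W_CM = state.W_CM.astype(float)
    W_rec = alpha * state.W_CC          # zero diagonal by invariant
    g = state.g
    p = params

    M = np.full((n_mc, batch), p.M_sp)
    C = np.full((p.N_CC, batch), _rest_cc_potential(p))

    dt = p.dt
    dt_min = p.dt / 4096.0
    dt_max = 5.0 * p.dt
    t = 0.0
    it = 0
    check_every = 20
    res = np.inf
    res_at_check = np.inf
    snapshot = (M.copy(), C.copy())

    while t < p.t_max:
        Mp = np.maximum(M, 0.0)
        sig = cc_sigmoid(C, p)
        G = W_GM @ Mp + w_gc * (W_GC @ sig)
        inhib = W_MG @ np.maximum(G - p.G_th, 0.0)
        dM = (-M + S + p.M_sp - g * inhib) / p.tau_M
        sig_sum = sig.sum(axis=0, keepdims=True)
        dC = (-C + p.w_CM * (W_CM @ Mp) + W_rec @ sig
              - p.w_inh * (sig_sum - sig) + C_ext) / p.tau_C
        res = max(np.abs(dM).max(initial=0.0), np.abs(dC).max(initial=0.0))
        if res <= p.steady_tol:
            return M, G, C, res, True, it
        if not np.isfinite(res) or res > 1e9:
            M, C = (a.copy() for a in snapshot)
            dt *= 0.5
            if dt < dt_min:
                break
            continue
        M = M + dt * dM
        C = C + dt * dC
        t += dt
        it += 1
        if it % check_every == 0:
            if res > res_at_check and res > 10.0 * p.steady_tol:
                dt *= 0.5
                if dt < dt_min:
                    break
            elif res < 0.3 * res_at_check and dt < dt_max:
                # smooth contraction: take larger steps (still guarded by
                # the halving/revert logic above)
                dt = min(1.5 * dt, dt_max)
            res_at_check = res
            snapshot = (M.copy(), C.copy())

    Mp = np.maximum(M, 0.0)
    G = W_GM @ Mp + w_gc * (W_GC @ cc_sigmoid(C, p))
    return M, G, C, float(res), False, it


def solve_steady_state(
    stimulus: Stimulus,
    state: NetworkState,
    params: ModelParams,
    alpha: Optional[float] = None,
    w_gc: Optional[float] = None,
    check: bool = True,
) -> SteadyStateResult:
    """Fixed point of the rate equations for one stimulus/context scene.

    ``alpha`` scales the recurrent cortical excitation (``alpha_recall`` by
    default); ``w_gc`` overrides the top-down weight, with ``w_gc=0``
    implementing the feedback-blockade probes.  Raises :class:`ConvergenceError`
    if no fixed point is reached within ``t_max`` (pass ``check=False`` to get
    the unconverged result instead).
    """
    if alpha is None:
        alpha = params.alpha_recall
    if w_gc is None:
        w_gc = params.w_GC
    S = np.asarray(stimulus.S, dtype=float)
    if S.shape[0] != params.N_MC:
        raise ValueError(f"stimulus has {S.shape[0]} channels, model has {params.N_MC} MCs")
    C_ext = context_drive(stimulus, params)
    M, G, C, res, ok, it = _euler_fixed_point(
        S[:, None], C_ext[:, None], state, params, alpha, w_gc
    )
    if check and not ok:
        raise ConvergenceError(
            f"no steady state within t_max={params.t_max} (residual {res:.3g}); "
            "the cortical network may be bistable"
        )
    return SteadyStateResult(M[:, 0], G[:, 0], C[:, 0], float(res), ok, it)


def steady_states_batch(
    stimuli: Sequence[Stimulus],
    state: NetworkState,
    params: ModelParams,
    alpha: Optional[float] = None,
    w_gc: Optional[float] = None,
):
    """Steady states for several scenes at once (columns of the returned M, G, C).

    All scenes share the wiring and are solved in one vectorized relaxation;
    results are identical to per-scene :func:`solve_steady_state` calls.
    """
    if alpha is None:
        alpha = params.alpha_recall
    if w_gc is None:
        w_gc = params.w_GC
    S = np.column_stack([np.asarray(s.S, dtype=float) for s in stimuli])
    C_ext = np.column_stack([context_drive(s, params) for s in stimuli])
    M, G, C, res, ok, _ = _euler_fixed_point(S, C_ext, state, params, alpha, w_gc)
    if not ok:
        raise ConvergenceError(
            f"no steady state within t_max={params.t_max} (residual {res:.3g})"
        )
    return M, G, C
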