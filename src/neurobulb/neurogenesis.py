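"""Structural plasticity of the granule-cell population.

Each neurogenic time step (i) adds ``N_new_G`` granule cells, each wiring to
``N_conn_MG`` random MCs (reciprocally) and ``N_conn_GC`` random CCs; (ii)
solves the steady state of the full network for every training scene; (iii)
scores each GC by its resilience, the sum of its thresholded steady-state
activity over the training scenes, R_i = sum_beta [G_i(beta) - G_th]_+; (iv)
keeps each GC independently with survival probability
P_i = (tanh(gamma_R (R_i - R_0)) + 1)/2; and (v) nudges the reciprocal
inhibition strength ``g`` multiplicatively to hold the surviving population
near the target count ``N_GC_aim``.  New GCs take part in the same step's
evaluation and selection.  Repeating the step drives the network to a
statistically steady wiring in which surviving GCs connect MCs and CCs with
matched odor receptive fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .cortical_plasticity import extinguish_memory
from .dynamics import steady_states_batch
from .model_core import Environment, ModelParams, NetworkState, Stimulus, rectify

__all__ = ["NeurogenesisFlags", "EvolutionRecord", "add_gcs",
           "compute_resilience", "survival_probability", "remove_gcs",
           "adapt_inhibition", "neurogenesis_step", "evolve"]


@dataclass
class NeurogenesisFlags:
    """Runtime switches for intervention protocols."""

    block_addition: bool = False
    apoptosis_blocked: bool = False
    freeze_g: bool = False


@dataclass
class EvolutionRecord:
    """Per-step history of a neurogenic run (one row per step)."""

    rows: List[dict] = field(default_factory=list)

    def append(self, row: dict) -> None:
        if row.get("N_G", 0) < 0 or row.get("g", 1.0) <= 0:
            raise ValueError("invalid record row")
        self.rows.append(row)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def __len__(self) -> int:
        return len(self.rows)


def add_gcs(state: NetworkState, params: ModelParams,
            rng: np.random.Generator) -> NetworkState:
    """Append ``N_new_G`` randomly wired GCs; existing wiring is untouched."""
    n_new = params.N_new_G
    out = state.copy()
    if n_new == 0:
        return out
    new_mg = np.zeros((params.N_MC, n_new), dtype=np.int8)
    new_gc = np.zeros((n_new, params.N_CC), dtype=np.int8)
    for k in range(n_new):
        new_mg[rng.choice(params.N_MC, size=params.N_conn_MG, replace=False), k] = 1
        new_gc[k, rng.choice(params.N_CC, size=params.N_conn_GC, replace=False)] = 1
    out.W_MG = np.concatenate([out.W_MG, new_mg], axis=1)
    out.W_GC = np.concatenate([out.W_GC, new_gc], axis=0)
    out.G = np.concatenate([out.G, np.zeros(n_new)])
    return out


def compute_resilience(G_responses: np.ndarray, G_th: float) -> np.ndarray:
    """Resilience R_i = sum over stimuli of the thresholded GC response."""
    G_responses = np.atleast_2d(np.asarray(G_responses, dtype=float))
    return rectify(G_responses - G_th).sum(axis=1)


def survival_probability(R: np.ndarray, params: ModelParams) -> np.ndarray:
    """Sigmoidal survival probability P_i = (tanh(gamma_R (R_i - R_0)) + 1)/2."""
    R = np.asarray(R, dtype=float)
    if np.any(R < 0):
        raise ValueError("resilience must be nonnegative")
    return 0.5 * (np.tanh(params.gamma_R * (R - params.R_0)) + 1.0)


def remove_gcs(
    state: NetworkState,
    P: np.ndarray,
    rng: np.random.Generator,
    apoptosis_blocked: bool = False,
) -> Tuple[NetworkState, np.ndarray]:
    """Independent Bernoulli survival per GC; returns (new state, removed indices)."""
    P = np.asarray(P, dtype=float)
    if P.shape != (state.N_G,):
        raise ValueError(f"P has shape {P.shape}, expected ({state.N_G},)")
    out = state.copy()
    if apoptosis_blocked:
        return out, np.zeros(0, dtype=int)
    survive = rng.random(state.N_G) < P
    removed = np.nonzero(~survive)[0]
    out.W_MG = out.W_MG[:, survive]
    out.W_GC = out.W_GC[survive, :]
    out.G = out.G[survive]
    return out, removed


def adapt_inhibition(g: float, N_G: int, params: ModelParams,
                     frozen: bool = False) -> float:
    """Multiplicative controller keeping N_G inside the band around N_GC_aim."""
    if g <= 0:
        raise ValueError("g must be positive")
    if frozen:
        return g
    if N_G > params.N_GC_aim * (1.0 + params.g_band):
        return g * (1.0 + params.g_gain)
    if N_G < params.N_GC_aim * (1.0 - params.g_band):
        return g * (1.0 - params.g_gain)
    return g


def neurogenesis_step(
    state: NetworkState,
    env: Environment,
    params: ModelParams,
    rng: np.random.Generator,
    flags: Optional[NeurogenesisFlags] = None,
) -> Tuple[NetworkState, dict]:
    """One neurogenic time step: add, evaluate, select, remove, regulate.

    The returned record row holds the post-removal GC count, the (possibly
    adapted) inhibition strength, the mean survival probability, and the mean
    pre-removal thresholded odor response of the removed GCs for every
    training stimulus (NaN when nothing was removed) — the quantity tracked in
    extinction protocols.
    """
    flags = flags or NeurogenesisFlags()
    if not flags.block_addition:
        state = add_gcs(state, params, rng)
    row: dict = {}
    if state.N_G > 0 and env.N_s > 0:
        # survival is evaluated on the odors alone: contexts enter cortical
        # learning and probing, not the resilience sum over training odors
        odors_only = [Stimulus(s.S, context_id=None, name=s.name)
                      for s in env.training_pairs]
        _, G_resp, _ = steady_states_batch(
            odors_only, state, params, alpha=params.alpha_recall
        )  # G_resp: (N_G, N_s)
        R = compute_resilience(G_resp, params.G_th)
        P = survival_probability(R, params)
        thresh_resp = rectify(G_resp - params.G_th)
        state, removed = remove_gcs(state, P, rng, flags.apoptosis_blocked)
        row["mean_survival_p"] = float(P.mean())
        row["n_removed"] = int(removed.size)
        for b, stim in enumerate(env.training_pairs):
            key = f"removed_resp_{stim.name or b}"
            row[key] = (float(thresh_resp[removed, b].mean())
                        if removed.size else float("nan"))
    else:
        row["mean_survival_p"] = float("nan")
        row["n_removed"] = 0
    g_new = adapt_inhibition(state.g, state.N_G, params, frozen=flags.freeze_g)
    state.g = g_new
    row["N_G"] = state.N_G
    row["g"] = g_new
    return state, row


Action = Union[str, Tuple[str, object], Callable[[NetworkState, ModelParams], NetworkState]]


def _apply_action(action: Action, state: NetworkState, params: ModelParams,
                  flags: NeurogenesisFlags) -> NetworkState:
    if callable(action):
        return action(state, params)
    if isinstance(action, tuple) and action[0] == "extinguish":
        return extinguish_memory(state, action[1])
    if action == "freeze_g":
        flags.freeze_g = True
    elif action == "unfreeze_g":
        flags.freeze_g = False
    elif action == "block_apoptosis":
        flags.apoptosis_blocked = True
    elif action == "unblock_apoptosis":
        flags.apoptosis_blocked = False
    else:
        raise ValueError(f"unknown intervention {action!r}")
    return state


def evolve(
    state: NetworkState,
    env: Environment,
    params: ModelParams,
    n_steps: int,
    rng: np.random.Generator,
    flags: Optional[NeurogenesisFlags] = None,
    interventions: Optional[Dict[int, Sequence[Action]]] = None,
) -> Tuple[NetworkState, EvolutionRecord]:
    """Run ``n_steps`` neurogenic steps with optional scheduled interventions.

    ``interventions`` maps a step index to actions applied just before that
    step runs: ``"freeze_g"``, ``"block_apoptosis"`` (and their inverses), an
    ``("extinguish", cc_indices)`` pair, or any callable
    ``(state, params) -> state``.  The run is fully determined by the initial
    state and the generator's seed.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    flags = flags or NeurogenesisFlags()
    interventions = interventions or {}
    record = EvolutionRecord()
    for step in range(n_steps):
        for action in interventions.get(step, ()):
            state = _apply_action(action, state, params, flags)
        state, row = neurogenesis_step(state, env, params, rng, flags)
        row["step"] = step
        record.append(row)
    return state, record
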