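"""Derived connectivities and performance statistics.

Effective disynaptic connectivity counts how many GCs mediate inhibition
between each MC pair (``W_MM = W_MG W_MG^T``) and from each CC onto each MC
(``W_MC = W_MG W_GC``).  Discriminability of two MC activity patterns is
scored with Fisher linear discriminants in which the firing rate itself
stands in for the (Poisson-like) trial-to-trial variance:

    F_opt    = sum_i ([M1_i]_+ - [M2_i]_+)^2 / ([M1_i]_+ + [M2_i]_+)
    F_random = (sum_i w_i D_i)^2 / sum_i w_i^2 ([M1_i]_+ + [M2_i]_+),
               w_i ~ U(-1, 1),  D_i = [M1_i]_+ - [M2_i]_+

with F_nonopt the mean of F_random over many random read-outs, modeling a
naive downstream population that has not yet learned task-optimal weights.
MCs silent in both patterns carry no information and their 0/0 terms are
dropped.  A selectivity score quantifies how block-structured an effective
connectivity matrix is with respect to per-odor MC/CC sets, and a
receptive-field matching statistic measures the central structural outcome:
the correlation, per GC, between its MC-side and CC-side odor response
profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .model_core import ModelParams, NetworkState, rectify

__all__ = ["EffectiveConnectivity", "effective_connectivity", "fisher_opt",
           "fisher_nonopt", "pattern_correlation", "connectivity_selectivity",
           "odor_mc_sets", "receptive_field_matching", "shuffle_gc_wiring"]


@dataclass
class EffectiveConnectivity:
    W_MM: np.ndarray       # (N_MC, N_MC) GC-mediated MC<->MC inhibition counts
    W_MC: np.ndarray       # (N_MC, N_CC) GC-mediated CC->MC inhibition counts
    diag_zeroed: bool


def effective_connectivity(state: NetworkState,
                           diag_zeroed: bool = False) -> EffectiveConnectivity:
    """Disynaptic inhibition counts W_MM = W_MG W_MG^T and W_MC = W_MG W_GC.

    The diagonal of W_MM equals each MC's GC degree and dwarfs the
    off-diagonal structure; ``diag_zeroed`` zeroes it for display only.
    """
    mg = state.W_MG.astype(np.int64)
    W_MM = mg @ mg.T
    W_MC = mg @ state.W_GC.astype(np.int64)
    if diag_zeroed:
        W_MM = W_MM.copy()
        np.fill_diagonal(W_MM, 0)
    return EffectiveConnectivity(W_MM=W_MM, W_MC=W_MC, diag_zeroed=diag_zeroed)


def _fisher_terms(M1: np.ndarray, M2: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    M1 = rectify(M1)
    M2 = rectify(M2)
    if M1.shape != M2.shape:
        raise ValueError("patterns must have equal length")
    s = M1 + M2
    keep = s > 0
    return (M1 - M2)[keep], s[keep]


def fisher_opt(M1: np.ndarray, M2: np.ndarray) -> float:
    """Optimal Fisher discriminant of two MC patterns (rate-proportional noise)."""
    d, s = _fisher_terms(M1, M2)
    if d.size == 0:
        return 0.0
    return float(np.sum(d * d / s))


def fisher_nonopt(
    M1: np.ndarray,
    M2: np.ndarray,
    n_readouts: int = 5000,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Mean Fisher discriminant over random uniform(-1,1) read-out weights."""
    if n_readouts < 1:
        raise ValueError("n_readouts must be >= 1")
    d, s = _fisher_terms(M1, M2)
    if d.size == 0:
        return 0.0
    rng = rng or np.random.default_rng()
    w = rng.uniform(-1.0, 1.0, size=(n_readouts, d.size))
    num = (w @ d) ** 2
    den = (w * w) @ s
    return float(np.mean(num / den))


def pattern_correlation(a: np.ndarray, b: np.ndarray,
                        rectified: bool = True) -> float:
    """Pearson correlation of two activity patterns.

    By default patterns are rectified first (what downstream neurons see).
    ``rectified=False`` correlates the raw rate variables; this is needed for
    context-evoked MC patterns, which lie almost entirely below threshold —
    the 'negative odor' — and would otherwise be constant zero.
    """
    if rectified:
        a = rectify(a)
        b = rectify(b)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("patterns must have equal length")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("pattern_correlation needs nonzero variance in both patterns")
    return float(np.corrcoef(a, b)[0, 1])


def odor_mc_sets(odors: Dict[str, np.ndarray],
                 frac_of_max: float = 0.5) -> Dict[str, np.ndarray]:
    """Disjoint per-odor MC index sets.

    An MC belongs to the odor that drives it hardest, provided that drive
    exceeds ``frac_of_max`` of the odor's peak; ties and sub-threshold MCs are
    left unassigned.  Disjointness is required by the selectivity score.
    """
    names = list(odors)
    S = np.column_stack([odors[n] for n in names])
    best = S.argmax(axis=1)
    peak = S.max(axis=0)
    ok = S[np.arange(S.shape[0]), best] >= frac_of_max * peak[best]
    return {n: np.nonzero(ok & (best == k))[0] for k, n in enumerate(names)}


def connectivity_selectivity(
    W: np.ndarray,
    row_sets: Dict[str, np.ndarray],
    col_sets: Dict[str, np.ndarray],
) -> float:
    """Block-structure score of an effective connectivity matrix, in [-1, 1].

    Mean over odors of (within - between)/(within + between), where "within"
    averages the entries linking an odor's rows to its own columns and
    "between" averages entries linking them to the other odors' columns.
    Structureless (constant) matrices score 0; a block-diagonal matrix aligned
    with the sets scores 1.
    """
    if set(row_sets) != set(col_sets):
        raise ValueError("row and column sets must cover the same odors")
    scores = []
    for name, rows in row_sets.items():
        if len(rows) == 0 or len(col_sets[name]) == 0:
            raise ValueError(f"odor {name!r} has an empty index set")
        within = W[np.ix_(rows, col_sets[name])].mean()
        others = [W[np.ix_(rows, col_sets[o])].mean()
                  for o in col_sets if o != name]
        between = float(np.mean(others))
        tot = within + between
        scores.append(0.0 if tot == 0 else (within - between) / tot)
    return float(np.mean(scores))


def shuffle_gc_wiring(state: NetworkState, rng: np.random.Generator,
                      side: str = "cc") -> NetworkState:
    """GC-shuffled null model for structure statistics.

    ``side="cc"`` permutes the rows of ``W_GC`` among GCs, decoupling each
    GC's cortical partners from its bulbar partners while preserving both
    marginal wiring patterns — the null for top-down selectivity and
    receptive-field matching.  ``side="mc"`` redraws every GC's MC partner
    set uniformly (degree-preserving) — the null for intra-bulbar
    selectivity, which a mere GC permutation would leave unchanged.
    """
    out = state.copy()
    n_g = state.N_G
    if side == "cc":
        out.W_GC = state.W_GC[rng.permutation(n_g), :]
    elif side == "mc":
        deg = int(state.W_MG[:, 0].sum()) if n_g else 0
        n_mc = state.W_MG.shape[0]
        W = np.zeros_like(state.W_MG)
        for k in range(n_g):
            W[rng.choice(n_mc, deg, replace=False), k] = 1
        out.W_MG = W
    else:
        raise ValueError("side must be 'cc' or 'mc'")
    return out


def receptive_field_matching(
    state: NetworkState,
    M_responses: np.ndarray,
    C_outputs: np.ndarray,
) -> np.ndarray:
    """Per-GC correlation between MC-side and CC-side odor response profiles.

    ``M_responses`` (N_MC x N_s) are steady-state MC rates and ``C_outputs``
    (N_CC x N_s) steady-state CC outputs sigma(C) for the N_s training odors.
    For each GC the MC-side profile is the summed rectified activity of its MC
    partners per odor, and the CC-side profile the summed output of its CC
    partners; returns the Pearson correlation of the two profiles per GC (NaN
    for GCs with a constant profile).  A positive mean against a GC-shuffled
    null is the receptive-field matching signature.
    """
    mc_prof = state.W_MG.T.astype(float) @ rectify(M_responses)   # (N_G, N_s)
    cc_prof = state.W_GC.astype(float) @ np.asarray(C_outputs, dtype=float)
    a = mc_prof - mc_prof.mean(axis=1, keepdims=True)
    b = cc_prof - cc_prof.mean(axis=1, keepdims=True)
    denom = np.sqrt((a * a).sum(axis=1) * (b * b).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (a * b).sum(axis=1) / denom
    r[denom == 0] = np.nan
    return r
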