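"""Seeded experiment protocols.

Each protocol builds a scene, learns the cortical weights, evolves the bulb
by neurogenesis to a statistically steady wiring, and then probes the network
under controlled conditions (context present / absent / incorrect, or with the
top-down input blocked by setting w_GC = 0 at probe time only).  Because the
wiring keeps fluctuating through GC turnover, probe statistics are reported as
mean +/- SD over a trailing window of network snapshots taken while evolution
continues.

Protocols
---------
``run_development``       cortex training + neurogenic evolution for any scene
``run_extinction_protocol`` erase one odor pair's cortical memory mid-run
``run_context_recall``    odorless recall: context-evoked vs odor-evoked patterns
``run_occluder_task``     detect a weak target under a strong familiar occluder
``run_distractor_task``   discriminate novel targets next to a familiar distractor
``run_task_switch``       retrain cortex on a mixture to re-purpose the network
``run_wgc_sweep``         connectivity and performance vs top-down weight
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .analysis import (
    connectivity_selectivity,
    effective_connectivity,
    fisher_nonopt,
    fisher_opt,
    odor_mc_sets,
    pattern_correlation,
    receptive_field_matching,
    shuffle_gc_wiring,
)
from .cortical_plasticity import (
    PlasticityConfig,
    extinguish_memory,
    responsive_cc_set,
    train_cortex,
)
from .dynamics import steady_states_batch
from .model_core import (
    Environment,
    ModelParams,
    NetworkState,
    Stimulus,
    cc_sigmoid,
    initial_state,
    save_state,
)
from .neurogenesis import (
    EvolutionRecord,
    NeurogenesisFlags,
    evolve,
    neurogenesis_step,
)
from .stimuli import Scene, build_scene

__all__ = ["ExperimentConfig", "Development", "run_development", "run_probe",
           "structure_statistics",
           "run_extinction_protocol", "run_context_recall", "run_occluder_task",
           "run_distractor_task", "run_task_switch", "run_wgc_sweep",
           "burn_in_step", "condition_probe", "probe_patterns"]

# printed per-figure GC scales, used behind the --full switch
FULL_SCALE = {"two_odors": 2000, "extinction_4odors": 2000, "occluder": 2000,
              "distractor": 2000, "context_recall": 4000, "mixtures": 16000}


@dataclass
class ExperimentConfig:
    """Scene, scale and seed of one experiment run."""

    scene: str = "two_odors"
    seed: Optional[int] = None
    n_steps: int = 400
    snapshot_window: int = 20      # trailing snapshots for probe error bars
    n_replicates: int = 5
    full: bool = False             # use the printed (large) GC scales
    params_overrides: dict = field(default_factory=dict)
    scene_overrides: dict = field(default_factory=dict)
    plasticity: PlasticityConfig = field(default_factory=PlasticityConfig)
    outdir: Optional[Path] = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("an explicit seed is required for reproducibility")

    def make_params(self) -> ModelParams:
        over = dict(self.params_overrides)
        if self.full and "N_GC_aim" not in over:
            over["N_GC_aim"] = FULL_SCALE.get(self.scene, 2000)
        return ModelParams(seed=self.seed, **over)


@dataclass
class Development:
    """A developed network: trained cortex plus neurogenically evolved bulb."""

    cfg: ExperimentConfig
    params: ModelParams
    scene: Scene
    state: NetworkState
    record: EvolutionRecord
    rng: np.random.Generator     # continues the run's random stream


def burn_in_step(record: EvolutionRecord, params: ModelParams,
                 window: int = 20) -> Optional[int]:
    """First step after which the trailing-window mean of N_G stays inside the
    homeostatic band for ``window`` consecutive steps; None if never."""
    ng = np.array([r["N_G"] for r in record.rows], dtype=float)
    lo = params.N_GC_aim * (1 - params.g_band)
    hi = params.N_GC_aim * (1 + params.g_band)
    run = 0
    for t in range(window - 1, len(ng)):
        mean = ng[t - window + 1: t + 1].mean()
        if lo <= mean <= hi:
            run += 1
            if run >= window:
                return t
        else:
            run = 0
    return None


def run_development(cfg: ExperimentConfig) -> Development:
    """Build the scene, train the cortex, evolve the bulb to steady turnover."""
    params = cfg.make_params()
    scene = build_scene(cfg.scene, params, **cfg.scene_overrides)
    rng = np.random.default_rng(cfg.seed)
    state = initial_state(params)
    state = train_cortex(scene.env, state, params, cfg.plasticity)
    record = EvolutionRecord()
    if cfg.n_steps > 0:
        state, record = evolve(state, scene.env, params, cfg.n_steps, rng)
    dev = Development(cfg, params, scene, state, record, rng)
    if cfg.outdir is not None:
        _persist(dev)
    return dev


def _persist(dev: Development) -> None:
    out = Path(dev.cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    echo = dataclasses.asdict(dev.cfg)
    echo["outdir"] = str(echo["outdir"])
    (out / "config.json").write_text(json.dumps(echo, indent=2, default=str))
    dev.record.to_dataframe().to_csv(out / "evolution.csv", index=False)
    save_state(dev.state, out / "state.npz")
    eff = effective_connectivity(dev.state, diag_zeroed=True)
    np.savetxt(out / "W_MM.csv", eff.W_MM, fmt="%d", delimiter=",")
    np.savetxt(out / "W_MC.csv", eff.W_MC, fmt="%d", delimiter=",")


# ---------------------------------------------------------------------------
# probing

def condition_probe(stim: Stimulus, condition: str, info: dict) -> Tuple[Stimulus, bool]:
    """Attach a probe condition to a stimulus.

    Conditions: ``none`` (no context), ``correct`` / ``incorrect`` (the scene's
    trained contexts), ``blocked`` (no context, top-down weight zeroed at
    probe time).  Returns (stimulus, blocked_flag).
    """
    if condition == "none":
        return Stimulus(stim.S, context_id=None, name=stim.name), False
    if condition == "blocked":
        return Stimulus(stim.S, context_id=None, name=stim.name), True
    if condition in ("correct", "incorrect"):
        ctx = info[f"{condition}_context"]
        return Stimulus(stim.S, context_id=ctx, A_context=stim.A_context,
                        name=stim.name), False
    raise ValueError(f"unknown probe condition {condition!r}")


def probe_patterns(
    state: NetworkState,
    params: ModelParams,
    probes: Dict[str, Tuple[Stimulus, bool]],
) -> Dict[str, dict]:
    """Steady-state M/G/sigma(C) patterns for a set of conditioned probes."""
    out: Dict[str, dict] = {}
    for blocked in (False, True):
        keys = [k for k, (_, b) in probes.items() if b == blocked]
        if not keys:
            continue
        stims = [probes[k][0] for k in keys]
        M, G, C = steady_states_batch(
            stims, state, params, alpha=params.alpha_recall,
            w_gc=0.0 if blocked else params.w_GC,
        )
        for j, k in enumerate(keys):
            out[k] = {"M": M[:, j], "G": G[:, j],
                      "sigC": cc_sigmoid(C[:, j], params)}
    return out


def _snapshot_probe_patterns(
    dev: Development,
    probes: Dict[str, Tuple[Stimulus, bool]],
    n_snapshots: int,
    flags: Optional[NeurogenesisFlags] = None,
) -> List[Dict[str, dict]]:
    """Continue evolution; after each of ``n_snapshots`` steps probe the network."""
    snaps = []
    for _ in range(n_snapshots):
        dev.state, _ = neurogenesis_step(dev.state, dev.scene.env, dev.params,
                                         dev.rng, flags)
        snaps.append(probe_patterns(dev.state, dev.params, probes))
    return snaps


def run_probe(
    dev: Development,
    probe_a: str,
    probe_b: str,
    condition: str = "none",
    n_snapshots: Optional[int] = None,
    n_readouts: int = 5000,
) -> dict:
    """Discriminability statistics for a pair of probe scenes under a condition.

    Returns mean +/- SD of F_opt and F_nonopt over a trailing window of
    network snapshots, plus the Pearson correlation of the two MC patterns at
    the last snapshot.
    """
    n_snapshots = n_snapshots or dev.cfg.snapshot_window
    pa = condition_probe(dev.scene.probes[probe_a], condition, dev.scene.info)
    pb = condition_probe(dev.scene.probes[probe_b], condition, dev.scene.info)
    snaps = _snapshot_probe_patterns(dev, {"a": pa, "b": pb}, n_snapshots)
    rng = np.random.default_rng(dev.rng.integers(2**31))
    fo = [fisher_opt(s["a"]["M"], s["b"]["M"]) for s in snaps]
    fn = [fisher_nonopt(s["a"]["M"], s["b"]["M"], n_readouts, rng) for s in snaps]
    last = snaps[-1]
    return {
        "scene": dev.scene.name, "condition": condition,
        "probe_a": probe_a, "probe_b": probe_b,
        "F_opt": float(np.mean(fo)), "F_opt_sd": float(np.std(fo)),
        "F_nonopt": float(np.mean(fn)), "F_nonopt_sd": float(np.std(fn)),
        "r": pattern_correlation(last["a"]["M"], last["b"]["M"]),
    }


def _paired_fisher_table(
    dev: Development,
    pairs: Dict[str, Tuple[str, str]],
    conditions: Sequence[str],
    n_snapshots: int,
    n_readouts: int = 5000,
) -> pd.DataFrame:
    """F statistics for several probe pairs x conditions on shared snapshots."""
    probes: Dict[str, Tuple[Stimulus, bool]] = {}
    for cond in conditions:
        for label, (a, b) in pairs.items():
            for p in (a, b):
                probes[f"{cond}|{p}"] = condition_probe(
                    dev.scene.probes[p], cond, dev.scene.info)
    snaps = _snapshot_probe_patterns(dev, probes, n_snapshots)
    rng = np.random.default_rng(dev.rng.integers(2**31))
    rows = []
    for cond in conditions:
        for label, (a, b) in pairs.items():
            fo, fn = [], []
            for s in snaps:
                Ma, Mb = s[f"{cond}|{a}"]["M"], s[f"{cond}|{b}"]["M"]
                fo.append(fisher_opt(Ma, Mb))
                fn.append(fisher_nonopt(Ma, Mb, n_readouts, rng))
            rows.append({"pair": label, "condition": cond,
                         "F_opt": float(np.mean(fo)), "F_opt_sd": float(np.std(fo)),
                         "F_nonopt": float(np.mean(fn)),
                         "F_nonopt_sd": float(np.std(fn))})
    return pd.DataFrame(rows)


def structure_statistics(dev: Development, n_shuffles: int = 100,
                         rng: Optional[np.random.Generator] = None) -> dict:
    """Learned-structure scores of a developed network against shuffled nulls.

    Computes the block selectivity of the intra-bulbar (W_MM, diagonal
    zeroed) and top-down (W_MC) effective inhibition with respect to the
    training odors, and the mean per-GC receptive-field matching (correlation
    between MC-side and CC-side odor response profiles).  Nulls: W_MM against
    degree-preserving redraws of each GC's MC partners; W_MC and matching
    against permutations of the GC identity on the cortical side.  Returns
    observed values, null samples, and one-sided empirical p-values.
    """
    rng = rng or np.random.default_rng(dev.cfg.seed + 777)
    state, params, scene = dev.state, dev.params, dev.scene
    mc_sets = odor_mc_sets(scene.odors)
    cc_sets = {n: s.copy() for n, s in mc_sets.items()}  # identity W_CM
    eff = effective_connectivity(state, diag_zeroed=True)
    odors = [Stimulus(s, name=n) for n, s in scene.odors.items()]
    M, _, C = steady_states_batch(odors, state, params)
    sigC = cc_sigmoid(C, params)

    obs = {
        "sel_W_MM": connectivity_selectivity(eff.W_MM, mc_sets, mc_sets),
        "sel_W_MC": connectivity_selectivity(eff.W_MC, mc_sets, cc_sets),
        "rf_matching": float(np.nanmean(
            receptive_field_matching(state, M, sigC))),
    }
    nulls: Dict[str, list] = {k: [] for k in obs}
    for _ in range(n_shuffles):
        sh_mc = shuffle_gc_wiring(state, rng, side="mc")
        nulls["sel_W_MM"].append(connectivity_selectivity(
            effective_connectivity(sh_mc, diag_zeroed=True).W_MM,
            mc_sets, mc_sets))
        sh_cc = shuffle_gc_wiring(state, rng, side="cc")
        nulls["sel_W_MC"].append(connectivity_selectivity(
            effective_connectivity(sh_cc, diag_zeroed=True).W_MC,
            mc_sets, cc_sets))
        nulls["rf_matching"].append(float(np.nanmean(
            receptive_field_matching(sh_cc, M, sigC))))
    out = dict(obs)
    for k in obs:
        null = np.asarray(nulls[k])
        out[f"{k}_null_mean"] = float(null.mean())
        out[f"{k}_null"] = null
        out[f"{k}_p"] = float((1 + (null >= obs[k]).sum()) / (1 + n_shuffles))
    return out


# ---------------------------------------------------------------------------
# figure-level protocols

def run_occluder_task(cfg: ExperimentConfig) -> pd.DataFrame:
    """Detection of a weak target with/without a strong familiar occluder.

    Detection is the discrimination of the scene with the target from the same
    scene without it, under each probe condition.  The correct context (the
    one associated with the occluder) helps when the occluder is present and
    hurts when it is absent.
    """
    dev = run_development(dataclasses.replace(cfg, scene="occluder"))
    pairs = {"occluder": ("occluder+target", "occluder"),
             "no_occluder": ("target", "blank")}
    return _paired_fisher_table(dev, pairs, ("correct", "none", "blocked"),
                                cfg.snapshot_window)


def run_distractor_task(cfg: ExperimentConfig) -> pd.DataFrame:
    """Random-readout discrimination of two novel targets beside a familiar
    distractor, under correct / no / incorrect / blocked context."""
    dev = run_development(dataclasses.replace(cfg, scene="distractor"))
    pairs = {"targets": ("distractor+target_a", "distractor+target_b")}
    return _paired_fisher_table(
        dev, pairs, ("correct", "none", "incorrect", "blocked"),
        cfg.snapshot_window)


def run_extinction_protocol(cfg: ExperimentConfig, pre_window: int = 30,
                            post_window: int = 60) -> dict:
    """Erase the cortical memory of odor pair (O1, O2) and track the fallout.

    Protocol: develop on the four-odor scene, freeze the inhibition
    controller, record a pre-extinction window, zero the associative weights
    among the CCs responsive to O1/O2, then continue evolving.  Both the
    normal run and the apoptosis-blocked control branch from the same
    developed network.  Reports the GC-count trajectory, the mean pre-removal
    response of removed GCs to the extinguished (O1) vs spared (O3) odor
    after extinction, and F_opt for both odor pairs before vs after.
    """
    dev = run_development(dataclasses.replace(cfg, scene="extinction_4odors"))
    params, scene = dev.params, dev.scene
    flags = NeurogenesisFlags(freeze_g=True)

    pairs = {"extinguished": ("O1", "O2"), "spared": ("O3", "O4")}
    probes = {p: condition_probe(scene.probes[p], "none", scene.info)
              for p in ("O1", "O2", "O3", "O4")}

    def pair_fopt(snaps):
        out = {}
        for label, (a, b) in pairs.items():
            fo = [fisher_opt(s[a]["M"], s[b]["M"]) for s in snaps]
            out[f"F_opt_{label}"] = float(np.mean(fo))
            out[f"F_opt_{label}_sd"] = float(np.std(fo))
        return out

    before = pair_fopt(_snapshot_probe_patterns(dev, probes, pre_window, flags))
    ng_before = dev.state.N_G

    # the CCs carrying the memory of the extinguished pair
    cc_set = set()
    for nm in pairs["extinguished"]:
        cc_set |= responsive_cc_set(dev.state, scene.probes[nm], params,
                                    threshold=0.5 * params.C_max)
    extinguished = extinguish_memory(dev.state, cc_set)

    def post_phase(state0: NetworkState, rng: np.random.Generator,
                   apoptosis_blocked: bool) -> dict:
        # the blockade control arrests turnover entirely (no removal and no
        # addition), isolating the cortical-weight change from any structural
        # change; removal-only blockade would let the population grow without
        # bound and confound the comparison
        ph_flags = NeurogenesisFlags(freeze_g=True,
                                     apoptosis_blocked=apoptosis_blocked,
                                     block_addition=apoptosis_blocked)
        state = state0.copy()
        removed_resp = {"O1": [], "O3": []}
        ng, snaps = [], []
        for _ in range(post_window):
            state, row = neurogenesis_step(state, scene.env, params, rng,
                                           ph_flags)
            ng.append(row["N_G"])
            for nm in removed_resp:
                removed_resp[nm].append(row.get(f"removed_resp_{nm}",
                                                float("nan")))
            snaps.append(probe_patterns(state, params, probes))
        out = pair_fopt(snaps)
        out.update(
            apoptosis_blocked=apoptosis_blocked,
            N_G_after=int(ng[-1]),
            N_G_trajectory=np.array(ng),
            removed_resp_extinguished=(
                float(np.nanmean(removed_resp["O1"]))
                if np.any(np.isfinite(removed_resp["O1"])) else float("nan")),
            removed_resp_spared=(
                float(np.nanmean(removed_resp["O3"]))
                if np.any(np.isfinite(removed_resp["O3"])) else float("nan")),
        )
        return out

    rng_normal, rng_blocked = dev.rng.spawn(2)
    return {
        "params": params,
        "N_G_before": int(ng_before),
        "before": before,
        "extinguished_cc_count": len(cc_set),
        "normal": post_phase(extinguished, rng_normal, False),
        "blocked": post_phase(extinguished, rng_blocked, True),
    }


def run_context_recall(cfg: ExperimentConfig) -> dict:
    """Probe each context alone and each odor alone after paired training.

    Returns 2x2 matrices r[context, odor] of Pearson correlations between the
    context-evoked and odor-evoked patterns, for GC and for MC activities.
    Matching context/odor GC patterns should be strongly positively
    correlated; matching MC patterns anti-correlated (the context acts as a
    'negative' odor on the bulb).
    """
    dev = run_development(dataclasses.replace(cfg, scene="context_recall"))
    probes = {k: (dev.scene.probes[k], False)
              for k in ("O1", "O2", "ctx1", "ctx2")}
    pat = probe_patterns(dev.state, dev.params, probes)
    gc = np.zeros((2, 2))
    mc = np.zeros((2, 2))
    for i, ctx in enumerate(("ctx1", "ctx2")):
        for j, od in enumerate(("O1", "O2")):
            gc[i, j] = pattern_correlation(pat[ctx]["G"], pat[od]["G"])
            # raw M: context pushes MCs below threshold (a 'negative odor'),
            # so the anti-correlation lives in the unrectified variable
            mc[i, j] = pattern_correlation(pat[ctx]["M"], pat[od]["M"],
                                           rectified=False)
    return {"gc": gc, "mc": mc, "patterns": pat, "dev": dev}


def run_task_switch(cfg: ExperimentConfig, brief_epochs: int = 5) -> dict:
    """Mixture discrimination before vs after brief cortical retraining.

    Develops on the two-pair mixtures scene (cortex trained on the four
    components), measures F_opt(M1 vs M2) over a snapshot window, then
    retrains only the cortical weights on the 0.5/0.5 mixture and re-measures
    on the same bulbar snapshots (the bulb is frozen during retraining, so the
    comparison is paired).
    """
    dev = run_development(dataclasses.replace(cfg, scene="mixtures"))
    params, scene = dev.params, dev.scene

    # bulbar snapshots shared by both cortical configurations
    states: List[NetworkState] = []
    for _ in range(cfg.snapshot_window):
        dev.state, _ = neurogenesis_step(dev.state, scene.env, params, dev.rng)
        states.append(dev.state.copy())

    retrain_env = Environment([scene.probes["mix_half"]])
    # Cortical traces are formed from the afferent odor representation, as
    # in the initial training (which runs before any GCs exist): the mixture
    # is solved on a bulb without GC inhibition, so the Hebbian rule sees
    # supra-threshold CC activity and can associate the two components.
    # Recall is then probed through the developed, inhibiting bulb.
    afferent = states[-1].copy()
    afferent.W_MG = np.zeros((params.N_MC, 0), dtype=np.int8)
    afferent.W_GC = np.zeros((0, params.N_CC), dtype=np.int8)
    afferent.G = np.zeros(0)

    def mixture_fopt(W_CC: np.ndarray) -> List[float]:
        vals = []
        for st in states:
            probe_state = st.copy()
            probe_state.W_CC = W_CC
            pat = probe_patterns(probe_state, params,
                                 {"M1": (scene.probes["M1"], False),
                                  "M2": (scene.probes["M2"], False)})
            vals.append(fisher_opt(pat["M1"]["M"], pat["M2"]["M"]))
        return vals

    before = mixture_fopt(states[-1].W_CC)
    mixture_trained = train_cortex(
        retrain_env, afferent, params, PlasticityConfig(n_epochs=brief_epochs))
    after = mixture_fopt(mixture_trained.W_CC)
    return {
        "F_opt_before": float(np.mean(before)),
        "F_opt_before_sd": float(np.std(before)),
        "F_opt_after": float(np.mean(after)),
        "F_opt_after_sd": float(np.std(after)),
        "per_snapshot_before": before,
        "per_snapshot_after": after,
        "dev": dev,
        "W_CC_mixture": mixture_trained.W_CC,
    }


def run_wgc_sweep(
    cfg: ExperimentConfig,
    values: Sequence[float] = (0.25, 1.0, 2.0, 3.0, 6.0),
    n_seeds: int = 3,
) -> pd.DataFrame:
    """Develop the distractor scene at each top-down weight and score it.

    Per (w_GC, seed): selectivity of the intra-bulbar (W_MM, diagonal zeroed)
    and top-down (W_MC) effective inhibition with respect to the four training
    odors, and F_nonopt for the target discrimination under each context
    condition.  Selective structure needs an intermediate w_GC.
    """
    rows = []
    for v in values:
        for k in range(n_seeds):
            sub = dataclasses.replace(
                cfg, scene="distractor", seed=cfg.seed + 1000 * k,
                params_overrides={**cfg.params_overrides, "w_GC": float(v)},
            )
            dev = run_development(sub)
            mc_sets = odor_mc_sets(dev.scene.odors)
            cc_sets = {n: s.copy() for n, s in mc_sets.items()}  # identity W_CM
            eff = effective_connectivity(dev.state, diag_zeroed=True)
            row = {
                "w_GC": float(v), "seed": sub.seed,
                "sel_W_MM": connectivity_selectivity(eff.W_MM, mc_sets, mc_sets),
                "sel_W_MC": connectivity_selectivity(eff.W_MC, mc_sets, cc_sets),
                "N_G": dev.state.N_G, "g": dev.state.g,
            }
            tab = _paired_fisher_table(
                dev, {"targets": ("distractor+target_a", "distractor+target_b")},
                ("correct", "none", "incorrect", "blocked"),
                n_snapshots=max(5, cfg.snapshot_window // 2))
            for _, r in tab.iterrows():
                row[f"F_nonopt_{r['condition']}"] = r["F_nonopt"]
            rows.append(row)
    return pd.DataFrame(rows)
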