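"""Odor, context and probe scenes.

Odors are sums of Gaussian activity profiles over the MC index,
``S_i = sum_k A_k exp(-(i - x_k)^2 / w_k^2)``, with the MC index treated as a
continuous 1-based coordinate.  Training odors use amplitude ``A = 2 - M_sp``
and width ``w = 12``; contexts drive their block of contextual CCs with a
constant amplitude ``A_context = 2``.  Scene presets assemble the training
environments and probe stimuli of the standard experiments: structure
learning, memory extinction, context recall, occluded/distracted detection
and discrimination, and mixture task switching.  Only widths and amplitudes
are canonical; peak centers default to evenly spaced positions with the
overlap structure each experiment requires (similar odors offset by half a
width, dissimilar ones by far more than a width) and are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from .model_core import Environment, ModelParams, Stimulus

__all__ = ["GaussianPeak", "Scene", "gaussian_stimulus", "mixture",
           "build_scene", "SCENE_NAMES", "stimulus_to_csv"]

TRAIN_WIDTH = 12.0
A_CONTEXT = 2.0


@dataclass
class GaussianPeak:
    """One Gaussian component of an odor: amplitude, center (MC index), width."""

    A: float
    x: float
    w: float

    def __post_init__(self) -> None:
        if self.A < 0:
            raise ValueError("amplitude must be nonnegative")
        if self.w <= 0:
            raise ValueError("width must be positive")


def gaussian_stimulus(peaks: List[GaussianPeak], N_MC: int) -> np.ndarray:
    """Evaluate a sum of Gaussian profiles on the 1-based MC grid."""
    if N_MC < 1:
        raise ValueError("N_MC must be >= 1")
    i = np.arange(1, N_MC + 1, dtype=float)
    S = np.zeros(N_MC)
    for p in peaks:
        S += p.A * np.exp(-((i - p.x) ** 2) / p.w**2)
    return S


def mixture(S_a: np.ndarray, S_b: np.ndarray, c_a: float, c_b: float) -> np.ndarray:
    """Linear odor mixture c_a*S_a + c_b*S_b."""
    S_a = np.asarray(S_a, dtype=float)
    S_b = np.asarray(S_b, dtype=float)
    if S_a.shape != S_b.shape:
        raise ValueError("mixture components must have equal length")
    return c_a * S_a + c_b * S_b


def stimulus_to_csv(S: np.ndarray, path) -> None:
    """Write an odor drive as CSV rows (1-based MC index, rate) for plotting."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["mc_index", "rate"])
        for i, r in enumerate(np.asarray(S, dtype=float), start=1):
            w.writerow([i, repr(float(r))])


@dataclass
class Scene:
    """A named experiment scene: training environment plus probe stimuli.

    ``odors`` maps odor names to their drive vectors; ``contexts`` maps odor
    names to context ids (None if the odor was trained without context);
    ``info`` carries scene-specific labels such as the correct/incorrect
    context for a cluttered-scene probe.
    """

    name: str
    env: Environment
    odors: Dict[str, np.ndarray]
    probes: Dict[str, Stimulus] = field(default_factory=dict)
    contexts: Dict[str, Optional[int]] = field(default_factory=dict)
    info: dict = field(default_factory=dict)


def _train_amp(params: ModelParams) -> float:
    return 2.0 - params.M_sp


def _odor(center: float, params: ModelParams, A: Optional[float] = None,
          w: float = TRAIN_WIDTH) -> np.ndarray:
    A = _train_amp(params) if A is None else A
    return gaussian_stimulus([GaussianPeak(A, center, w)], params.N_MC)


def _scene_from(name, params, centers, context_of, probes=None, info=None) -> Scene:
    odors = {f"O{k + 1}": _odor(c, params) for k, c in enumerate(centers)}
    contexts = {f"O{k + 1}": context_of[k] for k in range(len(centers))}
    env = Environment([
        Stimulus(S, context_id=contexts[nm], A_context=A_CONTEXT, name=nm)
        for nm, S in odors.items()
    ])
    return Scene(name=name, env=env, odors=odors, probes=probes or {},
                 contexts=contexts, info=info or {"centers": list(centers)})


def build_scene(name: str, params: ModelParams, **overrides) -> Scene:
    """Build a preset scene.

    Presets: ``two_odors``, ``extinction_4odors``, ``context_recall``,
    ``occluder``, ``distractor``, ``mixtures``.  Keyword overrides replace the
    documented default peak centers and probe parameters.
    """
    builders = {
        "two_odors": _two_odors,
        "extinction_4odors": _extinction_4odors,
        "context_recall": _context_recall,
        "occluder": _occluder,
        "distractor": _distractor,
        "mixtures": _mixtures,
        "custom": _custom,
    }
    if name not in builders:
        raise ValueError(f"unknown scene preset {name!r}; choose from {sorted(builders)}")
    return builders[name](params, **overrides)


SCENE_NAMES = ("two_odors", "extinction_4odors", "context_recall",
               "occluder", "distractor", "mixtures", "custom")


def _custom(params: ModelParams, centers=(35.0, 75.0), contexts=None,
            amplitudes=None, widths=None) -> Scene:
    """User-defined training odors: one Gaussian per center, optional
    per-odor context ids, amplitudes and widths."""
    n = len(centers)
    contexts = list(contexts) if contexts is not None else [None] * n
    amplitudes = list(amplitudes) if amplitudes is not None else [None] * n
    widths = list(widths) if widths is not None else [TRAIN_WIDTH] * n
    if not (len(contexts) == len(amplitudes) == len(widths) == n):
        raise ValueError("centers, contexts, amplitudes and widths must match")
    odors = {f"O{k + 1}": _odor(c, params, A=amplitudes[k], w=widths[k])
             for k, c in enumerate(centers)}
    ctx = {f"O{k + 1}": contexts[k] for k in range(n)}
    env = Environment([
        Stimulus(S, context_id=ctx[nm], A_context=A_CONTEXT, name=nm)
        for nm, S in odors.items()
    ])
    probes = {nm: Stimulus(S, name=nm) for nm, S in odors.items()}
    return Scene(name="custom", env=env, odors=odors, probes=probes,
                 contexts=ctx, info={"centers": list(centers)})


def _two_odors(params: ModelParams, centers=(35.0, 75.0)) -> Scene:
    """Two dissimilar odors, no contexts; the structure-learning scene."""
    sc = _scene_from("two_odors", params, centers, [None, None])
    sc.probes = {nm: Stimulus(S, name=nm) for nm, S in sc.odors.items()}
    return sc


def _extinction_4odors(params: ModelParams,
                       centers=(30.0, 36.0, 74.0, 80.0)) -> Scene:
    """Two similar pairs (O1,O2) and (O3,O4); pair 1 is the extinction target."""
    sc = _scene_from("extinction_4odors", params, centers, [None] * 4)
    sc.probes = {nm: Stimulus(S, name=nm) for nm, S in sc.odors.items()}
    sc.info.update(extinguish_pair=("O1", "O2"), spared_pair=("O3", "O4"))
    return sc


def _context_recall(params: ModelParams, centers=(35.0, 75.0)) -> Scene:
    """Each of two dissimilar odors associated with its own context."""
    sc = _scene_from("context_recall", params, centers, [0, 1])
    blank = np.zeros(params.N_MC)
    sc.probes = {
        "O1": Stimulus(sc.odors["O1"], name="O1"),
        "O2": Stimulus(sc.odors["O2"], name="O2"),
        "ctx1": Stimulus(blank, context_id=0, A_context=A_CONTEXT, name="ctx1"),
        "ctx2": Stimulus(blank, context_id=1, A_context=A_CONTEXT, name="ctx2"),
    }
    return sc


def _occluder(params: ModelParams, centers=(30.0, 36.0, 74.0, 80.0),
              target_center=35.0, target_A=0.72, target_w=2.0) -> Scene:
    """Weak narrow target occluded by familiar odor O1 (associated with context 1).

    Probe compositions: occluder alone, occluder+target, target alone and a
    blank scene, so detection can be scored with and without the occluder.
    """
    sc = _scene_from("occluder", params, centers, [0, 0, 1, 1])
    target = _odor(target_center, params, A=target_A, w=target_w)
    occ = sc.odors["O1"]
    sc.probes = {
        "occluder": Stimulus(occ, name="occluder"),
        "occluder+target": Stimulus(occ + target, name="occluder+target"),
        "target": Stimulus(target, name="target"),
        "blank": Stimulus(np.zeros(params.N_MC), name="blank"),
    }
    sc.info.update(correct_context=0, incorrect_context=1, occluder_odor="O1")
    return sc


def _distractor(params: ModelParams, centers=(30.0, 36.0, 74.0, 80.0),
                target_centers=(29.0, 35.0), target_A=1.08,
                target_w=TRAIN_WIDTH) -> Scene:
    """Two similar novel targets on top of familiar distractor O3 (context 2).

    The targets overlap the context-1 odors O1/O2 but not the distractor, so
    the correct context (2) suppresses only uninformative MC channels while
    the incorrect context (1) inhibits the target channels themselves.
    """
    sc = _scene_from("distractor", params, centers, [0, 0, 1, 1])
    t_a = _odor(target_centers[0], params, A=target_A, w=target_w)
    t_b = _odor(target_centers[1], params, A=target_A, w=target_w)
    dist = sc.odors["O3"]
    sc.probes = {
        "distractor+target_a": Stimulus(dist + t_a, name="distractor+target_a"),
        "distractor+target_b": Stimulus(dist + t_b, name="distractor+target_b"),
        "target_a": Stimulus(t_a, name="target_a"),
        "target_b": Stimulus(t_b, name="target_b"),
    }
    sc.info.update(correct_context=1, incorrect_context=0, distractor_odor="O3")
    return sc


def _mixtures(params: ModelParams, centers=(30.0, 36.0, 80.0, 86.0)) -> Scene:
    """Two similar pairs near MC 30 and MC 80; probes are cross-pair mixtures."""
    sc = _scene_from("mixtures", params, centers, [None] * 4)
    o1, o3 = sc.odors["O1"], sc.odors["O3"]
    sc.probes = {
        "M1": Stimulus(mixture(o1, o3, 0.55, 0.45), name="M1"),
        "M2": Stimulus(mixture(o1, o3, 0.45, 0.55), name="M2"),
        "mix_half": Stimulus(mixture(o1, o3, 0.5, 0.5), name="mix_half"),
        "O1": Stimulus(o1, name="O1"),
        "O2": Stimulus(sc.odors["O2"], name="O2"),
    }
    sc.info.update(mixture_components=("O1", "O3"))
    return sc
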