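# Model and methods

## The network

`neurobulb` simulates a firing-rate model of the olfactory bulb coupled
bidirectionally to an effective associative cortex.  Three populations
interact:

- **Mitral/tufted cells (MCs)**, the bulb's excitatory principal neurons.
  They receive the sensory odor drive `S`, a spontaneous drive `M_sp`, and
  reciprocal inhibition from granule cells.
- **Granule cells (GCs)**, axonless inhibitory interneurons.  Each GC forms
  reciprocal dendrodendritic synapses with `N_conn_MG` MCs — a single
  contact both excites the GC and inhibits that MC — and receives top-down
  excitation from `N_conn_GC` cortical cells with weight `w_GC`.  The GC
  population turns over by adult neurogenesis (below).
- **Cortical cells (CCs)**, an effective associative population.  A block of
  `N_CC_odor` cells receives bulbar input (one MC per CC by default, weight
  `w_CM`); `N_CC_context` further cells receive only non-olfactory,
  contextual drive.  CCs excite each other through a plastic recurrent
  matrix `W_CC` (Hebbian, hard-bounded at `W_max_CC`), inhibit each other
  all-to-all with strength `w_inh`, and project top-down onto the GCs.

Rates follow threshold-linear dynamics for MCs and GCs and a sigmoidal
nonlinearity `sigma(C) = C_max / (1 + exp(-gamma_C (C - C_th)))` for CCs.
MC inhibition is driven by the thresholded GC activity `[G - G_th]_+` with
strength `g`.  The GC time constant is set to zero, so GC rates are an
algebraic function of the MC and CC rates and only the MC and CC equations
are integrated.

## Steady states

Every quantity in the package is a property of network steady states.  The
solver integrates the reduced MC/CC system by explicit Euler from a fixed
initial condition (`M = M_sp`, `C` at the uniform cortical rest potential,
the fixed point of `c = -w_inh (N_CC-1) sigma(c)`), with initial step
`dt = 0.05 min(tau_M, tau_C)`.  The step is halved whenever the residual
fails to decrease over a 20-step window, which keeps the scheme stable when
the disynaptic inhibition loop gain is large; convergence is declared when
the largest right-hand side falls below `steady_tol = 1e-6` (in rate units
per unit time).  Failure to converge within `t_max = 1000` time units raises
an error — this is how a bistable (self-sustaining) cortex manifests, a
regime the model deliberately avoids.

The rest-potential initialization matters: starting the cortex at `C = 0`
would mean an initial output `sigma(0) ≈ 0.35` per cell — far above the
inhibited rest output (~0.08) — and the resulting top-down transient can tip
the bulb into a spuriously collapsed branch when the network is multistable
(context-alone probes are the sensitive case).  Starting from rest selects
the branch reachable from the resting network, which is the physically
meaningful one for a probe.

Because the fixed point is independent of presentation order (fixed initial
condition, no warm starts), probe results cannot leak between scenes.

## Hebbian cortical learning

`W_CC` is learned once, before any neurogenesis, by presenting each training
scene (odor plus its associated context, if any), relaxing to the steady
state at the reduced learning-phase recurrence `alpha_learn`, and applying

    W_ij <- clip(W_ij + eta [ (sigma_i - Omega) sigma_j - kappa ], 0, W_max_CC)

for `i != j`.  With the default rates (`eta = 10`, `kappa = 0.1`,
`W_max_CC = 0.06`) the rule is one-shot: a single decay increment
`eta kappa = 1` exceeds the weight bound by 16x.  The increments of all
scenes in an epoch are therefore accumulated before clipping; applying
scenes one at a time would erase every association not co-active in the
current scene and leave only the last-presented memory, making training
order-dependent.  Batch accumulation keeps all memories and is exactly
order-invariant.  Training stops after `n_epochs = 50` or when the largest
weight change in an epoch falls below `1e-4 W_max_CC` (typically after 2–3
epochs).  During the subsequent neurogenic evolution `W_CC` is frozen.

Cortical traces are always formed from the *afferent* odor representation.
The initial training runs before any GC exists, so the Hebbian rule sees
the raw drive `S + M_sp`.  The task-switch retraining keeps this
convention: the mixture scene is solved on a bulb without GC inhibition
when computing the steady states that drive the weight update, and recall
is then probed through the developed, inhibiting bulb (whose wiring the
retraining never touches).  This matters because in the developed network
the suppressed MC output holds CC activity near `sigma ≈ 0.26`, below the
potentiation threshold `sigma ≈ 0.54` implied by
`(sigma - Omega) sigma > kappa`; Hebbian learning applied to those states
can only erase.  Forming traces at afferent drive realizes the intended
mechanism — the mixture memory's cross-associations make the top-down
inhibition of each mixture component common to both probe mixtures,
preserving their difference.

## Adult neurogenesis

Each neurogenic step:

1. **Add** `N_new_G = round(0.1 N_GC_aim)` GCs, each wiring to `N_conn_MG`
   uniformly chosen MCs (reciprocally) and `N_conn_GC` uniformly chosen CCs.
2. **Evaluate**: solve the steady state for each training odor.  The
   resilience of GC i is its summed thresholded response,
   `R_i = sum_beta [G_i(beta) - G_th]_+`.  Survival evaluation presents the
   odors alone: contexts act during cortical learning and at probe time, not
   in the resilience sum.
3. **Select**: each GC survives the step independently with probability
   `P_i = (tanh(gamma_R (R_i - R_0)) + 1)/2`.  New GCs take part in the same
   step's evaluation and selection.
4. **Regulate**: the reciprocal inhibition strength `g` is nudged by ±1%
   (multiplicative) whenever the surviving count leaves a ±5% band around
   `N_GC_aim`; inside the band it is left alone.  Protocols can freeze `g`,
   block removal, or block addition at scheduled steps.

Iterating this loop drives the wiring to a statistically steady state in
which surviving GCs connect MCs and CCs with matched odor receptive fields:
a GC survives only if enough of its MC partners (and, through `w_GC`, its CC
partners) are co-activated by some training odor.  The effective disynaptic
matrices `W_MM = W_MG W_MG^T` and `W_MC = W_MG W_GC` then show per-odor
block structure — odor-specific lateral inhibition in the bulb and
odor-specific top-down inhibitory control by the cortex.

## Parameters

All printed model constants take their canonical values: `tau_M = tau_C = 1`
(time is measured in MC time constants), `M_sp = 0.2`, `G_th = 3`,
`w_GC = 3`, `alpha_learn = 0.05`, `alpha_recall = 1`, `gamma_C = 3`,
`C_th = 0.2`, `C_max = 1`, `w_inh = 0.05`, `Omega = 0.2`, `kappa = 0.1`,
`eta = 10`, `W_max_CC = 0.06`, `N_conn_MG = 16`, `N_conn_GC = 2`,
`N_CC_context = 48` (split as two contexts of 24 cells), `gamma_R = 5`,
`R_0 = 3`, `N_MC = 110`, and `N_CC_odor = N_MC` with an identity
bulb-to-cortex map.  One published symbol list prints the top-down fan-in as
"Nconn(GP)"; it is the same quantity as `N_conn_GC` (the text defines only
the latter).

Two parameters required choices of our own:

- **`w_CM = 1.25`** (MC→CC feedforward weight; no canonical value exists).
  It positions the cortex between two failure modes.  Well below 1 the
  learned recurrence barely moves `sigma` at recall on the developed
  (inhibited) bulb: no odorless context recall, no extinction targeting, no
  context benefit.  At 1.5–2 the sigmoid saturates under odor drive, leaving
  the context and the learned associations nothing to add, and the mixture
  retraining and distractor orderings invert.  At 1.25 all of the model's
  qualitative operating behaviors hold simultaneously.
- **`g_init = 0.02`**.  The ±1% controller is slow; its equilibrium at the
  working scale is `g ≈ 0.004–0.008`, and starting at `g = 1` spends ~600
  steps just traveling there.  The statistically steady state is set by the
  homeostatic band, not the starting point (verified by property test), so
  `g` starts near the working-scale equilibrium.

## Scales

The working scale is `N_GC_aim = 500` GCs with 400 neurogenic steps
(burn-in of the controller takes 90–170 steps; probe statistics use a
trailing window of ~20 snapshots, reported as mean ± SD over the ongoing
wiring fluctuations).  The published experiments use 2,000–16,000 GCs;
those scales are available via `ExperimentConfig(full=True)` or explicit
`N_GC_aim` overrides; spot runs of the extinction protocol at 2,000 GCs
and of development at 1,500 reproduce the working-scale behavior in kind.
The selection effects are statements about wiring statistics per GC, so
they carry over across scales; what grows with scale is the smoothness of
the effective connectivity matrices and the stability of
Fisher-discriminant estimates.

## Stimuli

Odors are sums of Gaussian profiles over the MC index (treated as a
continuous, 1-based coordinate), `S_i = sum_k A_k exp(-(i-x_k)^2/w_k^2)`,
with training amplitude `A = 2 - M_sp` and width `w = 12`; contexts drive
their 24 contextual CCs with constant amplitude 2.  Probe stimuli for the
cluttered-scene tasks use a weak narrow target (`A = 0.72`, `w = 2`) under
the occluder and a pair of similar wide targets (`A = 1.08`, `w = 12`)
beside the distractor.  Peak centers are free scene parameters: training
odors sit at evenly spaced centers with similar pairs offset by half a
width and dissimilar pairs separated by several widths; the occluder target
sits at MC 35, inside the occluder band.  All scenes are deterministic
given their configuration.

What the generator does *not* emulate: natural odor maps (real glomerular
response patterns are correlated and multi-peaked), concentration dynamics,
trial-to-trial input noise (rates are deterministic; the Fisher
discriminant uses the rate itself as the variance proxy, as for
Poisson-like spiking), and sniff-cycle temporal structure.  Passing tests
therefore demonstrate the network-level mechanisms — activity-dependent
survival, receptive-field matching, context-gated inhibition — not
quantitative performance on natural stimuli.

## Read-outs and statistics

Discriminability of two MC patterns uses the Fisher linear discriminant
with rate-proportional noise: optimal weights give
`F_opt = sum_i D_i^2 / (M1_i + M2_i)` with `D = [M1]_+ - [M2]_+`; the naive
read-out `F_nonopt` averages 5,000 random uniform(−1,1) weight vectors.
Channels silent in both patterns are dropped (0/0).  Pattern correlations
are Pearson correlations of rectified activities, except the context-evoked
MC patterns, which lie almost entirely below threshold (the context acts as
a "negative odor"); these are correlated unrectified, as the effect exists
only in the raw rate variable.

Structure is scored by a block-selectivity index: MCs are assigned to the
odor that drives them hardest (above half its peak), and the score is the
mean over odors of (within − between)/(within + between) of the effective
connectivity entries.  This index is a stand-in defined here, so only its
shape and ordering across conditions are interpreted, never its absolute
value.  Nulls are degree-preserving redraws of each GC's MC partners (for
`W_MM`) or permutations of GC identity on the cortical side (for `W_MC`
and receptive-field matching).

## Known limitations

- Memory extinction reproduces the structural signatures (GC loss
  concentrated on the extinguished odor's GCs; no loss when apoptosis is
  blocked) but not the published *drop* in `F_opt` for the extinguished
  pair: at these parameters the network operates in a deep-suppression
  regime (most MC channels below threshold), where losing inhibition is
  expressed asymmetrically through the rectifier and *raises* the
  discriminant, and ongoing neurogenesis rebuilds the pair-specific wiring
  from feedforward survival within tens of steps.  The corresponding
  acceptance test asserts the published direction and fails.
- The cortex is a single effective population: no feedforward inhibition,
  no layered structure, no separate read-out population.
- Only steady states are modeled: no oscillations, spike timing or
  synchrony.
- The blockade control in the extinction protocol arrests turnover
  entirely (addition and removal); blocking removal alone would grow the
  population without bound under a frozen controller and confound the
  comparison.
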