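# Methods

## The model

`hippoctx` implements a family of rate-coded neural network models of the
hippocampal circuit built around one hypothesis: the anatomical
differentiation of the hippocampus — posterior vs. anterior poles, superior
vs. inferior blades of the dentate gyrus (DG), distal vs. proximal subregions
of CA3 and CA1 — manages the flow of two qualitatively different input
streams, *object* information arriving through the lateral entorhinal cortex
(LEC) and *context* information arriving through the medial entorhinal cortex
(MEC).

Each side (posterior = object-dominated, anterior = context-dominated)
contains DG, CA3, and a distal/proximal pair of CA1 subregions.  Both EC
divisions project into both sides; the *crossconnections* (MEC into the
posterior side, LEC into the anterior side) carry per-region relative weight
multipliers that are the central experimental variable.  Mossy fibers
(DG→CA3) are modeled as ordinary dense projections with a 10× relative
weight, CA3 carries recurrent collaterals, and CA3-proximal projects to
CA1-distal and vice versa.  Each CA1 subregion drives one of four output
layers:

| output | meaning                         | side      | CA1 subregion |
|--------|---------------------------------|-----------|---------------|
| O      | object guess                    | posterior | distal        |
| OBCG   | object-based context guess      | posterior | proximal      |
| CBOG   | context-based object guess      | anterior  | distal        |
| C      | context guess                   | anterior  | proximal      |

Five variants share this plan.  `Baseline` has one DG and one CA3 per side
and a single compromise crossconnection multiplier (posterior 1.5).
`SplitDG` splits each DG into superior/inferior blades (half size each) so
the O-stream blade can take a strong context multiplier (3.0) while the
OBCG-stream blade takes one close to zero (0.05; kept slightly positive so
the projection exists and can be swept).  `AllSplit` additionally splits CA3,
with the inferior blade wired only to proximal CA3 and the superior blade
only to distal CA3.  `SplitDGplus` and `AllSplitplus` double the split DG
(and, for AllSplitplus, CA3) layers to compensate the per-stream capacity
lost by splitting.  The anterior-side LEC multiplier is a single shared
value for all variants, set by the calibration sweep described below: the
argmin of the averaged C/CBOG sample error lies at zero object input, so the
default is 0.05 (kept slightly positive, like the posterior OBCG-stream
multiplier, so the projections exist and can be swept).

## Dynamics and learning

Units are rate-coded in [0, 1].  Within-layer inhibition is k-winner-take-all
(kWTA): the threshold is the midpoint between the k-th and (k+1)-th largest
net inputs (ties broken deterministically toward lower indices), the k
winners fire at `logistic(gain * (drive - threshold))`, and all other units
are silenced.  Activity fractions are 25% for the EC input and output layers,
1.5% for DG, 2.3% for CA3, and 2.5% for CA1.

Net input to a layer sums over incoming projections; each projection
contributes its relative weight multiplier times the weighted sum of sender
activity, normalized by the sender layer's expected active count so that
multipliers are comparable across source layers of different sizes.

Settling is synchronous with damped updates: each cycle a free unit moves
`step_size` of the way toward its instantaneous kWTA-gated rate.  The
discontinuous winner selection combined with bidirectional projections can
sustain winner-set limit cycles, so exact convergence is not guaranteed; the
damping plus a fixed cycle budget (default 8 cycles, tolerance 1e-3) yields
stable, fully deterministic behavior in practice.  Inputs are hard-clamped in
both phases.

Learning is contrastive Hebbian (the GeneRec family): a *minus* phase settles
with only LEC/MEC clamped, a *plus* phase continues from that state with the
four target outputs also clamped, and every learnable projection is updated
by

    dw_ij = eps * [ (1-lam) * (x+_i y+_j  -  x-_i y-_j)
                    + lam * y+_j (x+_i - w_ij) ]

with soft weight bounding (positive changes scaled by `1-w`, negative by
`w`), which confines weights to [0, 1].  Each CA1 subregion and its output
layer are connected bidirectionally (independent weights per direction) so
that plus-phase target information reaches the hidden layers during settling;
deeper feedback (output into CA3/DG) is not wired.  Defaults: learning rate
0.05, Hebbian mix 0.01, gain 6.

These dynamics/learning parameters are this package's calibration — the
modeling lineage the architecture follows does not pin them down — and were
chosen so that the Baseline network reliably memorizes the training world
within the fixed 20-epoch schedule: the learning rate 0.05 was selected from
{0.01, 0.05, 0.1, 0.2} (0.01 fails to memorize in 20 epochs; 0.2 causes
visible interference at larger world sizes), and the cycle budget from
{8, 10, 15, 30} (training outcomes are indistinguishable, so the cheapest
budget that propagates activity through the four-hop circuit is used).

## The synthetic world

The training set is generated, not loaded: each object and each context is a
random 8×8 binary matrix with exactly 16 of its 64 units active; the default
world has 120 unique objects and 40 unique contexts, 3 objects per context,
all patterns pairwise distinct.  Training presents all matched object-context
pairs once per epoch in random order, with one weight update per
presentation, for 20 epochs; weights are then frozen.

Test batteries corrupt one input while presenting the other clean:

* **additive noise** — `round(level*16)` extra units switched on;
* **non-additive noise** — the same number of paired on/off swaps (active
  count preserved);
* **partial cue** — the level is a *completeness* fraction: `round(level*16)`
  of the original ones are retained (1.0 = intact, 0.0 = empty);
* **mismatch** — every object is presented with a deranged context (no
  object sees its trained context);
* **context-only recall** — the LEC input is clamped to all zeros (absence
  of a cue is represented as absence of activity).

Noise levels are fractions of the pattern's original active count (16), not
of all 64 units; the alternative basis is available for sensitivity checks.
Ground truth on a mismatch trial follows each output's definition: O and
OBCG are keyed to the object and its *trained* context, C and CBOG to the
*presented* context.  The CBOG target concatenates the presented context's
three objects in ascending object-id order, and its error averages the
per-slot miss fractions on that canonical ordering.

Recall error for an output layer is the fraction of target-active units
missed by a top-m readout of the minus-phase activation (m = the target's
active count).  The per-network *combined score* on a test is
`mean(O error, min(C error, OBCG error))` — the object output plus the best
context output.  An untrained network scores ≈ 0.75 on a 16-of-64 output
(the expected miss rate of a random k-of-n overlap), which is the chance
floor for these curves.

What the generator does **not** emulate: structured or correlated stimuli
(real objects in a context share features; these patterns are independent
uniform draws), graded familiarity, temporal/list-order structure, and
multi-context objects.  Passing tests therefore demonstrate the circuit-level
information-routing effects, not performance on naturalistic stimuli.

## Experiments and problem sizes

The calibration ("sample") tasks score each output on its intended working
conditions: O and C on mixed additive/non-additive noise at the 15% level in
both inputs plus 40%-complete cues in both inputs; OBCG on mismatch plus
30% noise or 40% completeness in the context input only; CBOG the same with
the object input degraded instead.  The crossconnection sweep trains networks
with a uniform multiplier on all crossconnections and plots per-output sample
errors against it; the per-output optima motivate the variant multiplier
tables above, and the anterior multiplier is the argmin of the averaged
C/CBOG curve, then frozen for all batteries.

Comparative batteries use noise levels {0, .1, .2, .3, .4, .5} and
completeness levels {1.0, .8, .6, .4, .2, 0}; directional claims are tested
as mean comparisons over replicate seeds with SEMs reported, never on single
seeds.

Two study configurations are provided.  `full_study()` is the published
configuration (120 objects / 40 contexts; DG 800, CA3 256, CA1 2×400 per
side); a single 20-epoch training run takes minutes on one CPU, so the
replication suite and the acceptance script use `reduced_study()`: 36
objects / 12 contexts (preserving the 3:1 object:context ratio and the
16-of-64 pattern geometry) with DG 400, CA3 128, CA1 2×200 per side (half
the published sizes, same activity fractions), 20 epochs, which trains in
seconds per seed.  All reported comparisons state the study they were run
at.

## Known limitations

* The learning engine is a desk-scale contrastive-Hebbian implementation,
  not the full Leabra stack (no XCAL, no pretrained EC→CA1 mapping — the
  latter is deliberately excluded by the modeled design).  Its object-stream
  capacity is limited: at `full_study()` sizes the context stream memorizes
  essentially completely within 20 epochs but the object stream does not,
  which is why the memorization checks are stated (and tested) at the
  reduced study.
* Because every CA1 subregion also receives a direct EC projection, output
  streams can partially bypass DG/CA3; the training-error cost of halving
  DG/CA3 by splitting is therefore weaker in this engine than in the
  original comparisons, and the split-penalty ordering is the least robust
  of the replicated effects.
* kWTA winner counts are integers: at strongly scaled-down layer sizes a
  split CA3 region can drop to a single winner, which distorts capacity
  comparisons.  The replication study sizes were chosen to avoid that floor
  for the Baseline/SplitDG layers; the AllSplit CA3 regions sit at the k=1
  floor at those sizes.
* Settling is not guaranteed to converge (limit cycles); results are
  deterministic but depend on the documented cycle budget.
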