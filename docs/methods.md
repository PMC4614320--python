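# Methods

`lesionlab` simulates how networks endure and recover from spatio-temporal
patterns of node destruction. Two deliberately different architectures are
implemented so that conclusions about damage *timing* do not hinge on one
model's details: a feed-forward three-layer network whose recovery is
Hebbian relearning, and a recurrent ring whose recovery is homeostatic
structural rewiring. The primary outcome in both is the **maximum amount of
disability (MAoD)**: the largest value of the model's disability measure
after damage onset. The headline phenomenon is that MAoD decreases with the
**inter-removal time (IRT)** — the same total injury inflicted slowly is
less disabling at its worst moment than the same injury inflicted at once.

## Three-layer model

Three rings of `N` binary nodes (input `I`, middle `M`, output `O`). Node
`j` of one layer feeds the inclusive modular neighbourhood
`j - n//2 … j + n//2` of the next, i.e. `n_eff = 2*(n//2) + 1` connections
per node (for the reference `n = 100` that is 101; the run metadata records
`n_effective`). Middle nodes fire stochastically,

    P(M_i = 1) = F(X_i) = 1 / (1 + exp(-beta (X_i - theta_ml))),
    X_i = sum_j W_im[i,j] I_j,

independently each step (Bernoulli draws); output nodes are deterministic
threshold units, `O_i = 1` iff `sum_j W_mo[i,j] M_j >= theta_output`, with a
tie at exactly the threshold counting as firing (a fixed convention;
results are insensitive for continuous weights). Disability is the Hamming
distance `H` between actual and desired output. While `H > 0`, every
connection is updated by the Hebbian-like rule

    dw = eta (a s_post s_pre - b s_post - c s_pre),

then clipped to `[w_min, w_max]`. With the default constants
`(a, b, c) = (1.5, 0.5, 0.5)` the rule is +eta/2 for coincident activity,
-eta/2 for one-sided activity, 0 otherwise. The input→middle update uses
the actual middle activity as the postsynaptic state; the middle→output
update clamps the postsynaptic state to the *desired* output bit (teacher
clamping). A pure unsupervised reading of the rule on actual output states
cannot steer the output toward a target — a wrongly firing output would
strengthen itself — so the clamped form is the minimal reading under which
"learning while a difference exists" converges. The update is gated
network-wide on total `H > 0`; layers update synchronously
input→middle→output once per step; exactly one input/desired pattern pair
(random binary, 50% active by default) is used per run.

### Parameters (reference set)

| name | default | meaning |
|---|---|---|
| `N` | 500 | nodes per ring |
| `n` | 100 | fan-out neighbourhood width (`n_eff = n + 1` for even n) |
| `theta_ml`, `theta_output` | 5.54 | firing thresholds |
| `beta` | 0.25 | middle-layer sigmoid noise amplitude (1/activation) |
| `a, b, c` | 1.5, 0.5, 0.5 | Hebb constants |
| `w_min, w_max` | 0.0, 10.3 | weight bounds (lower bound keeps units purely excitatory; upper bound is coupled to the firing threshold so one or two strong surviving afferents can still fire an output) |
| `eta0` | 0.01 | base learning rate |
| `H0`, `Hc` | 5, case-dependent | knee and cutoff of the modified learning-rate law |

The scaled preset (`ThreeLayerParams().scaled()`, N=100, n=20) keeps all
per-connection arithmetic identical and is the default for experiments and
tests; full scale is available everywhere by passing the default
parameters. Simulation sizes in the test-suite and acceptance script (10
paired seeds, 16-node lesions, ~6000-step trials) were chosen as the
smallest replication at which the paired orderings are statistically
unambiguous.

### Initial weights

No initial condition is part of the model definition, and the trained
regime turns out to depend on it strongly. The input→middle layer is drawn
uniformly on `[w_min, w_max]`: its drive (~50 active inputs × mean weight
5.15) is far above `theta_ml`, so the middle layer becomes a reliable,
effectively saturated relay. The middle→output layer is drawn uniformly on
`[w_min, 2*theta_output/n_eff]`, which places initial output drive *at* the
threshold. Training then ends (first `H = 0`) with desired-on output rows
only slightly above threshold — the regime in which losing part of a node's
afferents actually flips outputs and recovery is gradual. Had the output
layer also started at full range, desired-on rows would saturate at `w_max`
before the error first vanished and no lesion smaller than the neighbourhood
could cause any disability at all, which contradicts the damage-and-recovery
behaviour the model exists to exhibit. Both ranges are configurable
(`init_w_im_high`, `init_w_mo_high`).

### Learning-rate law

`EtaPolicy.fixed()` keeps `eta = eta0`. `EtaPolicy.modified(H0, Hc)` is the
worst-case recovery model in which severe disability also degrades
plasticity:

    eta(H) = eta0                                  for H < H0
           = eta0 sqrt(1 - ((H-H0)/(Hc-H0))^2)     for H0 <= H < Hc
           = 0                                     for H >= Hc

(continuous and nonincreasing). The law applies **from damage onset**: the
pre-lesion learning phase always runs at fixed `eta0`, because the initial
disability of an untrained network (~N/2) exceeds any sensible `Hc` and a
law with `eta(H >= Hc) = 0` active from the start could never complete the
initial learning. `Hc` is case-dependent and therefore required
configuration whenever the modified mode is selected (the examples use
Hc=25 and 35 at full scale, 15 at the scaled size).

## Lesion schedules

All lesions kill a contiguous modular block of `m` middle-layer nodes
(damage in the systems being modelled is localized, not scattered):

* `immediate`: all `m` at `start_time`;
* `gradual`: one node every `irt` time units, in ring order;
* `resection`: `n_p` packages of `m/n_p` contiguous nodes every `irt`
  units; when `m mod n_p != 0` the earliest packages take one extra node
  each (deterministic, closest to equal packages).

At `irt = 0` all three collapse to the same event and the package
guarantees bit-identical traces per seed across kinds. Killing a node
clears its alive flag, zeroes its incident weights (three-layer) or deletes
all its synapses and bars it from rewiring (homeostasis); removal is
idempotent. `start_index` defaults to a draw from the run seed (fixed per
run and logged); one draw is consumed whether or not an explicit index is
given, so random streams stay aligned across schedule variants. Time units
are steps for the three-layer model and morphological steps for the
homeostasis model.

## Homeostasis model

A ring of `n_nodes = 100` stochastic binary neurons, 80% excitatory.
`C[i, j]` counts directed synapses from `j` to `i`; each synapse contributes
±1 per presynaptic spike according to the *presynaptic* neuron's type
(counts-as-weights, the minimal reading of connectivity expressed as
numbers of connections). Each activity step,

    X_i = sum_j sign_j C[i,j] s_j + Poisson(lambda_ext),
    F_i = 1 / (1 + exp(-beta (X_i - theta))),  s_i ~ Bernoulli(F_i).

Every `T = 100` activity steps a **morphological step** drives each
neuron's time-averaged firing probability `Fbar_i` (over the last
`window = 1000` activity steps; over what exists early in a run) toward the
homeostatic target 0.5:

    dI_i = nu (Fbar_i - 0.5) I_i     (inputs; outputs analogously)

Above target, synapses are shed; below target, new ones are formed with
presynaptic (resp. postsynaptic) partners drawn among alive neurons with
probability proportional to `exp(-d^2 / 2 sigma^2)` on ring distance — new
wiring prefers near neighbours. Because the per-step change is usually
≪ 1 synapse, signed changes accumulate in per-neuron input/output
residuals and only the integer part is realized; counts never go negative
and the single matrix `C` is the only source of truth, so an input-side
deletion is automatically the partner's output-side loss. Each synapse
marked for removal is actually deleted with probability `p_del` per
morphological step (marks are consumed, so decay is stochastic and gradual;
set `p_del = 1` for deterministic removal). Network **disability** is the
population variance, across alive neurons, of `Fbar_i`. Dead neurons are
excluded — with them included the variance could never recover, which would
contradict the recovery the model exhibits; the choice is recorded in trace
metadata.

Defaults: `theta = 500`, `beta = 0.002`, `nu = 0.005`, `p_del = 0.1`,
`lambda_ext = 30`, `T = 100`, `window = 1000`. Two quantities are not part
of the published parameter set and are package choices: `init_indegree =
940`, putting the expected drive at target rate near threshold
(0.5·940 + 30 = 500), and `kernel_sigma = 10` on the 100-ring, local enough
that a 10-node lesion deafferents its neighbourhood but wide enough that
rewiring partners exist. From this initialization the mean in-degree grows
to ≈1650 over the burn-in (the self-consistent level at which the mean
signed drive with 80/20 excitation/inhibition reaches threshold) and mean
|Fbar − 0.5| settles below 0.01; the reference burn-in is 2700 morphological
steps, and lesion trials run 3100 morphological steps (310k activity steps,
~10 s each) so the post-lesion peak and the start of recovery fall inside
the window. Note the contrast with the three-layer model: here the rate of
structural change *grows* with the deviation from homeostasis, whereas the
modified-eta law shrinks learning as disability grows; the IRT ordering
holds under both recovery laws, which is what makes it robust.

## Experiments and statistics

`run_three_layer_trial` / `run_homeostasis_trial` produce full traces
(pre/lesion/recovery phases, per-step learning rate, event log);
`maod(trace, damage_start)` reduces a trace to its primary outcome;
`gradual_grid`, `resection_grid` and `homeostasis_irt_sweep` sweep (m × IRT)
and (n_p × IRT) surfaces with per-cell replicate seeds derived as
`SeedSequence([master, i, j, r])`, so cells are independent, reproducible
and order-invariant. The default post-lesion window is 4× the removal span
plus 2000 steps, placing the MAoD safely inside the simulated window.

Orderings ("MAoD at IRT=0 exceeds MAoD at IRT=50") are asserted
statistically, not by eyeballing curves: paired designs in which both arms
share a replicate's seed — hence the same network, patterns, excitatory
layout and lesion location — evaluated with a one-sided sign test over ≥10
paired seeds at alpha = 0.05. Pairing matters: between-network variance
(especially the lesion location relative to the excitatory/inhibitory
layout in the ring model) is comparable to the IRT effect, so unpaired
designs at this replication are underpowered.

## Determinism and randomness

All randomness flows from one `numpy` Generator per trial (PCG64). The
middle layer consumes exactly `N` uniforms per step regardless of the alive
mask, and schedule expansion consumes none, so trials sharing a seed but
differing in schedule are bit-identical until their first removal, and the
IRT=0 schedule-equivalence family is bit-exact. Every artifact (CSV trace
or grid) carries a JSON sidecar with the seed, a full parameter echo and
the package version, sufficient to regenerate it bit-identically.

## What the simulations do and do not show

Inputs are internally generated (random binary patterns; Poisson noise);
nothing is fit to data. The models abstract away continuous-valued
activity, spike timing, conduction delays, distance-dependent synapse
*deletion*, vacant synaptic elements and cell-death cascades. Passing tests
therefore demonstrate properties of these idealized mechanisms — bounded
Hebbian relearning and degree-proportional homeostatic rewiring under
localized node loss — not of any biological tissue. Within that scope the
central ordering (slower damage → smaller peak disability) is shown in two
architectures with opposite disability-dependence of their recovery rates,
which is the strongest internal evidence the package offers that the
effect is generic rather than a modelling artifact.

## Known limitations

* The three-layer trained state depends on the initial-weight convention
  (see above); other conventions can make the network either trivially
  robust or unable to learn, and are available through configuration for
  study rather than as defaults.
* The homeostasis model's `p_del` mechanics and wiring kernel are package
  choices where the model definition defers to its antecedents; both are
  configurable and flagged in metadata.
* At default replication (10 paired seeds) the homeostasis IRT ordering is
  significant but not overwhelming (typical sign-test p ≈ 0.01); claims at
  finer IRT resolution would need more seeds.
* Full-scale (N=500) three-layer grids over many cells are computationally
  heavy and exposed through the CLI/flags rather than run by default.
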