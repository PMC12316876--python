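# Methods

`epimem` implements a dual-network spiking attractor model of episodic
item-in-context memory and the behavioural task suite used to probe the
interaction of episodic binding with short-term recency dynamics. This
note documents the model, the numerical methods, the synthetic task
generator, the design choices that were genuinely open, and the known
limitations.

## Model

### Neurons

All cells are adaptive exponential integrate-and-fire (AdEx) point
neurons with conductance-based synapses:

    C_m dV/dt = -g_L (V - E_L) + g_L * Delta_T * exp((V - V_t)/Delta_T)
                - I_w + I_beta + I_syn + I_ext
    dI_w/dt   = -I_w / tau_Iw   (+ b at each spike)

Subthreshold adaptation is removed; spike-frequency adaptation enters
only through the spike-triggered increment `b = 86 pA` (decay
`tau_Iw = 280 ms`). `I_beta` is the learned intrinsic-excitability
current (below). Defaults: `C_m = 280 pF`, `g_L = 14 nS`,
`E_L = -70.6 mV`, `Delta_T = 3 mV`, `V_t = -55 mV`, `V_r = -60 mV`,
refractory period 5 ms.

Synaptic currents are conductance-based with exponential-decay AMPA
(`tau = 5 ms`, `E = 0 mV`), NMDA (`100 ms`, `0 mV`; a slow linear
conductance, no voltage dependence) and GABA (`5 ms`, `-75 mV`)
channels.

### Short-term plasticity

Every glutamatergic (pyramidal-pyramidal) connection carries
Tsodyks-Markram state: utilization `u` relaxing to `U = 0.2` with the
slow augmentation constant `tau_A = 5 s`, and resources `x` recovering
to 1 with `tau_D = 280 ms`. At each presynaptic arrival the ordering is
facilitate-then-release (`u += U(1-u)`, gain `= u*x` with the
incremented u, then `x -= u*x`). Augmentation is the model's carrier of
recency: an assembly activated seconds ago transiently transmits more
strongly. Static basket-cell synapses (`+3 nS` pyramidal-to-basket,
`-7 nS` basket-to-pyramidal, both confined to the local hypercolumn at
70% connection probability) bypass this machinery.

### BCPNN learning

Plastic weights and biases derive from cascaded exponential traces of
spiking: Z traces (tau = receptor constant; unit-area spike impulse
`1/(f_max tau_Z)`, with `f_max = 25 Hz`, plus the floor source
`eps = 0.0026`), eligibility E traces (`tau_E = 500 ms`; the joint
trace is driven by `Z_i * Z_j`), and probability P traces
(`tau_P = 30 s`), whose update rate is scaled by the plasticity gain
kappa. Weights and bias follow

    w_ij = w_gain * log(P_ij / (P_i P_j)),    I_beta_j = beta_gain * log(P_j)

per receptor component (`w_gain` 0.33 nS AMPA / 0.03 nS NMDA,
`beta_gain = 40 pA`; the bias uses the slow NMDA-component P_j by
default, switchable). Negative weights are delivered as GABA
conductance and stand in for disynaptic inhibition via double-bouquet
cells, which are not explicitly simulated. `kappa = 0` freezes P traces
(and hence weights and biases) exactly. Reward transiently raises kappa
from 0.3 to 1 for 250 ms on the associative (between-network)
connections only, 250 ms after the decision; the eligibility traces
bridge that delay so synapses co-active around the decision are
credited. The published equations print the pairwise P drive as
`E_i * E_j` while also defining a joint eligibility trace `E_ij`; this
package follows the BCPNN module lineage and drives `P_ij` with `E_ij`
(the printed product form is available as `pij_drive="ei_ej"`).

### Architecture

Two identical networks (Item, Context) of 9 hypercolumns (HCs) on a
3x3 grid (0.5 mm spacing, 0.5 mm HC diameter, networks 10 mm apart),
16 minicolumns (MCs) per HC, 30 pyramidal + 4 basket cells per MC: 8640
pyramidal and 1152 basket cells in total. Patterns (16 odor items, 2-3
contexts) each claim one encoding MC per HC, non-overlapping.
Connectivity is drawn per ordered pair: 0.2 within-MC recurrent, 0.2
long-range within-network, 0.04 associative between networks (both
directions), 0.7 pyramidal-basket loops within the HC. Conduction
delays are normal with mean distance/speed + 1.5 ms (speed 0.2 m/s
within, 2 m/s between networks) and 30% relative SD, clamped at 1.5 ms.

### Attractor preloading

Within-network weights are embedded before the task by offline BCPNN
training and then frozen (only their STP state evolves during the
task). The training protocol cycles all patterns (10 epochs; each
pattern cued for 500 ms at a burst rate of 75 Hz, with calibrated
silent gaps). Because training all ~7 million within-network synapses
with explicit spikes is unnecessary for class-level weights, the
training is integrated in closed form at minicolumn level: marginal
Z/E/P cascades per activity class, joint cascades per pair class, and a
Campbell-theorem covariance term for cell pairs inside one MC (which
share their spiking through common drive and dense recurrence;
shared-spike fraction `c_share = 1` by default). The silent gap is the
one calibrated quantity: it sets the background sparsity of the P
traces and is root-found so the population-mean within-HC EPSP at rest
equals the target 0.72 mV (first-spike STP release gain 0.36, combined
AMPA+NMDA, linearized-membrane closed form). The resulting class
weights reproduce the attractor structure: same-MC weights >
cross-HC same-pattern weights > 0 > different-pattern weights
(disynaptic inhibition). Per-connection multiplicative Gaussian jitter
(relative sd 0.118, matching the printed 0.085/0.72 EPSP spread)
emulates the finite-sampling dispersion of per-synapse spiking
training. Training the assemblies above `f_max` is deliberate: `f_max`
is the plasticity normalisation constant, not a firing-rate cap, and
cued attractor bursts exceed it.

## Simulation engine

The clock-driven core (Numba kernels, `dt = 0.1 ms`) uses:

* exponential-Euler integration of the conductance/linear membrane
  terms (3rd-order Taylor decay factor, error < 1e-7 per step) and
  forward-Euler for the AdEx upstroke, with the exponential argument
  clamped at +20 and spike detection at `V_t + 10 Delta_T`;
* a per-step ring buffer for delayed conductance deliveries (delays
  rounded to the nearest step);
* exact event-driven STP keyed to spike arrival times;
* closed-form multi-exponential propagation of all BCPNN traces at
  spike events, learning-rate boundaries and a 10 ms bookkeeping grid.
  Spikes enter Z as unit-area delta impulses (the `t_spike -> 0` limit
  of the rectangular pulse; `t_spike = 1 ms` remains the convention of
  the dense reference implementation in `epimem.bcpnn`). Associative
  weights are evaluated from the P traces on demand when a presynaptic
  spike is emitted, so their staleness is bounded by the conduction
  delay (< 10 ms versus tau_P = 30 s). Conduction delays are ignored
  for trace timing (delays are at most ~10 ms against tau_E = 500 ms).
* background noise as two independent 470 Hz Poisson conductance
  sources per pyramidal cell (+1.5 nS at the AMPA reversal and +1.5 nS
  at the GABA reversal; basket cells receive none), and cues as 340 Hz
  Poisson +1.5 nS excitatory drive onto the target assembly.

Determinism: all randomness (connectivity, delays, weight jitter,
noise, schedules) derives from explicit integer seeds; identical seeds
give bit-identical spike records.

## Task suite

A session is Item-Context Encoding followed by Memory Assessment.
The context pattern is cued continuously during its block; the two
items of each pair are cued serially for 250 ms with a 200 ms
inter-stimulus interval. Decisions compare the two items'
trial-average assembly rates: the model responds "new" to an item
firing at least 15% below its partner. A rewarded choice triggers a
100 ms re-stimulation of the chosen odor and, 250 ms after the
decision, the 250 ms kappa_reward window. An item becomes
old-in-context upon its first presentation in that context; under the
standard rule only correctly selected new-in-context items are
rewarded (once), under the reverse rule old-in-context responses are
rewarded on every activation.

Encoding introduces item groups with *introduction blocks*: the first
trial pairs two new items, each later trial pairs one not-yet-shown
item with a random already-shown item of the same group, followed by
one consolidation round of re-pairings. Keeping groups contiguous
pins the recency order: Arrangement 1 presents the old-in-target-
context group before the new group in the preceding context,
Arrangement 2 reverses the group order. The variants follow the same
template (unbalanced: two extra consolidation rounds for the new
group; extra context: a third context with a random half of the items
before Assessment, Assessment pairs whose old item became the more
recent are excluded from the Arrangement-1 statistics; reverse
rewarding: extra old-group re-pairings inside context A where the
reversed rule assigns repeatable rewards). Assessment pairs each
never-shown-in-target-context item with a random old item (perfect
matching, no Encoding pair repeated, every item assessed once); an
independent validator replays the ledger and checks every invariant.

What the generator emulates: the trial structure, recency orderings,
reward contingencies and continual-learning character of the published
rodent paradigm, at compressed time (no multi-minute retention
intervals, no motor/sniffing dynamics). Passing the directional tests
therefore shows that the synaptic mechanisms produce the behavioural
orderings under these compressed conditions, not that the model
quantitatively matches rat behaviour at full scale.

## Scale profiles and calibration

The full-scale profile reproduces the published tables verbatim. The
reduced desk-scale profile (4 HCs x 8 MCs per network, 8 items, 2176
neurons) preserves cell counts per MC and all time constants but has
smaller assemblies and fan-ins, so a calibration script
(`scripts/calibrate_reduced.py`) re-tunes gain multipliers, mirroring
the published tuning procedure (cue and background strength were tuned
there to reach behavioural range). The calibrated multipliers, stored
in `REDUCED_PROFILE`, are:

* within-network weights and the basket loop scaled to preserve
  per-cell assembly fan-in conductance (x2.25 and x2);
* the context cue doubled and the associative connection probability
  tripled — the 120-cell reduced context assembly must deliver
  full-scale aggregate drive through ~14 rather than ~5 synapses per
  target cell, and a denser, faster-firing context sustains smoother
  (less pulsatile) disynaptic inhibition;
* associative gain multipliers that depend on direction and delivered
  sign (x14 positive / x32 negative context-to-item, x2.25
  item-to-context). The negative (disynaptic-inhibition) weights carry
  the larger multiplier because their log-ratios are intrinsically
  smaller than reward-boosted positive bindings, and the item-to-context
  direction stays near fan-in compensation so that a single igniting
  item assembly cannot silence the small context assembly — the
  full-scale population is too redundant for that failure mode, and
  permitting it produces uncontrolled attractor battles.

Only the reference (Arrangement 1) task guided these choices; the
directional predictions (Arrangement 2 > Arrangement 1, ablation
collapse, extra context and reverse reward below reference) were read
out after fixing the profile.

Problem sizes used in the test suite: the directional acceptance test
pools 8 sessions per condition (32 scored Assessment pairs, fewer for
the extra-context variant where excluded pairs are dropped) on one
seeded reduced-scale network; trace/oracle checks run single synapses
or the tiny 2-HC test network.

## Numerical choices and degenerate cases

* Tied or both-zero rates at decision time count as errors (no
  selection, no reward).
* The PSP closed form handles `tau_syn = tau_m` by the alpha-function
  limit.
* The mean-field preload guards the degenerate equal-rate case in its
  exponential algebra by rate nudging (1e-9 relative).
* P traces are floored by construction (the eps source term); the
  weight/bias formulas raise on non-positive P, which is unreachable
  in normal operation.
* The delay distribution's lower clamp at 1.5 ms makes the zero-
  distance delay median (not mean) equal 1.5 ms.

## Known limitations

* The preload is a minicolumn-level mean-field computation, not
  per-synapse spiking training; within-class weight dispersion is
  modelled, between-class covariances are not.
* NMDA conductances are linear (no Mg block), as in the source model.
* The reduced profile's gain multipliers are a calibrated compromise;
  absolute hit rates at reduced scale are not comparable to full-scale
  percentages, only orderings are.
* The reverse-rewarding decrement is not reproduced at reduced scale:
  the calibration that lets disynaptic suppression dominate the new
  items' recency advantage (required for the reference performance and
  the ablation collapse) also makes trials with weakly-bound old items
  resolvable by suppression alone, so reward-count imbalance does not
  translate into errors; reverse performance lands at the reference
  level instead of below it. The corresponding test asserts the
  predicted ordering and fails, documenting the limitation.
* Full-scale behavioural simulation (9 HCs, hundreds of Assessment
  pairs) is supported by the same code path but takes hours of CPU
  time; the shipped tests exercise the reduced profile.
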