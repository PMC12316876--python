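# epimem

A spiking neural network model of **episodic item-in-context memory**
and its interaction with short-term recency dynamics, for computational
neuroscientists studying how synaptic processes on different time
scales jointly shape recall behaviour.

Two reciprocally connected attractor networks — an Item network storing
16 odor memories and a Context network storing arena contexts as
distributed cell assemblies — are built from adaptive exponential
integrate-and-fire neurons (AdEx) with conductance-based AMPA/NMDA/GABA
synapses. Three plasticity processes coexist on the same substrate:

* **Short-term augmentation/depression** (Tsodyks–Markram; `tau_A = 5 s`,
  `tau_D = 280 ms`) — the carrier of recency;
* **Spike-based Bayesian–Hebbian learning (BCPNN)** — probability traces
  P_i, P_j, P_ij give weights `w_ij = w_gain · log(P_ij/(P_i P_j))` and
  intrinsic-excitability biases `I_beta = beta_gain · log(P_j)`;
  anti-correlated assemblies acquire *negative* weights delivered at the
  GABA reversal (learned disynaptic inhibition);
* **Reward-gated eligibility traces** — a reward 250 ms after a correct
  choice transiently raises the plasticity gain kappa (0.3 → 1) on the
  between-network connections, crediting synapses co-active around the
  decision.

The package regenerates the item-in-context task suite — encoding items
across contexts A/B(/C), Memory Assessment of new- vs old-in-context
pairs under two recency arrangements, unbalanced training, extra-context
interference, reverse rewarding, and disynaptic-inhibition ablation —
with the model choosing "new" whenever an item's trial-average assembly
rate falls 15% below its partner's.

## Worked example

```python
from epimem.params import ExperimentConfig
from epimem.network import preload_attractors

cfg = ExperimentConfig()                 # published parameter tables
pre = preload_attractors(cfg, n_items=16)
print(f"within-HC EPSP  {pre.mean_epsp_within_hc:.3f} mV")
for klass, (w_ampa, w_nmda) in pre.weights.items():
    print(f"{klass:>12}: AMPA {w_ampa:+.3f} nS  NMDA {w_nmda:+.4f} nS")
```

prints

```
within-HC EPSP  0.720 mV
     same_mc: AMPA +2.131 nS  NMDA +0.1642 nS
same_pattern: AMPA +1.850 nS  NMDA +0.1618 nS
diff_pattern: AMPA -0.155 nS  NMDA -0.0141 nS
      silent: AMPA -0.000 nS  NMDA -0.0000 nS
```

— the embedded long-term attractors: recurrent weights within a
pattern's home minicolumn are strongest, cross-hypercolumn same-pattern
weights weaker but excitatory, and competing patterns are coupled by
learned inhibition. The population-mean single-connection EPSP at rest
(0.72 mV) is in the physiological range for layer 2/3 pairs.

A behavioural run at desk scale (reduced 4-hypercolumn profile,
8 items):

```python
from epimem.experiment import run_experiment
cfg = ExperimentConfig(profile="reduced", variant="exp1_arr1")
res = run_experiment(cfg, seed=1, n_sessions=5)
print(res.summary)   # pooled Assessment hit rate with Bernoulli SD
```

The same driver exposes every task variant and the
`ablate_disynaptic=True` manipulation; `epimem --help` lists the CLI
(`build-network`, `generate-schedule`, `run-experiment`, `ablate`).

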