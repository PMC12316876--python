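"""Model parameters.

Defaults reproduce the published neuron, synapse, plasticity, layout,
connectivity and stimulation parameter tables of the dual-network
item-in-context attractor model. All quantities carry explicit units in
their field names or docstrings: conductances in nS, currents in pA,
capacitance in pF, voltages in mV, times in ms unless noted.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional

import yaml


@dataclass
class NeuronParams:
    """Adaptive exponential integrate-and-fire neuron (subthreshold
    adaptation removed; intrinsic-excitability current I_beta added).

    The spike cutoff is ``V_t + 10*Delta_T``: once the exponential upstroke
    carries the membrane past this point the precise cutoff no longer
    affects spike timing, and clamping there prevents overflow.
    """

    C_m: float = 280.0       # membrane capacitance, pF
    g_L: float = 14.0        # leak conductance, nS
    E_L: float = -70.6       # leak reversal, mV
    Delta_T: float = 3.0     # upstroke slope factor, mV
    V_t: float = -55.0       # spike threshold, mV
    V_r: float = -60.0       # reset potential, mV
    tau_ref: float = 5.0     # refractory period, ms
    b: float = 86.0          # adaptation increment, pA
    tau_Iw: float = 280.0    # adaptation decay, ms
    beta_gain: float = 40.0  # bias-current gain, pA

    def __post_init__(self) -> None:
        if self.C_m <= 0 or self.g_L <= 0:
            raise ValueError("C_m and g_L must be positive")
        if self.tau_ref < 0 or self.tau_Iw <= 0:
            raise ValueError("time constants must be positive")
        if self.V_r > self.V_t:
            raise ValueError("V_r must not exceed V_t")

    @property
    def tau_m(self) -> float:
        """Membrane time constant C_m/g_L in ms."""
        return self.C_m / self.g_L

    @property
    def spike_cutoff(self) -> float:
        """Numerical spike detection voltage, mV."""
        return self.V_t + 10.0 * self.Delta_T


@dataclass
class ReceptorParams:
    """Conductance-based receptor channels (exponential decay)."""

    tau_ampa: float = 5.0     # ms
    tau_nmda: float = 100.0   # ms
    tau_gaba: float = 5.0     # ms
    E_ampa: float = 0.0       # mV
    E_nmda: float = 0.0       # mV
    E_gaba: float = -75.0     # mV

    def __post_init__(self) -> None:
        if min(self.tau_ampa, self.tau_nmda, self.tau_gaba) <= 0:
            raise ValueError("receptor time constants must be positive")


@dataclass
class StpParams:
    """Tsodyks-Markram short-term plasticity (augmentation + depression).

    ``tau_A`` (facilitation/augmentation) and ``tau_D`` (depression
    recovery) follow the published table; augmentation is the slow (~5 s)
    component that carries the model's recency effect.
    """

    U: float = 0.2         # utilization increment, dimensionless
    tau_A: float = 5000.0  # augmentation decay, ms
    tau_D: float = 280.0   # depression recovery, ms

    def __post_init__(self) -> None:
        if not (0.0 < self.U <= 1.0):
            raise ValueError("U must be in (0, 1]")
        if self.tau_A <= 0 or self.tau_D <= 0:
            raise ValueError("STP time constants must be positive")


@dataclass
class BcpnnParams:
    """Spike-based Bayesian-Hebbian (BCPNN) learning rule parameters.

    Two full trace sets are maintained per connection: a fast component
    with tau_Z = tau_ampa producing the AMPA weight, and a slow component
    with tau_Z = tau_nmda producing the NMDA weight. The intrinsic
    excitability bias is computed from the slow (rate-like) component by
    default (``bias_component``).
    """

    tau_z_ampa: float = 5.0      # ms
    tau_z_nmda: float = 100.0    # ms
    tau_e: float = 500.0         # eligibility trace, ms
    tau_p: float = 30000.0       # probability trace, ms
    f_max: float = 25.0          # Hz
    f_min: float = 0.2           # Hz (table value; no printed equation uses it)
    eps: float = 0.0026          # lowest probability estimate
    t_spike: float = 1.0         # spike-pulse duration, ms
    w_gain_ampa: float = 0.33    # nS
    w_gain_nmda: float = 0.03    # nS
    beta_gain: float = 40.0      # pA
    kappa_normal: float = 0.3
    kappa_reward: float = 1.0
    reward_duration: float = 250.0  # ms; kappa_reward window length
    bias_component: str = "nmda"    # "nmda" | "ampa"
    pij_drive: str = "eij"          # "eij" | "ei_ej"

    def __post_init__(self) -> None:
        if not (self.tau_z_ampa < self.tau_e < self.tau_p):
            raise ValueError("require tau_Z < tau_E < tau_P")
        if not (0.0 < self.eps < 1.0):
            raise ValueError("eps must be in (0, 1)")
        for k in (self.kappa_normal, self.kappa_reward):
            if not (0.0 <= k <= 1.0):
                raise ValueError("kappa levels must lie in [0, 1]")
        if self.bias_component not in ("nmda", "ampa"):
            raise ValueError("bias_component must be 'nmda' or 'ampa'")
        if self.pij_drive not in ("eij", "ei_ej"):
            raise ValueError("pij_drive must be 'eij' or 'ei_ej'")

    def tau_z(self, component: str) -> float:
        return self.tau_z_ampa if component == "ampa" else self.tau_z_nmda


@dataclass
class LayoutParams:
    """Spatial layout of one network (hypercolumn/minicolumn grid)."""

    n_hc: int = 9               # hypercolumns per network (3x3 grid)
    n_mc_per_hc: int = 16       # minicolumns per hypercolumn
    n_pyr_per_mc: int = 30      # layer 2/3 pyramidal cells per MC
    n_basket_per_mc: int = 4    # basket cells per MC
    hc_diameter: float = 0.5    # mm
    grid_spacing: float = 0.5   # mm between HC centres
    network_distance: float = 10.0  # mm between the two networks

    @property
    def n_pyr(self) -> int:
        return self.n_hc * self.n_mc_per_hc * self.n_pyr_per_mc

    @property
    def n_basket(self) -> int:
        return self.n_hc * self.n_mc_per_hc * self.n_basket_per_mc


@dataclass
class ConnectivityParams:
    """Connection probabilities, static conductances and conduction."""

    cp_pp: float = 0.2       # pyr-pyr recurrent (within MC)
    cp_ppl: float = 0.2      # pyr-pyr long-range (within network, across MCs)
    cp_ppa: float = 0.04     # pyr-pyr associative (between networks)
    cp_pb: float = 0.7       # pyr->basket within HC
    cp_bp: float = 0.7       # basket->pyr within HC
    g_pb: float = 3.0        # nS, static pyr->basket
    g_bp: float = -7.0       # nS, static basket->pyr (GABA)
    speed: float = 0.2       # m/s axonal conduction, within network
    speed_myel: float = 2.0  # m/s, between networks (myelinated)
    t_min_syn: float = 1.5   # ms minimal synaptic delay
    delay_rel_sd: float = 0.3  # relative SD of the delay distribution

    def __post_init__(self) -> None:
        for p in (self.cp_pp, self.cp_ppl, self.cp_ppa, self.cp_pb, self.cp_bp):
            if not (0.0 <= p <= 1.0):
                raise ValueError("connection probabilities must lie in [0,1]")


@dataclass
class StimulusParams:
    """Background noise and cue stimulation (all onto pyramidal cells)."""

    r_bg: float = 470.0      # Hz, each of the two background Poisson sources
    g_bg: float = 1.5        # nS; +g_bg at E_ampa and +g_bg at E_gaba
    r_stim: float = 340.0    # Hz specific cue rate
    g_stim: float = 1.5      # nS cue conductance (excitatory)
    t_stim: float = 250.0    # ms item stimulation duration
    t_cue: float = 100.0     # ms pre-reward re-stimulation
    T_stim: float = 200.0    # ms inter-stimulus interval
    reward_delay: float = 250.0  # ms from decision to reward delivery

    def __post_init__(self) -> None:
        if min(self.r_bg, self.r_stim) < 0:
            raise ValueError("rates must be non-negative")


@dataclass
class PreloadParams:
    """Offline BCPNN training protocol embedding the long-term attractors.

    Patterns are cued one at a time at ``f_train`` for ``t_active`` with
    silent gaps of ``t_gap`` in between, over ``n_epochs`` shuffled epochs
    with full plasticity (kappa = 1). ``c_share`` is the shared-spike
    fraction of cell pairs inside one minicolumn (common drive), which
    boosts their co-activation trace (Campbell-theorem covariance term).
    ``t_gap`` is calibrated at build time so the population-mean within-HC
    EPSP at rest equals ``target_epsp`` (set target_epsp=None to skip).
    """

    n_epochs: int = 10
    t_active: float = 500.0     # ms per pattern presentation
    t_gap: float = 20000.0      # ms silence between presentations
    f_train: float = 75.0       # Hz burst rate of a cued assembly
    c_share: float = 1.0        # within-MC shared-spike fraction
    target_epsp: Optional[float] = 0.72  # mV, within-HC population mean
    weight_jitter: float = 0.118  # relative sd of per-connection jitter


@dataclass
class ScaleProfile:
    """Full-scale layout versus a reduced profile for desk-scale runs.

    The reduced profile shrinks the grid (fewer HCs and MCs) and rescales
    synaptic gains so that expected assembly fan-in conductances match the
    full-scale model (see the calibration helper in ``experiment``).
    """

    name: str = "full"
    n_hc: int = 9
    n_mc_per_hc: int = 16
    n_items: int = 16
    n_contexts: int = 2
    w_scale_within: float = 1.0   # multiplier on preloaded within-net weights
    g_bp_scale: float = 1.0       # multiplier on basket->pyr conductance
    g_stim_scale: float = 1.0     # multiplier on the item-cue conductance
    ctx_stim_scale: float = 1.0   # multiplier on the context-cue conductance
    cp_ppa_scale: float = 1.0     # multiplier on associative connectivity
    beta_gain_scale: float = 1.0  # multiplier on the bias-current gain
    # associative-gain multipliers by direction (context->item vs
    # item->context) and delivered-weight sign; all 1 at full scale
    assoc_scale_pos: float = 1.0
    assoc_scale_neg: float = 1.0
    assoc_scale_rev_pos: float = 1.0
    assoc_scale_rev_neg: float = 1.0


FULL_PROFILE = ScaleProfile()

# Reduced desk-scale profile: 4 HCs x 8 MCs per network, 8 items.
# Gain multipliers keep expected per-cell assembly fan-in conductance at the
# full-scale level: within-network same-pattern fan-in drops from
# 0.2*(29 + 8*30) cells to 0.2*(29 + 3*30), associative fan-in from
# 0.04*270 to 0.04*120 cells; basket fan-in from 0.7*64 to 0.7*32.
REDUCED_PROFILE = ScaleProfile(
    name="reduced",
    n_hc=4,
    n_mc_per_hc=8,
    n_items=8,
    n_contexts=2,
    w_scale_within=(29 + 8 * 30) / (29 + 3 * 30),
    g_bp_scale=64.0 / 32.0,
    ctx_stim_scale=2.0,
    cp_ppa_scale=3.0,
    assoc_scale_pos=14.0,
    assoc_scale_neg=32.0,
    assoc_scale_rev_pos=2.25,
    assoc_scale_rev_neg=2.25,
)

PROFILES = {"full": FULL_PROFILE, "reduced": REDUCED_PROFILE}


@dataclass
class SimulationConfig:
    """Clock-driven integration and recording configuration."""

    dt: float = 0.1            # ms
    dt_traces: float = 1.0     # ms cadence of per-neuron trace bookkeeping
    master_seed: int = 1
    record_spikes: bool = True
    snapshot_at_blocks: bool = True

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.dt > 0.1 + 1e-12:
            raise ValueError("dt must be positive and at most 0.1 ms")


@dataclass
class ExperimentConfig:
    """Full experiment description: model parameters + task variant."""

    neuron: NeuronParams = field(default_factory=NeuronParams)
    receptors: ReceptorParams = field(default_factory=ReceptorParams)
    stp: StpParams = field(default_factory=StpParams)
    bcpnn: BcpnnParams = field(default_factory=BcpnnParams)
    layout: LayoutParams = field(default_factory=LayoutParams)
    connectivity: ConnectivityParams = field(default_factory=ConnectivityParams)
    stimulus: StimulusParams = field(default_factory=StimulusParams)
    preload: PreloadParams = field(default_factory=PreloadParams)
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    profile: str = "full"
    variant: str = "exp1_arr1"
    n_sessions: int = 1
    f_bg_estimate: float = 1.0  # Hz; initial rate estimate for P-trace init
    decision_threshold: float = 0.85  # select "new" iff f_new < thr * f_old
    outdir: str = "results"

    def apply_profile(self) -> "ExperimentConfig":
        """Return a copy with the scale profile folded into the layout.

        The full-scale profile leaves the configured layout untouched
        (so bespoke layouts pass through); reduced profiles override the
        grid dimensions.
        """
        prof = PROFILES[self.profile]
        cfg = dataclasses.replace(self)
        if prof.name != "full":
            cfg.layout = dataclasses.replace(
                self.layout, n_hc=prof.n_hc, n_mc_per_hc=prof.n_mc_per_hc
            )
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "ExperimentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentConfig":
        kwargs = dict(data)
        sub = {
            "neuron": NeuronParams, "receptors": ReceptorParams,
            "stp": StpParams, "bcpnn": BcpnnParams, "layout": LayoutParams,
            "connectivity": ConnectivityParams, "stimulus": StimulusParams,
            "preload": PreloadParams, "sim": SimulationConfig,
        }
        for key, klass in sub.items():
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = klass(**kwargs[key])
        return cls(**kwargs)
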