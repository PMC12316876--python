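"""Spike-based Bayesian-Hebbian (BCPNN) plasticity.

The learning rule keeps three cascaded exponential filters of spiking
activity per connection and receptor component:

* Z traces (tau_Z = receptor time constant) low-pass filter the spike
  indicator normalised to ``S/(f_max * t_spike) + eps``;
* E traces (tau_E) low-pass the Z traces (eligibility; E_ij is driven by
  the co-activation product Z_i * Z_j);
* P traces (tau_P, scaled by the learning-rate gain kappa) low-pass the
  E traces and estimate firing/co-firing probabilities.

Weights and the intrinsic-excitability bias derive from the P traces:

    w_ij = w_gain * log(P_ij / (P_i P_j)),   I_beta_j = beta_gain * log(P_j)

Negative weights are delivered at the GABA reversal potential and model
disynaptic inhibition (double-bouquet cells are not simulated
explicitly). kappa = 0 freezes P traces (and hence weights and biases)
exactly; a transient switch to kappa_reward converts the eligibility
accumulated around the decision time into credit, implementing
reward-gated learning with a delay tolerance set by tau_E.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .params import BcpnnParams

COMPONENTS = ("ampa", "nmda")


class TraceFloorViolation(ValueError):
    """A probability trace left its admissible (positive) range."""


@dataclass
class ComponentTraces:
    """Z/E/P traces of one receptor component for one connection.

    Scalars by default, but all updates are numpy-compatible so arrays
    of connections can share one instance.
    """

    Z_i: float
    Z_j: float
    E_i: float
    E_j: float
    E_ij: float
    P_i: float
    P_j: float
    P_ij: float

    @classmethod
    def uncorrelated(cls, p_rate: float, eps: float) -> "ComponentTraces":
        """Initialise at the independent fixed point of rate estimate
        ``p_rate`` (a probability, e.g. f/f_max): P_ij = P_i * P_j, so the
        weight starts at zero."""
        p = max(p_rate, eps)
        return cls(Z_i=p, Z_j=p, E_i=p, E_j=p, E_ij=p * p,
                   P_i=p, P_j=p, P_ij=p * p)


@dataclass
class BcpnnTraceSet:
    """Dual-component trace set (fast AMPA and slow NMDA filters)."""

    ampa: ComponentTraces
    nmda: ComponentTraces

    @classmethod
    def uncorrelated(cls, p_rate: float, params: BcpnnParams) -> "BcpnnTraceSet":
        return cls(
            ampa=ComponentTraces.uncorrelated(p_rate, params.eps),
            nmda=ComponentTraces.uncorrelated(p_rate, params.eps),
        )

    def component(self, name: str) -> ComponentTraces:
        return getattr(self, name)


def update_traces(
    traces: BcpnnTraceSet,
    S_i: float,
    S_j: float,
    kappa: float,
    dt: float,
    params: BcpnnParams,
) -> BcpnnTraceSet:
    """Advance all traces by one step of length ``dt`` ms.

    ``S_i``/``S_j`` are pulse indicators: 1 while a spike pulse of
    duration ``t_spike`` is active (see :func:`spikes_to_pulse_train`),
    else 0. Uses exponential-Euler per stage (exact for piecewise-
    constant drive), so kappa = 0 leaves P traces bit-identical.
    """
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    f_max_khz = params.f_max / 1000.0
    amp = 1.0 / (f_max_khz * params.t_spike)
    for name in COMPONENTS:
        c = traces.component(name)
        tau_z = params.tau_z(name)
        dz = math.exp(-dt / tau_z)
        tgt_i = S_i * amp + params.eps
        tgt_j = S_j * amp + params.eps
        c.Z_i = tgt_i + (c.Z_i - tgt_i) * dz
        c.Z_j = tgt_j + (c.Z_j - tgt_j) * dz
        de = math.exp(-dt / params.tau_e)
        c.E_i = c.Z_i + (c.E_i - c.Z_i) * de
        c.E_j = c.Z_j + (c.E_j - c.Z_j) * de
        zz = c.Z_i * c.Z_j
        c.E_ij = zz + (c.E_ij - zz) * de
        if kappa > 0:
            dp = math.exp(-kappa * dt / params.tau_p)
            c.P_i = c.E_i + (c.P_i - c.E_i) * dp
            c.P_j = c.E_j + (c.P_j - c.E_j) * dp
            drive = c.E_ij if params.pij_drive == "eij" else c.E_i * c.E_j
            c.P_ij = drive + (c.P_ij - drive) * dp
    return traces


def compute_weight(traces: BcpnnTraceSet | ComponentTraces,
                   w_gain: float,
                   component: str | None = None) -> float:
    """Signed BCPNN weight w_gain * log(P_ij/(P_i P_j)) in nS."""
    c = traces.component(component) if isinstance(traces, BcpnnTraceSet) else traces
    if c.P_i <= 0 or c.P_j <= 0 or c.P_ij <= 0:
        raise TraceFloorViolation("non-positive P trace")
    return w_gain * math.log(c.P_ij / (c.P_i * c.P_j))


def compute_bias(P_j: float, beta_gain: float) -> float:
    """Intrinsic-excitability current beta_gain * log(P_j) in pA."""
    if P_j <= 0:
        raise TraceFloorViolation("non-positive P_j trace")
    return beta_gain * math.log(P_j)


def spikes_to_pulse_train(
    spike_times: np.ndarray, dt: float, t_spike: float, n_steps: int
) -> np.ndarray:
    """Binary pulse indicator per step: 1 for ``t_spike`` ms after each
    spike (pulses from overlapping spikes do not stack)."""
    S = np.zeros(n_steps)
    width = max(1, int(round(t_spike / dt)))
    for t in np.asarray(spike_times, dtype=float):
        i = int(math.floor(t / dt))
        if 0 <= i < n_steps:
            S[i:i + width] = 1.0
    return S


@dataclass
class KappaWindow:
    """Closed-open interval [t_start, t_end) with elevated kappa."""

    t_start: float
    t_end: float
    kappa: float


@dataclass
class KappaSchedule:
    """Piecewise-constant learning-rate timeline for one connection class.

    Baseline ``kappa_normal`` everywhere, overridden inside reward
    windows. Reward windows apply only to the associative
    (between-network) connections; within-network weights are frozen
    (kappa identically 0) during the task.
    """

    baseline: float
    windows: list[KappaWindow] = field(default_factory=list)

    def add_reward(self, t_start: float, duration: float, kappa: float) -> None:
        self.windows.append(KappaWindow(t_start, t_start + duration, kappa))

    def kappa_at(self, t: float) -> float:
        for w in self.windows:
            if w.t_start <= t < w.t_end:
                return w.kappa
        return self.baseline

    def boundaries(self, t0: float, t1: float) -> list[float]:
        """Switch times inside (t0, t1), sorted."""
        pts = set()
        for w in self.windows:
            for t in (w.t_start, w.t_end):
                if t0 < t < t1:
                    pts.add(t)
        return sorted(pts)


def set_kappa(
    schedule: KappaSchedule,
    event: str,
    t: float,
    params: BcpnnParams,
    scope: str = "associative",
) -> KappaSchedule:
    """Register a plasticity-gain event on the given connection scope.

    ``event`` is "reward" (open a kappa_reward window at ``t``) or
    "normal" (no-op; baseline applies outside windows). Targeting the
    frozen within-network connections is a configuration error.
    """
    if scope != "associative":
        raise ValueError(
            "reward modulation applies only to associative connections; "
            f"got scope={scope!r}"
        )
    if event == "reward":
        schedule.add_reward(t, params.reward_duration, params.kappa_reward)
    elif event != "normal":
        raise ValueError(f"unknown kappa event {event!r}")
    return schedule


@dataclass
class PairSimulator:
    """Dense simulator of one plastic pre/post pair; the module-level
    oracle used for equilibrium and reward-credit analyses."""

    params: BcpnnParams
    dt: float = 0.1
    init_rate: float | None = None

    def run(
        self,
        pre_spikes: np.ndarray,
        post_spikes: np.ndarray,
        duration: float,
        kappa_schedule: KappaSchedule | None = None,
    ) -> BcpnnTraceSet:
        n = int(round(duration / self.dt))
        p0 = self.init_rate if self.init_rate is not None else self.params.eps
        traces = BcpnnTraceSet.uncorrelated(p0, self.params)
        S_i = spikes_to_pulse_train(pre_spikes, self.dt, self.params.t_spike, n)
        S_j = spikes_to_pulse_train(post_spikes, self.dt, self.params.t_spike, n)
        sched = kappa_schedule or KappaSchedule(self.params.kappa_normal)
        for step in range(n):
            k = sched.kappa_at(step * self.dt)
            update_traces(traces, S_i[step], S_j[step], k, self.dt, self.params)
        return traces
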