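"""Adaptive exponential integrate-and-fire (AdEx) membrane dynamics.

Reference implementation of the point-neuron model used throughout the
package: conductance-based synapses (AMPA/NMDA/GABA), spike-frequency
adaptation via the adaptation current I_w, and a learned
intrinsic-excitability current I_beta. Subthreshold adaptation is removed.

The functions here operate on numpy arrays (a scalar is a 0-d array) and
are the readable, oracle-friendly counterpart of the compiled kernels in
``epimem._kernels``; both implement exactly the same update:

* exponential-Euler for all conductance/linear terms,
* forward-Euler for the exponential spike-upstroke nonlinearity,
* a spike is declared when V_m exceeds ``V_t + 10*Delta_T`` and the
  exponential argument is clamped at +20 before exponentiation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import NeuronParams, ReceptorParams

EXP_ARG_CLAMP = 20.0


class NumericalError(RuntimeError):
    """Raised when the membrane state becomes non-finite."""


@dataclass
class SynapticInput:
    """Total receptor conductances (nS) onto a neuron at one time step.

    Negative-weight (disynaptic-inhibition) deliveries are routed by the
    synapse layer as positive conductance on the GABA channel, so all
    entries here are non-negative.
    """

    g_ampa: np.ndarray | float = 0.0
    g_nmda: np.ndarray | float = 0.0
    g_gaba: np.ndarray | float = 0.0


@dataclass
class NeuronState:
    """Membrane state; fields are arrays over neurons."""

    V_m: np.ndarray
    I_w: np.ndarray
    I_beta: np.ndarray
    refractory_remaining: np.ndarray  # ms
    spike_count: np.ndarray

    @classmethod
    def resting(cls, n: int, params: NeuronParams) -> "NeuronState":
        return cls(
            V_m=np.full(n, params.E_L, dtype=float),
            I_w=np.zeros(n),
            I_beta=np.zeros(n),
            refractory_remaining=np.zeros(n),
            spike_count=np.zeros(n, dtype=np.int64),
        )


def exponential_term(V_m: np.ndarray, params: NeuronParams) -> np.ndarray:
    """AdEx upstroke current g_L * Delta_T * exp((V_m - V_t)/Delta_T), pA.

    The exponent is clamped at +20 so pathological states cannot overflow.
    """
    arg = np.minimum((V_m - params.V_t) / params.Delta_T, EXP_ARG_CLAMP)
    return params.g_L * params.Delta_T * np.exp(arg)


def step_membrane(
    state: NeuronState,
    params: NeuronParams,
    syn: SynapticInput,
    receptors: ReceptorParams,
    I_ext: np.ndarray | float,
    dt: float,
) -> NeuronState:
    """Advance V_m by one time step of length ``dt`` (ms), in place.

    Refractory neurons stay clamped at V_r (their refractory clock is
    decremented); I_w decay is handled by :func:`fire_and_reset` so the
    two functions together apply exactly one decay per step.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    V = state.V_m
    refractory = state.refractory_remaining > 0

    g_a = np.asarray(syn.g_ampa, dtype=float)
    g_n = np.asarray(syn.g_nmda, dtype=float)
    g_g = np.asarray(syn.g_gaba, dtype=float)
    G_tot = params.g_L + g_a + g_n + g_g

    I_exp = exponential_term(V, params)
    numer = (
        params.g_L * params.E_L
        + g_a * receptors.E_ampa
        + g_n * receptors.E_nmda
        + g_g * receptors.E_gaba
        + I_exp
        + state.I_beta
        + I_ext
        - state.I_w
    )
    V_inf = numer / G_tot
    decay = np.exp(-dt * G_tot / params.C_m)
    V_new = V_inf + (V - V_inf) * decay

    state.V_m = np.where(refractory, params.V_r, V_new)
    state.refractory_remaining = np.where(
        refractory, state.refractory_remaining - dt, 0.0
    )
    if not np.all(np.isfinite(state.V_m)):
        raise NumericalError("non-finite membrane potential after step")
    return state


def fire_and_reset(
    state: NeuronState, params: NeuronParams, dt: float
) -> tuple[NeuronState, np.ndarray]:
    """Detect spikes, reset, start refractoriness and update I_w.

    I_w decays by exp(-dt/tau_Iw) every step and jumps by ``b`` on each
    spike. Returns (state, boolean spike flags).
    """
    spiking = state.V_m > params.spike_cutoff
    state.I_w = state.I_w * np.exp(-dt / params.tau_Iw)
    state.I_w = np.where(spiking, state.I_w + params.b, state.I_w)
    state.V_m = np.where(spiking, params.V_r, state.V_m)
    state.refractory_remaining = np.where(
        spiking, params.tau_ref, state.refractory_remaining
    )
    state.spike_count = state.spike_count + spiking.astype(np.int64)
    return state, spiking


@dataclass
class SingleNeuronSim:
    """Convenience dense simulator for one neuron with exponentially
    decaying receptor conductances; used for PSP measurements and tests."""

    params: NeuronParams = field(default_factory=NeuronParams)
    receptors: ReceptorParams = field(default_factory=ReceptorParams)
    dt: float = 0.1

    def run(
        self,
        duration: float,
        V0: float | None = None,
        I_ext: float = 0.0,
        I_hold_at: float | None = None,
        conductance_events: list[tuple[float, str, float]] | None = None,
    ) -> dict[str, np.ndarray]:
        """Integrate one neuron for ``duration`` ms.

        ``conductance_events`` is a list of (time_ms, receptor, g_nS)
        jumps. If ``I_hold_at`` is given, a constant holding current
        clamps the resting potential at that voltage (voltage-clamp-like
        baseline for PSP amplitude measurements).
        """
        n_steps = int(round(duration / self.dt))
        p, r = self.params, self.receptors
        state = NeuronState.resting(1, p)
        if I_hold_at is not None:
            # steady state: 0 = -g_L (V - E_L) + exp-term + I_hold
            I_hold = p.g_L * (I_hold_at - p.E_L) - float(
                exponential_term(np.array(I_hold_at), p)
            )
            state.V_m[:] = I_hold_at
        else:
            I_hold = 0.0
        if V0 is not None:
            state.V_m[:] = V0
        g = {"ampa": 0.0, "nmda": 0.0, "gaba": 0.0}
        taus = {"ampa": r.tau_ampa, "nmda": r.tau_nmda, "gaba": r.tau_gaba}
        decays = {k: np.exp(-self.dt / v) for k, v in taus.items()}
        events = sorted(conductance_events or [])
        ev_idx = 0
        V_trace = np.empty(n_steps + 1)
        V_trace[0] = state.V_m[0]
        spikes = []
        for step in range(n_steps):
            t = step * self.dt
            while ev_idx < len(events) and events[ev_idx][0] <= t:
                _, rec, amount = events[ev_idx]
                g[rec] += amount
                ev_idx += 1
            syn = SynapticInput(g["ampa"], g["nmda"], g["gaba"])
            step_membrane(state, p, syn, r, I_ext + I_hold, self.dt)
            state, spiked = fire_and_reset(state, p, self.dt)
            if spiked[0]:
                spikes.append(t + self.dt)
            for k in g:
                g[k] *= decays[k]
            V_trace[step + 1] = state.V_m[0]
        return {
            "t": np.arange(n_steps + 1) * self.dt,
            "V_m": V_trace,
            "spikes": np.asarray(spikes),
        }


def measure_psp_peak(
    w_eff: float,
    receptor: str,
    V_hold: float,
    params: NeuronParams | None = None,
    receptors: ReceptorParams | None = None,
    dt: float = 0.1,
    duration: float = 200.0,
) -> float:
    """Simulate a single postsynaptic potential and return its peak
    deflection (mV, signed) relative to the holding potential.

    ``w_eff`` is the delivered conductance amplitude in nS; negative
    values are routed to the GABA channel with magnitude ``|w_eff|``.
    """
    params = params or NeuronParams()
    receptors = receptors or ReceptorParams()
    if w_eff < 0:
        receptor = "gaba"
    sim = SingleNeuronSim(params, receptors, dt)
    out = sim.run(
        duration,
        I_hold_at=V_hold,
        conductance_events=[(10.0, receptor, abs(w_eff))],
    )
    dv = out["V_m"] - V_hold
    i = np.argmax(np.abs(dv))
    return float(dv[i])
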