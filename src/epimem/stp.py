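"""Tsodyks-Markram short-term plasticity and receptor conductances.

Glutamatergic connections carry a per-connection (u, x) state:
``u`` (utilization) decays toward U with the slow augmentation constant
tau_A and is incremented at each presynaptic spike, while ``x``
(available resources) recovers toward 1 with tau_D and is depleted by
each release. The facilitation increment is applied *before* release
(u-plus convention), so the release gain of a spike is ``u_post * x_pre``
with the post-increment u.

Static basket-cell synapses bypass this machinery entirely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import NeuronParams, ReceptorParams, StpParams


@dataclass
class StpState:
    """Per-connection Tsodyks-Markram state (lazily updated)."""

    u: float
    x: float
    last_update: float  # ms, time of last presynaptic arrival

    @classmethod
    def resting(cls, params: StpParams, t: float = 0.0) -> "StpState":
        return cls(u=params.U, x=1.0, last_update=t)


def stp_decay(state: StpState, params: StpParams, t: float) -> StpState:
    """Relax (u, x) toward their resting values (U, 1) up to time ``t``."""
    dt = t - state.last_update
    if dt < 0:
        raise ValueError("time must not run backwards for STP state")
    if dt > 0:
        state.u = params.U + (state.u - params.U) * math.exp(-dt / params.tau_A)
        state.x = 1.0 + (state.x - 1.0) * math.exp(-dt / params.tau_D)
        state.last_update = t
    return state


def stp_on_spike(
    state: StpState, params: StpParams, t_spike_arrival: float
) -> tuple[StpState, float]:
    """Process one presynaptic spike arrival; return the release gain.

    Ordering at the spike instant: facilitation increment
    ``u += U*(1-u)``, then release gain ``u*x`` with the incremented u,
    then depression ``x -= u*x``.
    """
    state = stp_decay(state, params, t_spike_arrival)
    state.u = state.u + params.U * (1.0 - state.u)
    gain = state.u * state.x
    state.x = state.x - gain
    return state, gain


def conductance_on_spike(
    g_ampa: float, g_nmda: float, g_gaba: float,
    w_ampa: float, w_nmda: float, release_gain: float,
) -> tuple[float, float, float]:
    """Apply one delivered spike to the receptor conductances.

    Positive weights increment their matching glutamatergic channel;
    negative weights (learned disynaptic inhibition) are delivered as
    positive conductance on the GABA channel.
    """
    for w, chan in ((w_ampa, "ampa"), (w_nmda, "nmda")):
        inc = release_gain * abs(w)
        if w >= 0:
            if chan == "ampa":
                g_ampa += inc
            else:
                g_nmda += inc
        else:
            g_gaba += inc
    return g_ampa, g_nmda, g_gaba


def psp_peak_closed_form(
    g0: float,
    E_syn: float,
    V_hold: float,
    tau_syn: float,
    C_m: float = 280.0,
    g_L: float = 14.0,
) -> float:
    """Peak deflection (mV) of a double-exponential PSP on a passive
    linearized membrane.

    The conductance transient ``g0 * exp(-t/tau_syn)`` with driving force
    linearized at V_hold gives

        dV(t) = g0 (E_syn - V_hold) tau_s tau_m / (C_m (tau_m - tau_s))
                * (exp(-t/tau_m) - exp(-t/tau_s)),

    peaking at t* = tau_m tau_s ln(tau_m/tau_s)/(tau_m - tau_s). The
    degenerate case tau_m == tau_s uses the alpha-function limit
    dV(t) = g0 (E - V) t exp(-t/tau) / C_m, peaking at t* = tau.
    """
    tau_m = C_m / g_L
    drive = g0 * (E_syn - V_hold)
    if abs(tau_m - tau_syn) < 1e-9 * tau_m:
        # limit form: alpha function, peak value drive * tau / (C_m e)
        return drive * tau_m / (C_m * math.e)
    t_star = tau_m * tau_syn * math.log(tau_m / tau_syn) / (tau_m - tau_syn)
    amp = drive * tau_syn * tau_m / (C_m * (tau_m - tau_syn))
    return amp * (math.exp(-t_star / tau_m) - math.exp(-t_star / tau_syn))


def epsp_peak_closed_form(
    w_ampa: float,
    w_nmda: float,
    V_hold: float,
    neuron: NeuronParams | None = None,
    receptors: ReceptorParams | None = None,
) -> float:
    """Peak of the combined AMPA+NMDA PSP (linear superposition of the
    two double-exponential components, maximised numerically)."""
    neuron = neuron or NeuronParams()
    receptors = receptors or ReceptorParams()
    tau_m = neuron.tau_m
    t = np.linspace(0.0, 20.0 * tau_m, 4000)

    def component(g0: float, E: float, tau_s: float) -> np.ndarray:
        drive = g0 * (E - V_hold)
        if abs(tau_m - tau_s) < 1e-9 * tau_m:
            return drive * t * np.exp(-t / tau_m) / neuron.C_m
        amp = drive * tau_s * tau_m / (neuron.C_m * (tau_m - tau_s))
        return amp * (np.exp(-t / tau_m) - np.exp(-t / tau_s))

    dv = component(w_ampa, receptors.E_ampa, receptors.tau_ampa)
    dv = dv + component(w_nmda, receptors.E_nmda, receptors.tau_nmda)
    i = int(np.argmax(np.abs(dv)))
    return float(dv[i])


def stp_dense_oracle(
    spike_times: np.ndarray,
    params: StpParams,
    dt: float = 0.01,
    t_end: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Dense forward-Euler integration of the TM ODEs; independent oracle
    for the event-driven update. Returns per-spike (u, x) *release values*
    (u after increment, x before depletion), matching stp_on_spike.
    """
    spike_times = np.sort(np.asarray(spike_times, dtype=float))
    t_end = t_end if t_end is not None else (spike_times[-1] + dt)
    u, x = params.U, 1.0
    t = 0.0
    us, xs = [], []
    idx = 0
    n_steps = int(math.ceil(t_end / dt)) + 1
    for _ in range(n_steps):
        while idx < len(spike_times) and spike_times[idx] <= t + 1e-12:
            u = u + params.U * (1.0 - u)
            us.append(u)
            xs.append(x)
            x = x - u * x
            idx += 1
        u += dt * (params.U - u) / params.tau_A
        x += dt * (1.0 - x) / params.tau_D
        t += dt
    return np.asarray(us), np.asarray(xs)
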