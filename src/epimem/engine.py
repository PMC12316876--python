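"""Clock-driven simulation engine.

Wraps the compiled kernels with session orchestration: context/item cue
segments, the rate-based decision at the end of every trial, reward
delivery (100 ms re-stimulation of the selected odor, reward — a
kappa_reward window on the associative connections — arriving 250 ms
after the decision), bookkeeping snapshots, and spike recording.

Within-network attractor weights stay frozen throughout a session (the
within-network learning rate is identically zero); only their effective
efficacy changes through short-term augmentation/depression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _kernels as K
from .network import ASSOC, BP, PB, WITHIN_PP, WITHIN_PPL, NetworkModel
from .params import PROFILES, ExperimentConfig
from .task import (
    BLOCK_GAP,
    ItemStatusLedger,
    TaskSchedule,
    TrialResult,
    TrialSpec,
    decide_and_reward,
)


class SimulationError(RuntimeError):
    pass


@dataclass
class Snapshot:
    """State dump at a block boundary."""

    t: float
    label: str
    assoc_w_ampa: np.ndarray      # per associative connection, nS
    assoc_w_nmda: np.ndarray
    assoc_pre_pattern: np.ndarray
    assoc_post_pattern: np.ndarray
    assoc_pre_net: np.ndarray
    assoc_p: dict[str, np.ndarray]
    bias: np.ndarray              # per pyramidal neuron, pA
    bias_gid: np.ndarray
    u: np.ndarray                 # STP state of within-network connections
    x: np.ndarray

    def weight_table(self):
        """Tabular dump of the associative weights and their P traces
        (one row per between-network connection)."""
        import pandas as pd
        df = pd.DataFrame({
            "pre_pattern": self.assoc_pre_pattern,
            "post_pattern": self.assoc_post_pattern,
            "pre_network": self.assoc_pre_net,
            "w_ampa_nS": self.assoc_w_ampa,
            "w_nmda_nS": self.assoc_w_nmda,
        })
        for k, v in self.assoc_p.items():
            df[k] = v
        df["t_ms"] = self.t
        df["label"] = self.label
        return df


@dataclass
class SessionResult:
    schedule: TaskSchedule
    trials: list[TrialResult]
    spike_t: np.ndarray
    spike_gid: np.ndarray
    snapshots: list[Snapshot]
    trial_meta: list[dict] = field(default_factory=list)

    @property
    def scored_trials(self) -> list[TrialResult]:
        return [t for t in self.trials if t.scored]

    def save_raster(self, path: str, model: "NetworkModel",
                    sidecar_path: Optional[str] = None) -> None:
        """Write the spike raster (time_ms, gid) as CSV, plus an
        optional population-map sidecar (gid -> network/HC/MC/pattern)."""
        import pandas as pd
        pd.DataFrame({"time_ms": self.spike_t, "gid": self.spike_gid}
                     ).to_csv(path, index=False)
        if sidecar_path:
            pd.DataFrame({
                "gid": np.arange(model.n_neurons),
                "network": model.net_id,
                "hc": model.hc_id,
                "mc": model.mc_id,
                "pattern": model.pattern_id,
                "is_pyr": model.is_pyr.astype(int),
            }).to_csv(sidecar_path, index=False)


class Simulator:
    """Stateful simulator bound to one built network."""

    def __init__(self, model: NetworkModel, config: ExperimentConfig,
                 seed: int):
        self.model = model
        self.cfg = config
        prof = PROFILES[config.profile]
        n = config.neuron
        r = config.receptors
        bp = config.bcpnn
        self.dt = config.sim.dt
        self.t = 0.0
        self.step = 0
        N = model.n_neurons

        # neuron state
        self.V = np.full(N, n.E_L)
        self.I_w = np.zeros(N)
        self.I_beta = np.zeros(N)
        self.refr = np.zeros(N, np.int32)
        self.g_a = np.zeros(N)
        self.g_n = np.zeros(N)
        self.g_g = np.zeros(N)

        # connections: fold the scale profile into local copies
        self.w_a = model.w_ampa.copy()
        self.w_n = model.w_nmda.copy()
        within = (model.conn_class == WITHIN_PP) | (model.conn_class == WITHIN_PPL)
        self.w_a[within] *= prof.w_scale_within
        self.w_n[within] *= prof.w_scale_within
        self.w_a[model.conn_class == BP] *= prof.g_bp_scale
        self.wg_a = bp.w_gain_ampa
        self.wg_n = bp.w_gain_nmda

        self.delay_steps = np.maximum(
            np.round(model.delay_ms / self.dt).astype(np.int32), 1)
        S = int(self.delay_steps.max()) + 2
        self.buf = np.zeros((S, N, 3))

        E = model.n_connections
        self.u = np.full(E, config.stp.U)
        self.x = np.ones(E)
        self.t_stp = np.zeros(E)

        # BCPNN state
        p0 = max(config.f_bg_estimate / bp.f_max, bp.eps)
        self.p0 = p0
        self.z = np.full((N, 2), p0)
        self.e_i = np.full((N, 2), p0)
        self.p_i = np.full((N, 2), p0)
        self.t_tr = np.zeros(N)
        self.z_spk = np.full((N, 2), p0)
        self.e_spk = np.full((N, 2), p0)
        self.t_spk = np.zeros(N)
        self.eij = np.full((E, 2), p0 * p0)
        self.pij = np.full((E, 2), p0 * p0)
        self.pic = np.full((E, 2), p0)
        self.pjc = np.full((E, 2), p0)
        self.t_conn = np.zeros(E)
        bias0 = bp.beta_gain * PROFILES[config.profile].beta_gain_scale * np.log(p0)
        self.I_beta[model.is_pyr] = bias0

        # associative transpose CSR (in-edges per postsynaptic neuron)
        pre_all = np.repeat(np.arange(N), np.diff(model.indptr))
        amask = model.conn_class == ASSOC
        self.assoc_idx = np.nonzero(amask)[0].astype(np.int64)
        self.assoc_pre = pre_all[amask].astype(np.int32)
        self.assoc_post = model.post[amask].astype(np.int32)
        order = np.argsort(self.assoc_post, kind="stable")
        tin_counts = np.zeros(N + 1, np.int64)
        np.add.at(tin_counts, self.assoc_post + 1, 1)
        self.tin_ptr = np.cumsum(tin_counts)
        self.tin_idx = self.assoc_idx[order]
        self.tin_pre = self.assoc_pre[order]

        self.pyr_gids = np.nonzero(model.is_pyr)[0].astype(np.int32)
        self.within_idx = np.nonzero(within)[0]
        self.within_pre = pre_all[within].astype(np.int32)

        cap = int(2e6 + 50 * N * 60)
        self.rec_t = np.zeros(cap, np.float32)
        self.rec_gid = np.zeros(cap, np.int32)
        self.rec_count = np.zeros(1, np.int64)

        self.ablate_neg = False
        self._kappa = bp.kappa_normal
        self.grid_steps = max(int(round(config.sim.dt_traces * 10 / self.dt)), 1)

        # pattern -> assembly gid cache and per-pattern within connections
        self._assembly: dict[int, np.ndarray] = {}
        for p in model.patterns:
            self._assembly[p.pattern_id] = model.assembly_gids(p)
        self._within_of_pattern: dict[int, np.ndarray] = {}
        w_post = model.post[self.within_idx]
        for p in model.patterns:
            sel = ((model.pattern_id[self.within_pre] == p.pattern_id)
                   & (model.pattern_id[w_post] == p.pattern_id))
            self._within_of_pattern[p.pattern_id] = self.within_idx[sel]

        K.seed_rng(int(np.random.default_rng([seed, 0xE17]).integers(2**31)))

    # -- low-level ------------------------------------------------------
    def _kernel_args(self, stim_gids: np.ndarray, ctx_gids: np.ndarray,
                     kappa: float, n_steps: int):
        cfg = self.cfg
        n, r, st, bp, sp = (cfg.neuron, cfg.receptors, cfg.stp,
                            cfg.bcpnn, cfg.stimulus)
        lam_bg = self.pyr_gids.size * sp.r_bg / 1000.0 * self.dt
        lam_stim = stim_gids.size * sp.r_stim / 1000.0 * self.dt
        lam_ctx = ctx_gids.size * sp.r_stim / 1000.0 * self.dt
        f_max_khz = bp.f_max / 1000.0
        return dict(
            t0=self.t, n_steps=n_steps, step0=self.step, dt=self.dt,
            V=self.V, I_w=self.I_w, I_beta=self.I_beta, refr=self.refr,
            g_a=self.g_a, g_n=self.g_n, g_g=self.g_g,
            is_pyr=self.model.is_pyr,
            C_m=n.C_m, g_L=n.g_L, E_L=n.E_L, Delta_T=n.Delta_T, V_t=n.V_t,
            V_r=n.V_r, tref_steps=int(round(n.tau_ref / self.dt)), b=n.b,
            diw=np.exp(-self.dt / n.tau_Iw), cutoff=n.spike_cutoff,
            dec_a=np.exp(-self.dt / r.tau_ampa),
            dec_n=np.exp(-self.dt / r.tau_nmda),
            dec_g=np.exp(-self.dt / r.tau_gaba),
            E_a=r.E_ampa, E_n=r.E_nmda, E_g=r.E_gaba,
            indptr=self.model.indptr, post=self.model.post,
            delay_steps=self.delay_steps, cls=self.model.conn_class,
            w_a=self.w_a, w_n=self.w_n,
            u_arr=self.u, x_arr=self.x, t_stp=self.t_stp,
            U=st.U, tau_A=st.tau_A, tau_D=st.tau_D,
            z=self.z, e_i=self.e_i, p_i=self.p_i, t_tr=self.t_tr,
            z_spk=self.z_spk, e_spk=self.e_spk, t_spk=self.t_spk,
            eij=self.eij, pij=self.pij, pic=self.pic, pjc=self.pjc,
            t_conn=self.t_conn,
            tin_ptr=self.tin_ptr, tin_idx=self.tin_idx,
            tin_pre=self.tin_pre,
            lz_a=1.0 / bp.tau_z_ampa, lz_n=1.0 / bp.tau_z_nmda,
            le=1.0 / bp.tau_e,
            lp_neuron=bp.kappa_normal / bp.tau_p,
            lp_assoc=kappa / bp.tau_p, eps=bp.eps,
            zjump_a=1.0 / (f_max_khz * bp.tau_z_ampa),
            zjump_n=1.0 / (f_max_khz * bp.tau_z_nmda),
            wg_a=self.wg_a, wg_n=self.wg_n,
            m_pos_c2i=PROFILES[cfg.profile].assoc_scale_pos,
            m_neg_c2i=PROFILES[cfg.profile].assoc_scale_neg,
            m_pos_i2c=PROFILES[cfg.profile].assoc_scale_rev_pos,
            m_neg_i2c=PROFILES[cfg.profile].assoc_scale_rev_neg,
            net_id=self.model.net_id,
            beta_gain=bp.beta_gain * PROFILES[cfg.profile].beta_gain_scale,
            bias_comp=1 if bp.bias_component == "nmda" else 0,
            buf=self.buf,
            pyr_gids=self.pyr_gids, lam_bg=lam_bg, g_bg=sp.g_bg,
            stim_gids=stim_gids.astype(np.int32), lam_stim=lam_stim,
            g_stim=sp.g_stim * PROFILES[cfg.profile].g_stim_scale,
            stim2_gids=ctx_gids.astype(np.int32), lam_stim2=lam_ctx,
            g_stim2=sp.g_stim * PROFILES[cfg.profile].ctx_stim_scale,
            ablate_neg=self.ablate_neg,
            rec_t=self.rec_t, rec_gid=self.rec_gid,
            rec_count=self.rec_count, grid_steps=self.grid_steps,
        )

    def _propagate_all(self) -> None:
        bp = self.cfg.bcpnn
        K.propagate_all(
            self.t, self.model.is_pyr, self.z, self.e_i, self.p_i,
            self.t_tr, self.z_spk, self.e_spk, self.t_spk, self.I_beta,
            self.assoc_idx, self.assoc_pre, self.assoc_post,
            self.eij, self.pij, self.pic, self.pjc, self.t_conn,
            1.0 / bp.tau_z_ampa, 1.0 / bp.tau_z_nmda, 1.0 / bp.tau_e,
            bp.kappa_normal / bp.tau_p, self._kappa / bp.tau_p, bp.eps,
            bp.beta_gain * PROFILES[self.cfg.profile].beta_gain_scale,
            1 if bp.bias_component == "nmda" else 0,
        )

    def run_segment(self, duration: float,
                    stim_patterns: tuple[int, ...] = (),
                    ctx_patterns: tuple[int, ...] = (),
                    kappa: Optional[float] = None) -> None:
        """Advance by ``duration`` ms with the given cued item and
        context patterns (cued at the same rate; the scale profile may
        apply distinct conductance multipliers)."""
        kappa = self.cfg.bcpnn.kappa_normal if kappa is None else kappa
        if kappa != self._kappa:
            self._propagate_all()
            self._kappa = kappa
        n_steps = int(round(duration / self.dt))
        if n_steps == 0:
            return
        gids = (np.concatenate([self._assembly[p] for p in stim_patterns])
                if stim_patterns else np.empty(0, np.int32))
        cgids = (np.concatenate([self._assembly[p] for p in ctx_patterns])
                 if ctx_patterns else np.empty(0, np.int32))
        err = K.run_segment(**self._kernel_args(gids, cgids, kappa,
                                                n_steps))
        if err == K.ERR_NONFINITE:
            raise SimulationError(f"non-finite membrane state at t={self.t}")
        if err == K.ERR_RECORD_OVERFLOW:
            raise SimulationError("spike record capacity exceeded")
        self.t += n_steps * self.dt
        self.step += n_steps

    # -- measurements ---------------------------------------------------
    def spikes(self) -> tuple[np.ndarray, np.ndarray]:
        k = self.rec_count[0]
        return self.rec_t[:k].copy(), self.rec_gid[:k].copy()

    def assembly_rate(self, pattern: int, t0: float, t1: float) -> float:
        """Mean single-cell rate (Hz) of a pattern assembly in [t0, t1)."""
        gids = self._assembly[pattern]
        k = self.rec_count[0]
        ts = self.rec_t[:k]
        sel = (ts >= t0) & (ts < t1)
        count = np.isin(self.rec_gid[:k][sel], gids).sum()
        return 1000.0 * count / (gids.size * (t1 - t0))

    def effective_within_weight(self, pattern: int) -> float:
        """Mean effective within-network weight (nS) of a pattern's
        recurrent connections right now: static (AMPA+NMDA) weight times
        the instantaneous STP factor u*x."""
        idx = self._within_of_pattern[pattern]
        if idx.size == 0:
            return 0.0
        st = self.cfg.stp
        dt = self.t - self.t_stp[idx]
        u = st.U + (self.u[idx] - st.U) * np.exp(-dt / st.tau_A)
        x = 1.0 + (self.x[idx] - 1.0) * np.exp(-dt / st.tau_D)
        return float(np.mean((self.w_a[idx] + self.w_n[idx]) * u * x))

    def mean_bias(self, pattern: int) -> float:
        return float(self.I_beta[self._assembly[pattern]].mean())

    def assoc_weights(self) -> tuple[np.ndarray, np.ndarray]:
        """Current associative weights (AMPA, NMDA) per connection."""
        self._propagate_all()
        c = self.assoc_idx
        wa = self.wg_a * np.log(self.pij[c, 0]
                                / (self.pic[c, 0] * self.pjc[c, 0]))
        wn = self.wg_n * np.log(self.pij[c, 1]
                                / (self.pic[c, 1] * self.pjc[c, 1]))
        return wa, wn

    def snapshot(self, label: str) -> Snapshot:
        wa, wn = self.assoc_weights()
        pid = self.model.pattern_id
        return Snapshot(
            t=self.t, label=label,
            assoc_w_ampa=wa, assoc_w_nmda=wn,
            assoc_pre_pattern=pid[self.assoc_pre].copy(),
            assoc_post_pattern=pid[self.assoc_post].copy(),
            assoc_pre_net=self.model.net_id[self.assoc_pre].copy(),
            assoc_p={
                "P_ij_ampa": self.pij[self.assoc_idx, 0].copy(),
                "P_ij_nmda": self.pij[self.assoc_idx, 1].copy(),
                "P_i_ampa": self.pic[self.assoc_idx, 0].copy(),
                "P_j_ampa": self.pjc[self.assoc_idx, 0].copy(),
            },
            bias=self.I_beta[self.pyr_gids].copy(),
            bias_gid=self.pyr_gids.copy(),
            u=self.u[self.within_idx].copy(),
            x=self.x[self.within_idx].copy(),
        )


def run_session(
    model: NetworkModel,
    schedule: TaskSchedule,
    config: ExperimentConfig,
    seed: int,
    settle_ms: float = 500.0,
    ablate_disynaptic_at_assessment: bool = False,
) -> SessionResult:
    """Simulate one full session: settle, encoding blocks, assessment.

    Decisions are taken on-line from the trial-average firing rates of
    the two cued item assemblies; rewarded choices trigger the 100 ms
    re-stimulation and the delayed kappa_reward window.
    """
    sim = Simulator(model, config, seed)
    sp = config.stimulus
    bp = config.bcpnn
    ledger = ItemStatusLedger()
    results: list[TrialResult] = []
    snapshots: list[Snapshot] = []
    meta: list[dict] = []

    sim.run_segment(settle_ms)
    current_ctx: Optional[int] = None
    in_assessment = False

    for trial in schedule.trials:
        if trial.block == "assessment" and not in_assessment:
            in_assessment = True
            sim._propagate_all()
            snapshots.append(sim.snapshot("pre_assessment"))
            if ablate_disynaptic_at_assessment:
                sim.ablate_neg = True
        if trial.context != current_ctx:
            sim.run_segment(BLOCK_GAP)
            current_ctx = trial.context

        ctx = (current_ctx,)
        t_w1_start = sim.t
        sim.run_segment(sp.t_stim, (trial.item_first,), ctx)
        w1 = (t_w1_start, sim.t)
        sim.run_segment(sp.T_stim, (), ctx)
        t_w2_start = sim.t
        sim.run_segment(sp.t_stim, (trial.item_second,), ctx)
        w2 = (t_w2_start, sim.t)

        rates = {
            trial.item_first: sim.assembly_rate(trial.item_first, *w1),
            trial.item_second: sim.assembly_rate(trial.item_second, *w2),
        }
        res = decide_and_reward(trial, rates, ledger, schedule.variant,
                                config.decision_threshold)
        results.append(res)
        meta.append({
            "trial_index": trial.trial_index,
            "t_decision": sim.t,
            "within_w": {p: sim.effective_within_weight(p)
                         for p in trial.items},
            "bias": {p: sim.mean_bias(p) for p in trial.items},
            "recency": {p: ledger.recency(p) for p in trial.items},
        })

        remaining = schedule.trial_duration - 2 * sp.t_stim - sp.T_stim
        if res.rewarded_item is not None:
            sim.run_segment(sp.t_cue, (res.rewarded_item,), ctx)
            sim.run_segment(sp.reward_delay - sp.t_cue, (), ctx)
            sim.run_segment(bp.reward_duration, (), ctx,
                            kappa=bp.kappa_reward)
            used = sp.t_cue + (sp.reward_delay - sp.t_cue) + bp.reward_duration
            sim.run_segment(max(remaining - used, 0.0), (), ctx)
        else:
            sim.run_segment(remaining, (), ctx)

        ledger.record(trial.item_first, trial.context, trial.trial_index)
        ledger.record(trial.item_second, trial.context, trial.trial_index)

    sim._propagate_all()
    snapshots.append(sim.snapshot("end"))
    ts, gids = sim.spikes()
    return SessionResult(schedule=schedule, trials=results,
                         spike_t=ts, spike_gid=gids,
                         snapshots=snapshots, trial_meta=meta)
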