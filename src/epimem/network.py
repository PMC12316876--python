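"""Two-network architecture: layout, connectivity, delays, preloading.

Both the Item and the Context network are modular cortical layer 2/3
patches: a grid of hypercolumns (HCs), each containing minicolumns (MCs)
of 30 pyramidal cells plus 4 basket cells. Memory patterns (16 odor
items in the Item network, 2 contexts in the Context network) are
distributed, non-overlapping cell assemblies claiming exactly one
encoding MC per HC. Long-term attractor weights inside each network are
embedded by offline BCPNN training and frozen; plastic associative
connections between the networks are learned on-line during the task.

Connection classes
------------------
within_pp   pyr-pyr recurrent inside one MC          (cp 0.2, frozen)
within_ppl  pyr-pyr long-range within one network    (cp 0.2, frozen)
assoc       pyr-pyr between the networks             (cp 0.04, plastic)
pb / bp     pyr<->basket inside one HC               (cp 0.7, static)
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .params import (
    BcpnnParams,
    ConnectivityParams,
    ExperimentConfig,
    LayoutParams,
    NeuronParams,
    PreloadParams,
    ReceptorParams,
)
from .stp import epsp_peak_closed_form

# connection class codes
WITHIN_PP = 0
WITHIN_PPL = 1
ASSOC = 2
PB = 3
BP = 4

CLASS_NAMES = {WITHIN_PP: "within_pp", WITHIN_PPL: "within_ppl",
               ASSOC: "assoc", PB: "pb", BP: "bp"}

# weight classes produced by preloading
W_SAME_MC = "same_mc"            # same pattern, same HC (one MC)
W_SAME_PATTERN = "same_pattern"  # same pattern, different HC
W_DIFF_PATTERN = "diff_pattern"  # two different coding MCs
W_SILENT = "silent"              # at least one non-coding MC


class BuildError(RuntimeError):
    pass


@dataclass
class MemoryPattern:
    """A distributed assembly: one encoding MC per HC of its network."""

    pattern_id: int
    network: int            # 0 = Item, 1 = Context
    mc_in_hc: int           # encoding MC index inside every HC

    def mcs(self, layout: LayoutParams) -> list[tuple[int, int]]:
        return [(hc, self.mc_in_hc) for hc in range(layout.n_hc)]


@dataclass
class PreloadResult:
    """Outcome of offline attractor training (class-level weights, nS)."""

    weights: dict[str, tuple[float, float]]  # class -> (w_ampa, w_nmda)
    traces: dict[str, dict[str, float]]      # class -> P_i, P_j, P_ij per comp
    t_gap: float                              # calibrated silence, ms
    mean_epsp_within_hc: float                # mV, at E_L, first-spike STP


@dataclass
class NetworkModel:
    """Flat-array network representation consumed by the engine."""

    layout: LayoutParams
    n_networks: int
    # neuron arrays (gid-indexed)
    x: np.ndarray
    y: np.ndarray
    is_pyr: np.ndarray          # bool
    net_id: np.ndarray          # 0/1
    hc_id: np.ndarray           # HC index within its network
    mc_id: np.ndarray           # MC index within its network (-1 for baskets)
    pattern_id: np.ndarray      # pattern encoded by the cell's MC, -1 if none
    # connection arrays (CSR by presynaptic gid)
    indptr: np.ndarray
    post: np.ndarray
    delay_ms: np.ndarray
    conn_class: np.ndarray
    w_ampa: np.ndarray
    w_nmda: np.ndarray
    frozen: np.ndarray
    patterns: list[MemoryPattern] = field(default_factory=list)
    preload: Optional[PreloadResult] = None
    seed: Optional[int] = None
    ablated: list[str] = field(default_factory=list)

    @property
    def n_neurons(self) -> int:
        return self.x.size

    @property
    def n_connections(self) -> int:
        return self.post.size

    def pyr_gids(self, network: int) -> np.ndarray:
        return np.where(self.is_pyr & (self.net_id == network))[0]

    def assembly_gids(self, pattern: MemoryPattern) -> np.ndarray:
        """Pyramidal gids of a pattern's encoding MCs."""
        return np.where(
            self.is_pyr
            & (self.net_id == pattern.network)
            & (self.pattern_id == pattern.pattern_id)
        )[0]

    def validate(self) -> None:
        """Structural invariants: basket locality, delay positivity."""
        cfg = ConnectivityParams()
        if np.any(self.delay_ms < cfg.t_min_syn - 1e-9):
            raise BuildError("delay below the minimal synaptic delay")
        pre = np.repeat(np.arange(self.n_neurons), np.diff(self.indptr))
        bas = ~self.is_pyr[pre]
        if bas.any():
            same_hc = (self.hc_id[pre[bas]] == self.hc_id[self.post[bas]]) & (
                self.net_id[pre[bas]] == self.net_id[self.post[bas]]
            )
            if not same_hc.all():
                raise BuildError("basket cell with targets outside its HC")

    # -- serialization -------------------------------------------------
    def edge_table(self) -> pd.DataFrame:
        pre = np.repeat(np.arange(self.n_neurons), np.diff(self.indptr))
        return pd.DataFrame(
            {
                "pre": pre,
                "post": self.post,
                "class": [CLASS_NAMES[c] for c in self.conn_class],
                "delay_ms": self.delay_ms,
                "w_ampa_nS": self.w_ampa,
                "w_nmda_nS": self.w_nmda,
                "frozen": self.frozen,
            }
        )

    def layout_json(self) -> dict:
        return {
            "n_neurons": int(self.n_neurons),
            "coordinates_mm": np.c_[self.x, self.y].tolist(),
            "is_pyr": self.is_pyr.astype(int).tolist(),
            "net_id": self.net_id.tolist(),
            "hc_id": self.hc_id.tolist(),
            "mc_id": self.mc_id.tolist(),
            "pattern_id": self.pattern_id.tolist(),
            "patterns": [
                {"id": p.pattern_id, "network": p.network, "mc": p.mc_in_hc}
                for p in self.patterns
            ],
        }

    def save(self, edge_path: str, layout_path: str) -> None:
        self.edge_table().to_csv(edge_path, index=False)
        with open(layout_path, "w") as fh:
            json.dump(self.layout_json(), fh)


def sample_delay(
    pre_xy: np.ndarray,
    post_xy: np.ndarray,
    speed: float,
    rng: np.random.Generator,
    cfg: ConnectivityParams,
) -> np.ndarray:
    """Conduction + synaptic delay in ms for connection arrays.

    Mean = Euclidean distance / speed + t_min_syn; samples are normal
    with a relative SD of ``delay_rel_sd`` of the mean, clamped below at
    t_min_syn. ``speed`` is in m/s (= mm/ms).
    """
    d = np.linalg.norm(np.atleast_2d(pre_xy) - np.atleast_2d(post_xy), axis=1)
    mean = d / speed + cfg.t_min_syn
    samples = rng.normal(mean, cfg.delay_rel_sd * mean)
    return np.maximum(samples, cfg.t_min_syn)


def _hc_centres(layout: LayoutParams) -> np.ndarray:
    side = int(math.ceil(math.sqrt(layout.n_hc)))
    centres = []
    for i in range(layout.n_hc):
        r, c = divmod(i, side)
        centres.append((c * layout.grid_spacing, r * layout.grid_spacing))
    return np.asarray(centres)


def _scatter_in_disc(centre, radius, n, rng):
    r = radius * np.sqrt(rng.random(n))
    phi = rng.random(n) * 2 * np.pi
    return centre[0] + r * np.cos(phi), centre[1] + r * np.sin(phi)


def default_patterns(layout: LayoutParams, n_items: int, n_contexts: int
                     ) -> list[MemoryPattern]:
    """Non-overlapping patterns: item k claims MC k in every Item-network
    HC; context c claims MC c in every Context-network HC."""
    if n_items > layout.n_mc_per_hc or n_contexts > layout.n_mc_per_hc:
        raise BuildError("more patterns than minicolumns per hypercolumn")
    pats = [MemoryPattern(k, 0, k) for k in range(n_items)]
    pats += [MemoryPattern(n_items + c, 1, c) for c in range(n_contexts)]
    return pats


def _bernoulli_pairs(n_pre: int, n_post: int, p: float,
                     rng: np.random.Generator,
                     exclude_diag: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Sample directed edges between index ranges with probability p."""
    if p <= 0 or n_pre == 0 or n_post == 0:
        return np.empty(0, int), np.empty(0, int)
    # sample edge count then positions: equivalent to per-pair Bernoulli
    n_pairs = n_pre * n_post
    mask = rng.random(n_pairs) < p
    idx = np.nonzero(mask)[0]
    pre, post = np.divmod(idx, n_post)
    if exclude_diag:
        keep = pre != post
        pre, post = pre[keep], post[keep]
    return pre, post


def build_network(
    config: ExperimentConfig,
    seed: Optional[int] = None,
    patterns: Optional[list[MemoryPattern]] = None,
    n_items: int = 16,
    n_contexts: int = 2,
    do_preload: bool = True,
) -> NetworkModel:
    """Instantiate neurons, draw connectivity and delays, and (optionally)
    preload the within-network attractor weights.

    A seed is mandatory (reproducibility contract): the same seed and
    configuration always produce identical edge lists and weights.
    """
    if seed is None:
        raise BuildError("build_network requires an explicit seed")
    layout = config.layout
    conn = config.connectivity
    rng_master = np.random.default_rng([seed, 0xC0FFEE])
    rng_conn = np.random.default_rng(rng_master.integers(2**31, size=4))
    rng_delay = np.random.default_rng(rng_master.integers(2**31, size=4))
    rng_w = np.random.default_rng(rng_master.integers(2**31, size=4))

    n_networks = 2
    n_pyr_net = layout.n_pyr
    n_bas_net = layout.n_basket
    N = n_networks * (n_pyr_net + n_bas_net)

    x = np.zeros(N)
    y = np.zeros(N)
    is_pyr = np.zeros(N, bool)
    net_id = np.zeros(N, np.int32)
    hc_id = np.full(N, -1, np.int32)
    mc_id = np.full(N, -1, np.int32)
    pattern_id = np.full(N, -1, np.int32)

    patterns = patterns or default_patterns(layout, n_items, n_contexts)
    # pattern lookup: network -> mc -> pattern id
    pat_of_mc = {0: {}, 1: {}}
    for p in patterns:
        if p.mc_in_hc in pat_of_mc[p.network]:
            raise BuildError("overlapping memory patterns are not supported")
        pat_of_mc[p.network][p.mc_in_hc] = p.pattern_id

    centres = _hc_centres(layout)
    gid = 0
    for net in range(n_networks):
        x_off = net * layout.network_distance
        for hc in range(layout.n_hc):
            c = centres[hc] + np.array([x_off, 0.0])
            for mc in range(layout.n_mc_per_hc):
                for kind, count in (("pyr", layout.n_pyr_per_mc),
                                    ("bas", layout.n_basket_per_mc)):
                    sl = slice(gid, gid + count)
                    xs, ys = _scatter_in_disc(c, layout.hc_diameter / 2,
                                              count, rng_conn)
                    x[sl], y[sl] = xs, ys
                    is_pyr[sl] = kind == "pyr"
                    net_id[sl] = net
                    hc_id[sl] = hc
                    mc_id[sl] = mc if kind == "pyr" else -1
                    if kind == "pyr":
                        pattern_id[sl] = pat_of_mc[net].get(mc, -1)
                    gid += count

    pre_list, post_list, class_list = [], [], []

    pyr_gids = {net: np.where(is_pyr & (net_id == net))[0]
                for net in range(n_networks)}
    bas_gids = {net: np.where(~is_pyr & (net_id == net))[0]
                for net in range(n_networks)}

    # within-network pyr-pyr (recurrent within MC + long-range across MCs)
    for net in range(n_networks):
        g = pyr_gids[net]
        pre, post = _bernoulli_pairs(g.size, g.size, conn.cp_pp, rng_conn,
                                     exclude_diag=True)
        same_mc = mc_id[g[pre]] == mc_id[g[post]]
        same_hc = hc_id[g[pre]] == hc_id[g[post]]
        local = same_mc & same_hc
        # cp_pp applies within one MC; cp_ppl across MCs. They are equal in
        # the published table, so one Bernoulli draw covers both classes;
        # distinct probabilities would require separate draws.
        if abs(conn.cp_pp - conn.cp_ppl) > 1e-12:
            keep_long = rng_conn.random(pre.size) < conn.cp_ppl / conn.cp_pp
            keep = local | keep_long
            pre, post, local = pre[keep], post[keep], local[keep]
        pre_list.append(g[pre])
        post_list.append(g[post])
        class_list.append(np.where(local, WITHIN_PP, WITHIN_PPL))

    # associative pyr-pyr between networks, both directions
    from .params import PROFILES
    cp_ppa = conn.cp_ppa * PROFILES[config.profile].cp_ppa_scale
    for a, b in ((0, 1), (1, 0)):
        ga, gb = pyr_gids[a], pyr_gids[b]
        pre, post = _bernoulli_pairs(ga.size, gb.size, cp_ppa, rng_conn)
        pre_list.append(ga[pre])
        post_list.append(gb[post])
        class_list.append(np.full(pre.size, ASSOC))

    # pyr <-> basket within the local HC
    for net in range(n_networks):
        for hc in range(layout.n_hc):
            gp = pyr_gids[net][hc_id[pyr_gids[net]] == hc]
            gb = bas_gids[net][hc_id[bas_gids[net]] == hc]
            pre, post = _bernoulli_pairs(gp.size, gb.size, conn.cp_pb, rng_conn)
            pre_list.append(gp[pre]); post_list.append(gb[post])
            class_list.append(np.full(pre.size, PB))
            pre, post = _bernoulli_pairs(gb.size, gp.size, conn.cp_bp, rng_conn)
            pre_list.append(gb[pre]); post_list.append(gp[post])
            class_list.append(np.full(pre.size, BP))

    pre = np.concatenate(pre_list)
    post = np.concatenate(post_list).astype(np.int32)
    conn_class = np.concatenate(class_list).astype(np.int8)

    # delays
    delay = np.empty(pre.size)
    between = conn_class == ASSOC
    xy = np.c_[x, y]
    if between.any():
        delay[between] = sample_delay(xy[pre[between]], xy[post[between]],
                                      conn.speed_myel, rng_delay, conn)
    within = ~between
    delay[within] = sample_delay(xy[pre[within]], xy[post[within]],
                                 conn.speed, rng_delay, conn)

    # sort into CSR by presynaptic gid
    order = np.lexsort((post, pre))
    pre, post = pre[order], post[order]
    conn_class, delay = conn_class[order], delay[order]
    indptr = np.zeros(N + 1, np.int64)
    np.add.at(indptr, pre + 1, 1)
    indptr = np.cumsum(indptr)

    w_ampa = np.zeros(pre.size, np.float64)
    w_nmda = np.zeros(pre.size, np.float64)
    frozen = np.zeros(pre.size, bool)
    w_ampa[conn_class == PB] = conn.g_pb
    w_ampa[conn_class == BP] = conn.g_bp
    frozen[(conn_class == PB) | (conn_class == BP)] = True

    model = NetworkModel(
        layout=layout, n_networks=n_networks, x=x, y=y, is_pyr=is_pyr,
        net_id=net_id, hc_id=hc_id, mc_id=mc_id, pattern_id=pattern_id,
        indptr=indptr, post=post, delay_ms=delay, conn_class=conn_class,
        w_ampa=w_ampa, w_nmda=w_nmda, frozen=frozen,
        patterns=patterns, seed=seed,
    )
    if do_preload:
        result = preload_attractors(config, n_items=n_items)
        assign_preloaded_weights(model, result, rng_w,
                                 jitter=config.preload.weight_jitter)
    model.validate()
    return model


# ---------------------------------------------------------------------------
# offline attractor preloading (mean-field BCPNN training)
# ---------------------------------------------------------------------------

def _propagate_stage(y0, lam, sources, T):
    """Propagate y' = lam*(s(t) - y) over [0, T] where s(t) is a sum of
    exponentials [(amp, rate)]. Returns (y(T), expression of y(t),
    integral of y over [0, T])."""
    const = 0.0
    terms = []
    for amp, rate in sources:
        if rate == 0.0:
            const += amp
        else:
            if abs(lam - rate) < 1e-12 * lam:
                rate = rate * (1.0 + 1e-9)
            terms.append((amp * lam / (lam - rate), rate))
    homog = y0 - const - sum(k for k, _ in terms)
    terms_full = terms + [(homog, lam)]
    yT = const + sum(k * math.exp(-r * T) for k, r in terms_full)
    int_y = const * T + sum(
        k * (1.0 - math.exp(-r * T)) / r for k, r in terms_full if r > 0
    )
    return yT, [(const, 0.0)] + terms_full, int_y


class _MeanFieldZEP:
    """One cascade Z -> E -> P under piecewise-constant drive.

    ``P_mean`` averages P over the intervals stepped with
    ``accumulate=True`` (used over the final training cycle, which
    removes the dependence on pattern training order).
    """

    def __init__(self, tau_z, tau_e, tau_p, kappa, eps):
        self.lz, self.le = 1.0 / tau_z, 1.0 / tau_e
        self.lp = kappa / tau_p
        self.eps = eps
        self.Z = self.E = self.P = eps
        self._int_p = 0.0
        self._int_t = 0.0

    def step(self, drive, T, accumulate=False):
        z_inf = drive + self.eps
        a = self.Z - z_inf
        self.Z = z_inf + a * math.exp(-self.lz * T)
        z_expr = [(z_inf, 0.0), (a, self.lz)]
        self.E, e_expr, _ = _propagate_stage(self.E, self.le, z_expr, T)
        self.P, _, int_p = _propagate_stage(self.P, self.lp, e_expr, T)
        if accumulate:
            self._int_p += int_p
            self._int_t += T
        return z_expr, e_expr

    @property
    def P_mean(self):
        return self._int_p / self._int_t if self._int_t > 0 else self.P


class _MeanFieldJoint:
    """E_ij/P_ij cascade driven by the product of two Z expressions,
    optionally plus a shared-spike covariance term while co-active."""

    def __init__(self, tau_e, tau_p, kappa, eps):
        self.le = 1.0 / tau_e
        self.lp = kappa / tau_p
        self.E = self.P = eps * eps
        self._int_p = 0.0
        self._int_t = 0.0

    def step(self, zi_expr, zj_expr, cov, T, accumulate=False):
        prod = {}
        for ai, ri in zi_expr:
            for aj, rj in zj_expr:
                r = ri + rj
                prod[r] = prod.get(r, 0.0) + ai * aj
        prod[0.0] = prod.get(0.0, 0.0) + cov
        sources = [(a, r) for r, a in prod.items()]
        self.E, e_expr, _ = _propagate_stage(self.E, self.le, sources, T)
        self.P, _, int_p = _propagate_stage(self.P, self.lp, e_expr, T)
        if accumulate:
            self._int_p += int_p
            self._int_t += T

    @property
    def P_mean(self):
        return self._int_p / self._int_t if self._int_t > 0 else self.P


def _campbell_cov(f_khz: float, f_max_khz: float, tau_z: float,
                  c_share: float) -> float:
    """Covariance of the Z traces of two cells sharing a fraction
    ``c_share`` of a common Poisson train at rate f (Campbell's theorem,
    exponential kernels of unit area 1/f_max)."""
    return c_share * f_khz / (2.0 * f_max_khz**2 * tau_z)


def preload_attractors(
    config: ExperimentConfig,
    n_items: int = 16,
    t_gap: Optional[float] = None,
) -> PreloadResult:
    """Run the offline training protocol at minicolumn level and return
    class weights.

    Patterns are cued one at a time (``t_active`` at ``f_train``) in a
    repeating cycle over ``n_epochs`` epochs with full plasticity
    (kappa = 1); the silence between presentations (``t_gap``) sets the
    background sparsity of the P traces and is calibrated by root
    finding so the within-HC population-mean EPSP at rest matches
    ``preload.target_epsp`` (skipped when a ``t_gap`` is given or the
    target is None).
    """
    pre = config.preload
    if t_gap is None:
        if pre.target_epsp is None:
            t_gap = pre.t_gap
        else:
            t_gap = _calibrate_gap(config, n_items)
    return _preload_with_gap(config, n_items, t_gap)


def _preload_with_gap(config: ExperimentConfig, n_items: int,
                      t_gap: float) -> PreloadResult:
    pre = config.preload
    bp = config.bcpnn
    rec = config.receptors
    f = pre.f_train / 1000.0       # kHz
    fmax = bp.f_max / 1000.0
    z_hi = f / fmax                # mean Z of an active cell (above eps)
    comps = {"ampa": bp.tau_z_ampa, "nmda": bp.tau_z_nmda}

    result_traces: dict[str, dict[str, float]] = {}
    weights: dict[str, tuple[float, float]] = {}
    per_comp_w: dict[str, dict[str, float]] = {c: {} for c in comps}

    for comp, tau_z in comps.items():
        cov = _campbell_cov(f, fmax, tau_z, pre.c_share)
        # marginal cascades: active-pattern unit and silent unit
        u_act = _MeanFieldZEP(tau_z, bp.tau_e, bp.tau_p, 1.0, bp.eps)
        u_oth = _MeanFieldZEP(tau_z, bp.tau_e, bp.tau_p, 1.0, bp.eps)
        u_sil = _MeanFieldZEP(tau_z, bp.tau_e, bp.tau_p, 1.0, bp.eps)
        joint = {
            W_SAME_MC: _MeanFieldJoint(bp.tau_e, bp.tau_p, 1.0, bp.eps),
            W_SAME_PATTERN: _MeanFieldJoint(bp.tau_e, bp.tau_p, 1.0, bp.eps),
            W_DIFF_PATTERN: _MeanFieldJoint(bp.tau_e, bp.tau_p, 1.0, bp.eps),
            W_SILENT: _MeanFieldJoint(bp.tau_e, bp.tau_p, 1.0, bp.eps),
        }
        # cycle: pattern 0 active, then the other n-1 patterns + gaps.
        # Tracked units: "act" = pattern 0, "oth" = pattern 1, "sil" = a
        # never-active cell. One epoch = n_items presentations; by
        # symmetry all patterns share the "act" statistics.
        for epoch in range(pre.n_epochs):
            last = epoch == pre.n_epochs - 1
            for k in range(n_items):
                for drive_T in ((1, pre.t_active), (0, t_gap)):
                    active_phase, T = drive_T
                    if T <= 0:
                        continue
                    d_act = z_hi if (active_phase and k == 0) else 0.0
                    d_oth = z_hi if (active_phase and k == 1) else 0.0
                    za, _ = u_act.step(d_act, T, accumulate=last)
                    zo, _ = u_oth.step(d_oth, T, accumulate=last)
                    zs, _ = u_sil.step(0.0, T, accumulate=last)
                    cv = cov if (active_phase and k == 0) else 0.0
                    joint[W_SAME_MC].step(za, za, cv, T, accumulate=last)
                    joint[W_SAME_PATTERN].step(za, za, 0.0, T, accumulate=last)
                    joint[W_DIFF_PATTERN].step(za, zo, 0.0, T, accumulate=last)
                    joint[W_SILENT].step(za, zs, 0.0, T, accumulate=last)
        P_act, P_oth, P_sil = u_act.P_mean, u_oth.P_mean, u_sil.P_mean
        for name, j in joint.items():
            P_i = P_act
            P_j = P_sil if name == W_SILENT else (
                P_oth if name == W_DIFF_PATTERN else P_act)
            w_gain = bp.w_gain_ampa if comp == "ampa" else bp.w_gain_nmda
            w = w_gain * math.log(max(j.P_mean, 1e-300) / (P_i * P_j))
            per_comp_w[comp][name] = w
            result_traces.setdefault(name, {})[f"P_i_{comp}"] = P_i
            result_traces[name][f"P_j_{comp}"] = P_j
            result_traces[name][f"P_ij_{comp}"] = j.P

    for name in (W_SAME_MC, W_SAME_PATTERN, W_DIFF_PATTERN, W_SILENT):
        weights[name] = (per_comp_w["ampa"][name], per_comp_w["nmda"][name])

    # population-mean within-HC EPSP at rest: first spike from rest, STP
    # release gain (U + U(1-U)) * 1, combined AMPA+NMDA closed form.
    gain0 = first_spike_release_gain(config.stp.U)
    wa, wn = weights[W_SAME_MC]
    epsp = epsp_peak_closed_form(
        gain0 * max(wa, 0.0), gain0 * max(wn, 0.0),
        V_hold=config.neuron.E_L, neuron=config.neuron, receptors=rec,
    )
    return PreloadResult(weights=weights, traces=result_traces,
                         t_gap=t_gap, mean_epsp_within_hc=epsp)


def first_spike_release_gain(U: float) -> float:
    """Release gain of the first spike from rest (u-plus convention):
    u = U + U(1-U) applied to full resources x = 1."""
    return (U + U * (1.0 - U)) * 1.0


def _calibrate_gap(config: ExperimentConfig, n_items: int) -> float:
    """Root-find the inter-pattern silence so the within-HC mean EPSP
    matches the preload target."""
    from scipy.optimize import brentq

    target = config.preload.target_epsp

    def f(gap):
        r = _preload_with_gap(config, n_items, gap)
        return r.mean_epsp_within_hc - target

    # EPSP rises with silence while the duty cycle exceeds ~eps and falls
    # again beyond it, so bracket the ascending branch via a coarse scan.
    gaps = np.geomspace(200.0, 80000.0, 14)
    vals = np.array([f(g) for g in gaps])
    i_max = int(np.argmax(vals))
    if vals[i_max] < 0:
        return float(gaps[i_max])  # target unreachable; best effort
    below = np.nonzero(vals[: i_max + 1] < 0)[0]
    if below.size == 0:
        return float(gaps[0])
    lo, hi = gaps[below[-1]], gaps[i_max]
    return float(brentq(f, lo, hi, xtol=1.0))


def assign_preloaded_weights(
    model: NetworkModel,
    result: PreloadResult,
    rng: np.random.Generator,
    jitter: float = 0.0,
) -> NetworkModel:
    """Write frozen within-network weights onto the connection arrays.

    Each within-network pyr-pyr connection receives its class weight with
    multiplicative Gaussian jitter (relative sd ``jitter``) emulating the
    finite-sampling spread of per-synapse spiking training.
    """
    pre = np.repeat(np.arange(model.n_neurons), np.diff(model.indptr))
    sel = (model.conn_class == WITHIN_PP) | (model.conn_class == WITHIN_PPL)
    idx = np.nonzero(sel)[0]
    p_pre = model.pattern_id[pre[idx]]
    p_post = model.pattern_id[model.post[idx]]
    same_mc = (model.mc_id[pre[idx]] == model.mc_id[model.post[idx]]) & (
        model.hc_id[pre[idx]] == model.hc_id[model.post[idx]])

    klass = np.full(idx.size, 3, np.int8)  # 3 = silent
    coding = (p_pre >= 0) & (p_post >= 0)
    klass[coding & (p_pre != p_post)] = 2
    klass[coding & (p_pre == p_post) & ~same_mc] = 1
    klass[coding & (p_pre == p_post) & same_mc] = 0
    names = [W_SAME_MC, W_SAME_PATTERN, W_DIFF_PATTERN, W_SILENT]
    wa = np.array([result.weights[n][0] for n in names])
    wn = np.array([result.weights[n][1] for n in names])
    scale = 1.0 + jitter * rng.standard_normal(idx.size) if jitter > 0 else 1.0
    model.w_ampa[idx] = wa[klass] * scale
    model.w_nmda[idx] = wn[klass] * scale
    model.frozen[idx] = True
    model.preload = result
    return model


def ablate(model: NetworkModel, what: str) -> NetworkModel:
    """Sever a connection class in place.

    ``associative_disynaptic_inhibition`` zeroes all negative-valued
    between-network weights and marks them frozen at zero (excluded from
    further learning); positive associative weights are untouched.
    """
    if what != "associative_disynaptic_inhibition":
        raise ValueError(f"unknown ablation key {what!r}")
    sel = model.conn_class == ASSOC
    neg_a = sel & (model.w_ampa < 0)
    neg_n = sel & (model.w_nmda < 0)
    model.w_ampa[neg_a] = 0.0
    model.w_nmda[neg_n] = 0.0
    model.ablated.append(what)
    return model
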