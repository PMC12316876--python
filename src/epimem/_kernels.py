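"""Numba kernels for the clock-driven network simulation.

Design notes (mirrored in the engine module):

* membrane: exponential-Euler for the conductance/linear part (the decay
  factor uses a 3rd-order Taylor expansion of exp(-x), accurate to ~1e-8
  for the step sizes that occur), forward-Euler for the AdEx upstroke;
* delays: per-step ring buffer of conductance increments, delays rounded
  to the nearest step;
* STP: exact event-driven (u, x) updates keyed to spike *arrival* times;
* BCPNN: per-neuron Z/E/P cascades (bias) and, per associative
  connection, the full trace set E_ij/P_ij *and* local copies of
  P_i/P_j evolved under the connection's own learning-rate timeline
  (so reward windows modulate all three probability traces of a
  synapse, as in the published module). Everything is propagated with
  closed-form multi-exponential solutions at spike events,
  learning-rate boundaries and a 10 ms bookkeeping grid. Spikes enter Z
  as unit-area impulses 1/(f_max tau_Z);
* associative weights are evaluated from the connection's P traces on
  demand when the presynaptic spike is emitted.

Connection class codes match ``epimem.network``:
0 within_pp, 1 within_ppl, 2 assoc, 3 pb, 4 bp.
"""

import numpy as np
from numba import njit

ERR_NONE = 0
ERR_NONFINITE = 1
ERR_RECORD_OVERFLOW = 2


@njit(cache=True, inline="always")
def _fast_decay(x):
    # exp(-x) for small positive x (x = dt*G/C_m <~ 0.05)
    return 1.0 - x * (1.0 - 0.5 * x * (1.0 - x / 3.0))


@njit(cache=True, inline="always")
def _zep_propagate(z, e, p, dt, lz, le, lp, eps):
    """Closed-form propagation of one neuron cascade over dt (no spikes)."""
    ez = np.exp(-lz * dt)
    ee = np.exp(-le * dt)
    a = z - eps
    z1 = eps + a * ez
    Ae = a * le / (le - lz)
    Be = e - eps - Ae
    e1 = eps + Ae * ez + Be * ee
    if lp > 0.0:
        Ap = Ae * lp / (lp - lz)
        Bp = Be * lp / (lp - le)
        p1 = eps + Ap * ez + Bp * ee + (p - eps - Ap - Bp) * np.exp(-lp * dt)
    else:
        p1 = p
    return z1, e1, p1


@njit(cache=True, inline="always")
def _conn_update_comp(c, comp, i, j, t, z_spk, e_spk, t_spk,
                      eij, pij, pic, pjc, t_from,
                      lz, le, lp, eps):
    """Advance one receptor component of one associative connection from
    ``t_from`` to ``t``.

    Both endpoint Z traces decay freely over the interval (spikes of
    either endpoint trigger a connection update, so none lie inside).
    E_ij is driven by Z_i * Z_j; P_ij by E_ij; the connection-local
    P_i/P_j by the endpoint eligibility traces E_i/E_j, all with the
    connection's learning rate lp = kappa/tau_P.
    """
    dt = t - t_from
    # endpoint state at the interval start, decayed from the last spike
    # (the triggering endpoint usually has zero elapsed time: skip exps)
    dzi = t_from - t_spk[i]
    dzj = t_from - t_spk[j]
    cez = le / (le - lz)
    ai0 = (z_spk[i, comp] - eps)
    aj0 = (z_spk[j, comp] - eps)
    if dzi > 0.0:
        czi = np.exp(-lz * dzi)
        cei = np.exp(-le * dzi)
    else:
        czi = 1.0
        cei = 1.0
    if dzj > 0.0:
        czj = np.exp(-lz * dzj)
        cej = np.exp(-le * dzj)
    else:
        czj = 1.0
        cej = 1.0
    zi0 = eps + ai0 * czi
    zj0 = eps + aj0 * czj
    Ai = ai0 * cez * czi
    Bi = (e_spk[i, comp] - eps - ai0 * cez) * cei
    Aj = aj0 * cez * czj
    Bj = (e_spk[j, comp] - eps - aj0 * cez) * cej

    e1 = np.exp(-lz * dt)
    e2 = e1 * e1
    ee = np.exp(-le * dt)

    # E_ij: source Z_i*Z_j = eps^2 + eps(ai+aj) e^-lz t + ai aj e^-2lz t
    ai = zi0 - eps
    aj = zj0 - eps
    c0 = eps * eps
    s1 = eps * (ai + aj)
    s2 = ai * aj
    A1 = s1 * cez
    A2 = s2 * le / (le - 2.0 * lz)
    B = eij[c, comp] - c0 - A1 - A2
    eij[c, comp] = c0 + A1 * e1 + A2 * e2 + B * ee

    if lp > 0.0:
        ep = np.exp(-lp * dt)
        A1p = A1 * lp / (lp - lz)
        A2p = A2 * lp / (lp - 2.0 * lz)
        Bp = B * lp / (lp - le)
        pij[c, comp] = (c0 + A1p * e1 + A2p * e2 + Bp * ee
                        + (pij[c, comp] - c0 - A1p - A2p - Bp) * ep)
        # connection-local P_i / P_j driven by E_i(t) / E_j(t)
        cp = lp / (lp - lz)
        ce = lp / (lp - le)
        Aip = Ai * cp
        Bip = Bi * ce
        pic[c, comp] = (eps + Aip * e1 + Bip * ee
                        + (pic[c, comp] - eps - Aip - Bip) * ep)
        Ajp = Aj * cp
        Bjp = Bj * ce
        pjc[c, comp] = (eps + Ajp * e1 + Bjp * ee
                        + (pjc[c, comp] - eps - Ajp - Bjp) * ep)


@njit(cache=True, inline="always")
def _conn_update(c, i, j, t, z_spk, e_spk, t_spk, eij, pij, pic, pjc,
                 t_conn, lz_a, lz_n, le, lp, eps):
    t_from = t_conn[c]
    if t - t_from <= 0.0:
        return
    _conn_update_comp(c, 0, i, j, t, z_spk, e_spk, t_spk,
                      eij, pij, pic, pjc, t_from, lz_a, le, lp, eps)
    _conn_update_comp(c, 1, i, j, t, z_spk, e_spk, t_spk,
                      eij, pij, pic, pjc, t_from, lz_n, le, lp, eps)
    t_conn[c] = t


@njit(cache=True, inline="always")
def _stp_release(u_arr, x_arr, t_arr, c, t_arrival, U, tau_A, tau_D):
    """Advance TM state of connection c to t_arrival and release."""
    dt = t_arrival - t_arr[c]
    u = U + (u_arr[c] - U) * np.exp(-dt / tau_A)
    x = 1.0 + (x_arr[c] - 1.0) * np.exp(-dt / tau_D)
    u = u + U * (1.0 - u)
    gain = u * x
    x = x - gain
    u_arr[c] = u
    x_arr[c] = x
    t_arr[c] = t_arrival
    return gain


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def propagate_all(
    t,
    # neuron trace state
    is_pyr, z, e_i, p_i, t_tr, z_spk, e_spk, t_spk, I_beta,
    # assoc connection trace state
    assoc_idx, assoc_pre, assoc_post, eij, pij, pic, pjc, t_conn,
    # constants
    lz_a, lz_n, le, lp_neuron, lp_assoc, eps, beta_gain, bias_comp,
):
    """Bring every neuron cascade and associative connection to time t
    (used at learning-rate boundaries and before snapshots)."""
    N = z.shape[0]
    for n in range(N):
        if not is_pyr[n]:
            continue
        dt = t - t_tr[n]
        if dt > 0.0:
            z[n, 0], e_i[n, 0], p_i[n, 0] = _zep_propagate(
                z[n, 0], e_i[n, 0], p_i[n, 0], dt, lz_a, le, lp_neuron, eps)
            z[n, 1], e_i[n, 1], p_i[n, 1] = _zep_propagate(
                z[n, 1], e_i[n, 1], p_i[n, 1], dt, lz_n, le, lp_neuron, eps)
            t_tr[n] = t
        I_beta[n] = beta_gain * np.log(p_i[n, bias_comp])
    for k in range(assoc_idx.shape[0]):
        _conn_update(assoc_idx[k], assoc_pre[k], assoc_post[k], t,
                     z_spk, e_spk, t_spk, eij, pij, pic, pjc, t_conn,
                     lz_a, lz_n, le, lp_assoc, eps)


@njit(cache=True)
def run_segment(
    # timing
    t0, n_steps, step0, dt,
    # neuron state
    V, I_w, I_beta, refr, g_a, g_n, g_g, is_pyr,
    # neuron params
    C_m, g_L, E_L, Delta_T, V_t, V_r, tref_steps, b, diw, cutoff,
    # receptor params
    dec_a, dec_n, dec_g, E_a, E_n, E_g,
    # connectivity (CSR by pre)
    indptr, post, delay_steps, cls, w_a, w_n,
    # STP state + params
    u_arr, x_arr, t_stp, U, tau_A, tau_D,
    # BCPNN neuron traces
    z, e_i, p_i, t_tr, z_spk, e_spk, t_spk,
    # BCPNN assoc connection traces + transpose CSR (assoc in-edges)
    eij, pij, pic, pjc, t_conn, tin_ptr, tin_idx, tin_pre,
    # BCPNN params
    lz_a, lz_n, le, lp_neuron, lp_assoc, eps,
    zjump_a, zjump_n, wg_a, wg_n,
    m_pos_c2i, m_neg_c2i, m_pos_i2c, m_neg_i2c, net_id, beta_gain, bias_comp,
    # delivery ring buffer
    buf,
    # noise / stimulation
    pyr_gids, lam_bg, g_bg, stim_gids, lam_stim, g_stim,
    stim2_gids, lam_stim2, g_stim2,
    # behaviour switches
    ablate_neg,
    # recording
    rec_t, rec_gid, rec_count, grid_steps,
):
    """Advance the network by ``n_steps`` steps of ``dt`` ms from ``t0``.

    The learning rate (lp_assoc = kappa/tau_P) is constant within a
    segment; the engine splits runs at reward-window boundaries.
    Returns an error code (0 ok).
    """
    N = V.shape[0]
    S = buf.shape[0]
    n_pyr = pyr_gids.shape[0]
    n_stim = stim_gids.shape[0]
    n_stim2 = stim2_gids.shape[0]
    nrec = rec_count[0]
    cap = rec_t.shape[0]

    for s in range(n_steps):
        t = t0 + s * dt
        slot = (step0 + s) % S

        # background noise: aggregated Poisson events over all pyramidals
        if lam_bg > 0.0 and n_pyr > 0:
            k = np.random.poisson(lam_bg)
            for _ in range(k):
                g_a[pyr_gids[np.random.randint(n_pyr)]] += g_bg
            k = np.random.poisson(lam_bg)
            for _ in range(k):
                g_g[pyr_gids[np.random.randint(n_pyr)]] += g_bg
        # specific stimulation (item cues, then the context cue)
        if lam_stim > 0.0 and n_stim > 0:
            k = np.random.poisson(lam_stim)
            for _ in range(k):
                g_a[stim_gids[np.random.randint(n_stim)]] += g_stim
        if lam_stim2 > 0.0 and n_stim2 > 0:
            k = np.random.poisson(lam_stim2)
            for _ in range(k):
                g_a[stim2_gids[np.random.randint(n_stim2)]] += g_stim2

        for n in range(N):
            # delayed deliveries arriving this step
            g_a[n] += buf[slot, n, 0]
            g_n[n] += buf[slot, n, 1]
            g_g[n] += buf[slot, n, 2]
            buf[slot, n, 0] = 0.0
            buf[slot, n, 1] = 0.0
            buf[slot, n, 2] = 0.0

            I_w[n] *= diw
            ga = g_a[n]
            gn = g_n[n]
            gg = g_g[n]

            spiked = False
            if refr[n] > 0:
                refr[n] -= 1
                V[n] = V_r
            else:
                v = V[n]
                arg = (v - V_t) / Delta_T
                if arg > 20.0:
                    arg = 20.0
                I_exp = g_L * Delta_T * np.exp(arg)
                G = g_L + ga + gn + gg
                num = (g_L * E_L + ga * E_a + gn * E_n + gg * E_g
                       + I_exp + I_beta[n] - I_w[n])
                v_inf = num / G
                v = v_inf + (v - v_inf) * _fast_decay(dt * G / C_m)
                if v > cutoff:
                    spiked = True
                    v = V_r
                    refr[n] = tref_steps
                    I_w[n] += b
                elif not np.isfinite(v):
                    return ERR_NONFINITE
                V[n] = v

            g_a[n] = ga * dec_a
            g_n[n] = gn * dec_n
            g_g[n] = gg * dec_g

            if spiked:
                if nrec >= cap:
                    rec_count[0] = nrec
                    return ERR_RECORD_OVERFLOW
                rec_t[nrec] = t
                rec_gid[nrec] = n
                nrec += 1

                if is_pyr[n]:
                    # bring own cascade to t (z jump applied after the
                    # outgoing weights/trace updates below)
                    dtr = t - t_tr[n]
                    if dtr > 0.0:
                        z[n, 0], e_i[n, 0], p_i[n, 0] = _zep_propagate(
                            z[n, 0], e_i[n, 0], p_i[n, 0], dtr,
                            lz_a, le, lp_neuron, eps)
                        z[n, 1], e_i[n, 1], p_i[n, 1] = _zep_propagate(
                            z[n, 1], e_i[n, 1], p_i[n, 1], dtr,
                            lz_n, le, lp_neuron, eps)
                        t_tr[n] = t

                # outgoing deliveries
                for c in range(indptr[n], indptr[n + 1]):
                    j = post[c]
                    cc = cls[c]
                    arrive = (step0 + s + delay_steps[c]) % S
                    if cc >= 3:  # static basket loops
                        w = w_a[c]
                        if w >= 0.0:
                            buf[arrive, j, 0] += w
                        else:
                            buf[arrive, j, 2] += -w
                        continue
                    t_arr_ms = t + delay_steps[c] * dt
                    gain = _stp_release(u_arr, x_arr, t_stp, c, t_arr_ms,
                                        U, tau_A, tau_D)
                    if cc == 2:
                        # associative: propagate traces to t, then weight
                        _conn_update(c, n, j, t, z_spk, e_spk, t_spk,
                                     eij, pij, pic, pjc, t_conn,
                                     lz_a, lz_n, le, lp_assoc, eps)
                        wa = wg_a * np.log(pij[c, 0]
                                           / (pic[c, 0] * pjc[c, 0]))
                        wn = wg_n * np.log(pij[c, 1]
                                           / (pic[c, 1] * pjc[c, 1]))
                        if ablate_neg:
                            if wa < 0.0:
                                wa = 0.0
                            if wn < 0.0:
                                wn = 0.0
                        # direction- and sign-dependent gain multipliers
                        # (scale-profile recalibration; all 1 at full
                        # scale)
                        if net_id[n] == 1:
                            m_pos = m_pos_c2i
                            m_neg = m_neg_c2i
                        else:
                            m_pos = m_pos_i2c
                            m_neg = m_neg_i2c
                        wa *= m_pos if wa >= 0.0 else m_neg
                        wn *= m_pos if wn >= 0.0 else m_neg
                    else:
                        wa = w_a[c]
                        wn = w_n[c]
                    wa *= gain
                    wn *= gain
                    if wa >= 0.0:
                        buf[arrive, j, 0] += wa
                    else:
                        buf[arrive, j, 2] += -wa
                    if wn >= 0.0:
                        buf[arrive, j, 1] += wn
                    else:
                        buf[arrive, j, 2] += -wn

                if is_pyr[n]:
                    # incoming associative traces see the post-spike jump
                    for q in range(tin_ptr[n], tin_ptr[n + 1]):
                        _conn_update(tin_idx[q], tin_pre[q], n, t,
                                     z_spk, e_spk, t_spk, eij, pij,
                                     pic, pjc, t_conn,
                                     lz_a, lz_n, le, lp_assoc, eps)
                    # Z impulse (unit area 1/f_max); record post-jump
                    # state for connection-side reconstruction
                    e_spk[n, 0] = e_i[n, 0]
                    e_spk[n, 1] = e_i[n, 1]
                    z[n, 0] += zjump_a
                    z[n, 1] += zjump_n
                    z_spk[n, 0] = z[n, 0]
                    z_spk[n, 1] = z[n, 1]
                    t_spk[n] = t

        # bookkeeping grid: refresh neuron cascades and biases
        if (step0 + s) % grid_steps == 0:
            tg = t + dt
            for n in range(N):
                if not is_pyr[n]:
                    continue
                dtr = tg - t_tr[n]
                if dtr > 0.0:
                    z[n, 0], e_i[n, 0], p_i[n, 0] = _zep_propagate(
                        z[n, 0], e_i[n, 0], p_i[n, 0], dtr,
                        lz_a, le, lp_neuron, eps)
                    z[n, 1], e_i[n, 1], p_i[n, 1] = _zep_propagate(
                        z[n, 1], e_i[n, 1], p_i[n, 1], dtr,
                        lz_n, le, lp_neuron, eps)
                    t_tr[n] = tg
                I_beta[n] = beta_gain * np.log(p_i[n, bias_comp])

    rec_count[0] = nrec
    return ERR_NONE
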