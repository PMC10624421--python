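"""Fused numba simulation loop for closed-loop CBGT sessions.

Replicates, step for step, the reference semantics of
:mod:`cbgt.network` (exponential-Euler membranes, conductance synapses with
one-step spike propagation delay) and :mod:`cbgt.plasticity` (traces,
eligibility, dopamine, soft-bounded weights, applied at a 1 ms stride), but
in a single compiled loop so that whole sessions run in seconds. The test
suite cross-checks this kernel against the pure-numpy reference steps.

Millisecond bookkeeping: background OU updates, per-neuron noise refresh,
plasticity stride, decision readout and spike-count logging all happen on
1 ms boundaries; membrane/synapse integration runs at ``dt``.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# population indices of the thalamic channels in INSTANCE_KEYS order
TH_LEFT, TH_RIGHT = 14, 15


@njit(cache=False)
def run_phase(
    seed,
    n_steps, dt, steps_per_ms,
    # state (mutated)
    V, h, sA, sN, sG, refr, spk_prev,
    # membrane parameters
    Cm, gL, VL, gT, Vh, VT, dec_hm, dec_hp, Vth, Vre, t_ref,
    # synapse parameters (per neuron)
    gAc, gNc, gGc, VE, VI, dec_a, dec_n, dec_g, alphaN,
    # static adjacency, CSR by source
    a_ptr, a_idx, a_wt, n_ptr, n_idx, n_wt, g_ptr, g_idx, g_wt,
    # populations / background
    pop_of, nuc_of, ou_x, ou_mu, ou_theta, ou_sigma, neuron_sigma_pop, I_offset, I_noise,
    stim, stim_ramp_ms,
    # logging
    counts,           # int64 [n_pop, n_ms_capacity], filled from ms_offset
    ms_offset,
    # readout
    do_readout, thr_rate_count_l, thr_rate_count_r, win_ms,
    # plastic corticostriatal synapses
    do_plast,
    cx_start, n_cx,            # int64[2], per channel
    spn_start, n_spn,          # int64[4]: dSPN_l, iSPN_l, dSPN_r, iSPN_r
    Wp, Mp, Ep,                # [4, n_cx, n_spn]
    A_pre, A_post,             # [2, n_cx], [4, n_spn]
    tau_pre, tau_post, d_pre, d_post, tau_e,
    k_da, tau_dop, c_scale, half_c,
    alpha_w, w_max, w_min,     # float64[4], float64[4], scalar
    da_event_ms, da_inc,
    spike_ids, spike_times, n_spikes,  # optional raster log (capacity-bounded)
):
    """Advance the network ``n_steps``; returns (decision_ms, channel, tie).

    ``decision_ms`` is -1 if no threshold crossing happened (or readout is
    off); ``channel`` is 0 = left, 1 = right. Spike counts per population
    and millisecond are accumulated into ``counts`` starting at column
    ``ms_offset``.
    """
    np.random.seed(seed)
    N = V.shape[0]
    n_pop = ou_x.shape[0]
    pre_cnt = np.zeros((2, n_cx[0]), dtype=np.int64)
    post_cnt = np.zeros((4, n_spn[0]), dtype=np.int64)
    dec_e = math.exp(-1.0 / tau_e)
    dec_pre = math.exp(-1.0 / tau_pre)
    dec_post = math.exp(-1.0 / tau_post)
    dec_dop = math.exp(-1.0 / tau_dop)
    decision_ms = -1
    channel = -1
    tie = 0
    ms = 0

    for step in range(n_steps):
        # ---- millisecond boundary bookkeeping --------------------------
        at_boundary = step % steps_per_ms == 0
        if at_boundary and step > 0:
            if True:
                ms_done = ms  # the ms just completed
                # plasticity stride
                if do_plast == 1:
                    for b in range(4):
                        ch = b // 2
                        npre = n_cx[ch]
                        nspn = n_spn[b]
                        # eligibility decay + spike impulses
                        for i in range(npre):
                            for j in range(nspn):
                                if Mp[b, i, j]:
                                    e = Ep[b, i, j] * dec_e
                                    if post_cnt[b, j] > 0:
                                        e += post_cnt[b, j] * A_pre[ch, i] / tau_e
                                    if pre_cnt[ch, i] > 0:
                                        e -= pre_cnt[ch, i] * A_post[b, j] / tau_e
                                    Ep[b, i, j] = e
                    # weight update (gated on appreciable dopamine)
                    if k_da[0] > 1e-4 or k_da[0] < -1e-4:
                        f_d = k_da[0]
                        f_i = k_da[0] / (half_c + abs(k_da[0]))
                        for b in range(4):
                            fX = f_d if b % 2 == 0 else f_i
                            aw = alpha_w[b]
                            wm = w_max[b]
                            for i in range(n_cx[b // 2]):
                                for j in range(n_spn[b]):
                                    if Mp[b, i, j]:
                                        drive = aw * Ep[b, i, j] * fX
                                        w = Wp[b, i, j]
                                        if drive > 0.0:
                                            w += drive * (wm - w)
                                        else:
                                            w += drive * (w - w_min)
                                        if w < w_min:
                                            w = w_min
                                        elif w > wm:
                                            w = wm
                                        Wp[b, i, j] = w
                    # traces decay + impulses
                    for ch in range(2):
                        for i in range(n_cx[ch]):
                            A_pre[ch, i] = A_pre[ch, i] * dec_pre + pre_cnt[ch, i] * d_pre / tau_pre
                    for b in range(4):
                        for j in range(n_spn[b]):
                            A_post[b, j] = A_post[b, j] * dec_post + post_cnt[b, j] * d_post / tau_post
                    pre_cnt[:] = 0
                    post_cnt[:] = 0
                    # dopamine decay / phasic event
                    k_da[0] *= dec_dop
                    if ms_done == da_event_ms:
                        k_da[0] += c_scale * (da_inc - k_da[0]) / tau_dop
                # decision readout on the completed ms
                if do_readout == 1 and decision_ms < 0:
                    col = ms_offset + ms_done
                    lo = col - int(win_ms) + 1
                    if lo < 0:
                        lo = 0
                    cl = 0
                    cr = 0
                    for c in range(lo, col + 1):
                        cl += counts[TH_LEFT, c]
                        cr += counts[TH_RIGHT, c]
                    hit_l = cl >= thr_rate_count_l
                    hit_r = cr >= thr_rate_count_r
                    if hit_l or hit_r:
                        if hit_l and hit_r:
                            tie = 1
                            if cl > cr:
                                channel = 0
                            elif cr > cl:
                                channel = 1
                            else:
                                channel = np.random.randint(0, 2)
                        else:
                            channel = 0 if hit_l else 1
                        decision_ms = ms_done + 1
                        return decision_ms, channel, tie
            ms += 1
        if at_boundary:
            # refresh background drive and per-neuron noise
            for p in range(n_pop):
                ou_x[p] += ou_theta[p] * (ou_mu[p] - ou_x[p]) + ou_sigma[p] * np.random.standard_normal()
            for i in range(N):
                s = neuron_sigma_pop[pop_of[i]]
                I_noise[i] = I_offset[i] + (s * np.random.standard_normal() if s > 0.0 else 0.0)

        # ---- synapse decay + spike propagation (one-step delay) --------
        for i in range(N):
            sA[i] *= dec_a[i]
            sN[i] *= dec_n[i]
            sG[i] *= dec_g[i]
        for j in range(N):
            if spk_prev[j] == 1:
                for k in range(a_ptr[j], a_ptr[j + 1]):
                    sA[a_idx[k]] += a_wt[k]
                for k in range(n_ptr[j], n_ptr[j + 1]):
                    t = n_idx[k]
                    sN[t] += alphaN[t] * (1.0 - sN[t]) * n_wt[k]
                for k in range(g_ptr[j], g_ptr[j + 1]):
                    sG[g_idx[k]] += g_wt[k]
                # plastic corticostriatal fan-out (drives AMPA and NMDA)
                for ch in range(2):
                    if cx_start[ch] <= j < cx_start[ch] + n_cx[ch]:
                        i_loc = j - cx_start[ch]
                        for b in range(2 * ch, 2 * ch + 2):
                            for jj in range(n_spn[b]):
                                if Mp[b, i_loc, jj]:
                                    w = Wp[b, i_loc, jj]
                                    t = spn_start[b] + jj
                                    sA[t] += w
                                    sN[t] += alphaN[t] * (1.0 - sN[t]) * w
                spk_prev[j] = 0

        # ---- membrane step ---------------------------------------------
        for i in range(N):
            v = V[i]
            if refr[i] > 0.0:
                refr[i] -= dt
                v_new = Vre[i]
                spiked = False
            else:
                g_t = 0.0
                if gT[i] > 0.0 and v >= Vh[i]:
                    g_t = gT[i] * h[i]
                mg = 1.0 / (1.0 + math.exp(-0.062 * v) / 3.57)
                ga = gAc[i] * sA[i]
                gn = gNc[i] * sN[i] * mg
                gg = gGc[i] * sG[i]
                g_tot = gL[i] + g_t + ga + gn + gg
                ramp = 1.0
                if stim_ramp_ms > 0.0 and ms < stim_ramp_ms:
                    ramp = (ms + 1.0) / stim_ramp_ms
                i_ext = ou_x[nuc_of[i]] + I_noise[i] + ramp * stim[i]
                v_inf = (gL[i] * VL[i] + g_t * VT[i] + (ga + gn) * VE[i] + gg * VI[i] + i_ext) / g_tot
                v_new = v_inf + (v - v_inf) * math.exp(-g_tot * dt / Cm[i])
                spiked = v_new >= Vth[i]
            if spiked:
                V[i] = Vre[i]
                refr[i] = t_ref[i]
                spk_prev[i] = 1
                counts[pop_of[i], ms_offset + ms] += 1
                if n_spikes[0] < spike_ids.shape[0]:
                    spike_ids[n_spikes[0]] = i
                    spike_times[n_spikes[0]] = (step + 1) * dt
                    n_spikes[0] += 1
                # plasticity spike accumulators
                for ch in range(2):
                    if cx_start[ch] <= i < cx_start[ch] + n_cx[ch]:
                        pre_cnt[ch, i - cx_start[ch]] += 1
                for b in range(4):
                    if spn_start[b] <= i < spn_start[b] + n_spn[b]:
                        post_cnt[b, i - spn_start[b]] += 1
            else:
                V[i] = v_new
            # burst gate
            if V[i] >= Vh[i]:
                h[i] *= dec_hm[i]
            else:
                h[i] = 1.0 + (h[i] - 1.0) * dec_hp[i]

    return decision_ms, channel, tie
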