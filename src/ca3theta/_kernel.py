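"""Vectorized time-stepped network integration (numba JIT kernel).

All structure is flattened into plain arrays by the engine:

* neurons: one slot per cell, ordered by population;
* pathways: per-class constants plus *lumped* receptor gating per
  postsynaptic cell (exact at fixed gain below saturation); gating lives in
  four flat arrays indexed by per-pathway offsets, with saturating binding
  applied per arrival;
* edges: CSR adjacency by source cell with per-edge weight and Varela
  short-term-plasticity state (lazily recovered in closed form at each
  presynaptic spike);
* delays: constant per pathway, rounded to whole steps, honored through
  per-pathway FIFO ring queues of pending arrivals;
* external drive: a pre-sorted (step, gating index, amount) event stream.

Neuron ODEs advance with a midpoint (RK2) step; gating decays by exact
exponential factors.  Returns an error code (0 ok; 1 non-finite state with
cell/step diagnostic; 2 spike-buffer overflow; 3 queue overflow).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=False)
def simulate(
    n_steps,
    dt,
    # neurons (length N)
    nC, nk, na, nb, nc, nd, nvr, nvt, nvpeak,
    nhen, nah, nbh, ndh, ndyn, nsil, i_inj,
    v, u, h,
    # pathways (length P)
    p_delay_steps, p_sign, p_tgt_lo, p_tgt_n, p_off,
    p_frd, p_fdd, p_srd, p_sdd, p_nmda, p_satf, p_sats,
    mg_slope, mg_k,
    # gating (length G = sum of p_tgt_n)
    gate_fr, gate_fd, gate_sr, gate_sd,
    # edges (length E), CSR by source cell
    src_ptr, e_path, e_gidx, e_amt_f, e_amt_s,
    e_stp_kind, e_stp_f, e_stp_tau, e_D, e_F, e_last,
    stp_f_max,
    # per-pathway ring queues
    q_step, q_g, q_af, q_as, q_head, q_tail,
    # external events, sorted by step
    x_step, x_g, x_path, x_af, x_as,
    # spike output
    spike_cell, spike_step,
    # traces
    rec_u_idx, rec_u, rec_v_idx, rec_v,
    rec_g_path, rec_g_gidx, rec_g_cell, rec_g,
):
    N = v.shape[0]
    P = p_sign.shape[0]
    Q = q_step.shape[1]
    n_spikes = 0
    xptr = 0
    nx = x_step.shape[0]
    g_exc = np.zeros(N)
    g_nmda = np.zeros(N)
    g_ga = np.zeros(N)
    g_gb = np.zeros(N)
    for t in range(n_steps):
        # 1. decay all gating, then apply arrivals scheduled for this step
        for p in range(P):
            o, n = p_off[p], p_tgt_n[p]
            for j in range(o, o + n):
                gate_fr[j] *= p_frd[p]
                gate_fd[j] *= p_fdd[p]
                gate_sr[j] *= p_srd[p]
                gate_sd[j] *= p_sdd[p]
            while q_head[p] < q_tail[p] and q_step[p, q_head[p] % Q] == t:
                k = q_head[p] % Q
                j = q_g[p, k]
                # saturating receptor binding per channel: the decay
                # envelope asymptotes at the pathway cap (linear when inf)
                af = q_af[p, k]
                if np.isfinite(p_satf[p]) and af > 0.0:
                    af = (p_satf[p] - gate_fd[j]) * (1.0 - np.exp(-af / p_satf[p]))
                    if af < 0.0:
                        af = 0.0
                asl = q_as[p, k]
                if np.isfinite(p_sats[p]) and asl > 0.0:
                    asl = (p_sats[p] - gate_sd[j]) * (1.0 - np.exp(-asl / p_sats[p]))
                    if asl < 0.0:
                        asl = 0.0
                gate_fr[j] += af
                gate_fd[j] += af
                gate_sr[j] += asl
                gate_sd[j] += asl
                q_head[p] += 1
        while xptr < nx and x_step[xptr] == t:
            j = x_g[xptr]
            p = x_path[xptr]
            af = x_af[xptr]
            if np.isfinite(p_satf[p]) and af > 0.0:
                af = (p_satf[p] - gate_fd[j]) * (1.0 - np.exp(-af / p_satf[p]))
                if af < 0.0:
                    af = 0.0
            asl = x_as[xptr]
            if np.isfinite(p_sats[p]) and asl > 0.0:
                asl = (p_sats[p] - gate_sd[j]) * (1.0 - np.exp(-asl / p_sats[p]))
                if asl < 0.0:
                    asl = 0.0
            gate_fr[j] += af
            gate_fd[j] += af
            gate_sr[j] += asl
            gate_sd[j] += asl
            xptr += 1

        # 2. synaptic conductance-like gating summed per postsynaptic cell
        # into receptor families; driving-force factors (and the NMDA Mg
        # block) are applied at update time with the cell's own voltage
        for i in range(N):
            g_exc[i] = 0.0
            g_nmda[i] = 0.0
            g_ga[i] = 0.0
            g_gb[i] = 0.0
        for p in range(P):
            o, n, lo = p_off[p], p_tgt_n[p], p_tgt_lo[p]
            for jj in range(n):
                j = o + jj
                cell = lo + jj
                gf = gate_fd[j] - gate_fr[j]
                gs = gate_sd[j] - gate_sr[j]
                if p_sign[p] > 0:
                    g_exc[cell] += gf
                    if p_nmda[p] == 1:
                        g_nmda[cell] += gs
                    else:
                        g_exc[cell] += gs
                else:
                    g_ga[cell] += gf
                    g_gb[cell] += gs

        # 3. neuron update (midpoint), reset, spike propagation
        for i in range(N):
            if nsil[i] == 1:
                continue
            vi, ui, hi = v[i], u[i], h[i]
            # driving forces normalized at -75 mV (exc) / -55 mV (inh)
            dfe = -vi / 75.0
            mg = 1.0 / (1.0 + np.exp(-mg_slope * vi) / mg_k)
            Ii = (i_inj[i]
                  + (g_exc[i] + g_nmda[i] * mg) * dfe
                  - g_ga[i] * (vi + 75.0) / 20.0
                  - g_gb[i] * (vi + 90.0) / 35.0)
            # midpoint update with adaptive sub-stepping: substeps are sized
            # so v moves at most ~2 mV per substep, keeping the explosive
            # spike upstroke accurate at coarse dt; the recovery currents see
            # v capped at v_t so the stereotyped spike contributes a bounded,
            # step-size-robust amount
            dv0 = (nk[i] * (vi - nvr[i]) * (vi - nvt[i]) - ui + hi + Ii) / nC[i]
            if not np.isfinite(dv0):
                return 1, i, t, n_spikes
            nsub = 1 + int(abs(dv0) * dt / 2.0)
            if nsub > 64:
                nsub = 64
            hsub = dt / nsub
            for _ss in range(nsub):
                vc = vi if vi < nvt[i] else nvt[i]
                dv1 = (nk[i] * (vi - nvr[i]) * (vi - nvt[i]) - ui + hi + Ii) / nC[i]
                du1 = na[i] * (nb[i] * (vc - nvr[i]) - ui)
                dh1 = nah[i] * (-nbh[i] * (vc - nvr[i]) - hi) if nhen[i] == 1 else 0.0
                vm = vi + 0.5 * hsub * dv1
                um = ui + 0.5 * hsub * du1
                hm = hi + 0.5 * hsub * dh1
                vcm = vm if vm < nvt[i] else nvt[i]
                dv2 = (nk[i] * (vm - nvr[i]) * (vm - nvt[i]) - um + hm + Ii) / nC[i]
                du2 = na[i] * (nb[i] * (vcm - nvr[i]) - um)
                dh2 = nah[i] * (-nbh[i] * (vcm - nvr[i]) - hm) if nhen[i] == 1 else 0.0
                vi += hsub * dv2
                ui += hsub * du2
                hi += hsub * dh2
                if vi >= nvpeak[i]:
                    break
            if not (np.isfinite(vi) and np.isfinite(ui) and np.isfinite(hi)):
                return 1, i, t, n_spikes
            if ndyn[i] == 1:
                un = ui / nC[i]
                if un > 1.5:
                    un = 1.5
                elif un < 0.0:
                    un = 0.0
                reset_v = nc[i] + 10.0 * un
                cutoff = nvpeak[i] - 30.0 * un
            else:
                reset_v = nc[i]
                cutoff = nvpeak[i]
            if vi >= cutoff:
                vi = reset_v
                if nhen[i] == 1:
                    hi += ndh[i]
                ui += nd[i]
                if n_spikes >= spike_cell.shape[0]:
                    return 2, i, t, n_spikes
                spike_cell[n_spikes] = i
                spike_step[n_spikes] = t
                n_spikes += 1
                for e in range(src_ptr[i], src_ptr[i + 1]):
                    p = e_path[e]
                    # closed-form STP recovery since the previous presyn spike
                    gain = 1.0
                    if e_stp_kind[e] != 0:
                        dts = (t - e_last[e]) * dt
                        rec = np.exp(-dts / e_stp_tau[e])
                        if e_stp_kind[e] == 1:
                            D = 1.0 - (1.0 - e_D[e]) * rec
                            gain = D
                            e_D[e] = D * e_stp_f[e]
                        else:
                            F = 1.0 + (e_F[e] - 1.0) * rec
                            gain = F
                            Fn = F + e_stp_f[e]
                            e_F[e] = Fn if Fn < stp_f_max else stp_f_max
                        e_last[e] = t
                    k = q_tail[p]
                    if k - q_head[p] >= Q:
                        return 3, i, t, n_spikes
                    kk = k % Q
                    q_step[p, kk] = t + p_delay_steps[p]
                    q_g[p, kk] = e_gidx[e]
                    q_af[p, kk] = e_amt_f[e] * gain
                    q_as[p, kk] = e_amt_s[e] * gain
                    q_tail[p] += 1
            v[i] = vi
            u[i] = ui
            h[i] = hi

        # 4. traces
        for r in range(rec_u_idx.shape[0]):
            rec_u[r, t] = u[rec_u_idx[r]]
        for r in range(rec_v_idx.shape[0]):
            rec_v[r, t] = v[rec_v_idx[r]]
        for r in range(rec_g_path.shape[0]):
            p = rec_g_path[r]
            j = rec_g_gidx[r]
            vc = v[rec_g_cell[r]]
            gf = gate_fd[j] - gate_fr[j]
            gs = gate_sd[j] - gate_sr[j]
            if p_sign[p] > 0:
                if p_nmda[p] == 1:
                    gs *= 1.0 / (1.0 + np.exp(-mg_slope * vc) / mg_k)
                rec_g[r, t] = (gf + gs) * (-vc / 75.0)
            else:
                rec_g[r, t] = -gf * (vc + 75.0) / 20.0 - gs * (vc + 90.0) / 35.0
    return 0, -1, -1, n_spikes
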