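"""Compiled network integration loop.

One fused numba kernel advances all three populations with fixed-step
exponential-Euler integration.  Gating kinetics are evaluated through
voltage-indexed lookup tables (built in :mod:`ca3gamma.engine` from the
exact rate functions in :mod:`ca3gamma.biophysics`, 0.02 mV grid, linear
interpolation).  Double-exponential synapses are aggregated per
(population, compartment, kinetics) bucket as linear two-state filters:
an event of weight w adds w to both states; the conductance is
N·(B − A), which peaks at exactly w.

Spike propagation uses per-projection ring buffers of future conductance
increments; background Poisson drives are thinned per step with one
uniform draw per (drive, cell) so that paired control/scaled runs consume
an identical random stream.
"""

import numpy as np
from numba import njit

# population codes
POP_PYR, POP_BAS, POP_OLM = 0, 1, 2


@njit(cache=True, fastmath=True)
def _lin(tab, i0, fr, col):
    a = tab[i0, col]
    return a + (tab[i0 + 1, col] - a) * fr


@njit(cache=True, fastmath=True)
def run_network(
    n_steps, dt, seed,
    n_pyr, n_bas, n_olm,
    # state (modified in place)
    v_pyr, g_pyr,            # (n_pyr,5), (n_pyr,5,6) gates m,h,n,a,b,q
    v_bas, g_bas,            # (n_bas,), (n_bas,3) m,h,n
    v_olm, g_olm, ca_olm,    # (n_olm,), (n_olm,5) m,h,n,q,s ; (n_olm,)
    # pyramidal passive/channel parameters
    pyr_parent, pyr_gax, pyr_c,
    pyr_gna, pyr_gkdr, pyr_gka, pyr_gih, pyr_gleak,
    pyr_ena, pyr_ek, pyr_eh, pyr_eleak,
    # basket
    bas_gna, bas_gkdr, bas_gleak, bas_c, bas_ena, bas_ek, bas_eleak,
    # OLM
    olm_gna, olm_gkdr, olm_gih, olm_gcal, olm_gkca, olm_gleak, olm_c,
    olm_ena, olm_ek, olm_eh, olm_eca, olm_eleak,
    # gating lookup tables over voltage
    v_min, inv_dv, nv,
    pyr_tab,   # (nv,10): m_inf,m_dec,h_inf,h_dec,n_inf,n_dec,a_inf,b_inf,q_inf,q_dec
    bas_tab,   # (nv,6):  m_inf,m_dec,h_inf,h_dec,n_inf,n_dec
    olm_tab,   # (nv,9):  m_inf,m_dec,h_inf,h_dec,n_inf,n_dec,q_inf,q_dec,s_inf
    ka_a_dec, ka_b_dec, cal_s_dec,
    kca_kd, ca_alpha, ca_tau, ca_dec, ca_rest,
    # synapse buckets
    bucket_pop, bucket_comp, bucket_off, bucket_size,
    bucket_norm, bucket_d1, bucket_d2, bucket_erev, bucket_nmda,
    syn_a, syn_b,            # (total_state,) states, modified in place
    mg_block,
    # background drives
    bg_bucket, bg_lam, bg_w,
    # projections (CSR per projection into shared arrays)
    proj_pre_pop, proj_bucket, proj_delay, proj_g,
    proj_ip0, proj_tg0, indptr_all, targets_all,
    ring,                    # (buflen, total_state)
    # exogenous events (sorted by step): MS pacemaker, probe volleys
    ev_step, ev_bucket, ev_w,
    # spike detection / output
    refrac_steps, max_spikes, spike_t, spike_gid,
    # recording
    record_every, rec_soma, rec_bdend, rec_adend3,
):
    np.random.seed(seed)
    buflen = ring.shape[0]
    n_buckets = bucket_pop.shape[0]
    n_bg = bg_bucket.shape[0]
    n_proj = proj_pre_pop.shape[0]
    n_ev = ev_step.shape[0]
    n_rec = rec_soma.shape[0]

    gs_p = np.zeros((n_pyr, 5))
    ge_p = np.zeros((n_pyr, 5))
    gs_b = np.zeros(n_bas)
    ge_b = np.zeros(n_bas)
    gs_o = np.zeros(n_olm)
    ge_o = np.zeros(n_olm)

    last_spk_p = np.full(n_pyr, -10**9, dtype=np.int64)
    last_spk_b = np.full(n_bas, -10**9, dtype=np.int64)
    last_spk_o = np.full(n_olm, -10**9, dtype=np.int64)
    # spiking cells this step, per population
    fired = np.empty(n_pyr + n_bas + n_olm, dtype=np.int64)

    n_spk = 0
    overflow = 0
    err_step = -1
    ev_ptr = 0
    nv2 = nv - 2

    for step in range(n_steps):
        # ---- recording (pre-step state, t = step*dt) ----
        if step % record_every == 0:
            r = step // record_every
            if r < n_rec:
                for j in range(n_pyr):
                    rec_soma[r, j] = v_pyr[j, 0]
                    rec_bdend[r, j] = v_pyr[j, 1]
                    rec_adend3[r, j] = v_pyr[j, 4]

        # ---- exogenous events ----
        while ev_ptr < n_ev and ev_step[ev_ptr] <= step:
            if ev_step[ev_ptr] == step:
                b = ev_bucket[ev_ptr]
                off = bucket_off[b]
                w = ev_w[ev_ptr]
                for c in range(bucket_size[b]):
                    syn_a[off + c] += w
                    syn_b[off + c] += w
            ev_ptr += 1

        # ---- delayed spike deliveries ----
        row = step % buflen
        for i in range(syn_a.shape[0]):
            w = ring[row, i]
            if w != 0.0:
                syn_a[i] += w
                syn_b[i] += w
                ring[row, i] = 0.0

        # ---- background Poisson (thinned; fixed draw order) ----
        for j in range(n_bg):
            b = bg_bucket[j]
            off = bucket_off[b]
            lam = bg_lam[j]
            w = bg_w[j]
            for c in range(bucket_size[b]):
                if np.random.random() < lam:
                    syn_a[off + c] += w
                    syn_b[off + c] += w

        # ---- synaptic conductances (nS → µS) ----
        for j in range(n_pyr):
            for k in range(5):
                gs_p[j, k] = 0.0
                ge_p[j, k] = 0.0
        for j in range(n_bas):
            gs_b[j] = 0.0
            ge_b[j] = 0.0
        for j in range(n_olm):
            gs_o[j] = 0.0
            ge_o[j] = 0.0
        for b in range(n_buckets):
            off = bucket_off[b]
            pop = bucket_pop[b]
            comp = bucket_comp[b]
            norm = bucket_norm[b]
            erev = bucket_erev[b]
            use_mg = mg_block == 1 and bucket_nmda[b] == 1
            for c in range(bucket_size[b]):
                g = norm * (syn_b[off + c] - syn_a[off + c]) * 1e-3
                if g <= 0.0:
                    continue
                if use_mg:
                    if pop == POP_PYR:
                        vv = v_pyr[c, comp]
                    elif pop == POP_BAS:
                        vv = v_bas[c]
                    else:
                        vv = v_olm[c]
                    g *= 1.0 / (1.0 + 0.28 * np.exp(-0.062 * vv))
                if pop == POP_PYR:
                    gs_p[c, comp] += g
                    ge_p[c, comp] += g * erev
                elif pop == POP_BAS:
                    gs_b[c] += g
                    ge_b[c] += g * erev
                else:
                    gs_o[c] += g
                    ge_o[c] += g * erev

        n_fired = 0

        # ---- pyramidal cells ----
        for j in range(n_pyr):
            # axial currents from pre-step voltages
            for k in range(5):
                p = pyr_parent[k]
                if p >= 0:
                    # child side: semi-implicit coupling term toward parent
                    gs_p[j, k] += pyr_gax[k]
                    ge_p[j, k] += pyr_gax[k] * v_pyr[j, p]
                    # parent side: explicit axial current from the child
                    ge_p[j, p] += pyr_gax[k] * (v_pyr[j, k] - v_pyr[j, p])
            for k in range(5):
                v = v_pyr[j, k]
                ti = (v - v_min) * inv_dv
                if ti < 0.0:
                    ti = 0.0
                elif ti > nv2:
                    ti = float(nv2)
                i0 = int(ti)
                fr = ti - i0
                m = g_pyr[j, k, 0]
                h = g_pyr[j, k, 1]
                n = g_pyr[j, k, 2]
                a = g_pyr[j, k, 3]
                bb = g_pyr[j, k, 4]
                q = g_pyr[j, k, 5]
                m += (_lin(pyr_tab, i0, fr, 0) - m) * (1.0 - _lin(pyr_tab, i0, fr, 1))
                h += (_lin(pyr_tab, i0, fr, 2) - h) * (1.0 - _lin(pyr_tab, i0, fr, 3))
                n += (_lin(pyr_tab, i0, fr, 4) - n) * (1.0 - _lin(pyr_tab, i0, fr, 5))
                a += (_lin(pyr_tab, i0, fr, 6) - a) * (1.0 - ka_a_dec)
                bb += (_lin(pyr_tab, i0, fr, 7) - bb) * (1.0 - ka_b_dec)
                q += (_lin(pyr_tab, i0, fr, 8) - q) * (1.0 - _lin(pyr_tab, i0, fr, 9))
                if m < 0.0:
                    m = 0.0
                elif m > 1.0:
                    m = 1.0
                if h < 0.0:
                    h = 0.0
                elif h > 1.0:
                    h = 1.0
                if n < 0.0:
                    n = 0.0
                elif n > 1.0:
                    n = 1.0
                if a < 0.0:
                    a = 0.0
                elif a > 1.0:
                    a = 1.0
                if bb < 0.0:
                    bb = 0.0
                elif bb > 1.0:
                    bb = 1.0
                if q < 0.0:
                    q = 0.0
                elif q > 1.0:
                    q = 1.0
                g_pyr[j, k, 0] = m
                g_pyr[j, k, 1] = h
                g_pyr[j, k, 2] = n
                g_pyr[j, k, 3] = a
                g_pyr[j, k, 4] = bb
                g_pyr[j, k, 5] = q

                gna = pyr_gna[k] * m * m * m * h
                gk = pyr_gkdr[k] * n * n * n * n + pyr_gka[k] * a * bb
                gh = pyr_gih[k] * q
                G = pyr_gleak[k] + gna + gk + gh + gs_p[j, k]
                GE = (
                    pyr_gleak[k] * pyr_eleak
                    + gna * pyr_ena
                    + gk * pyr_ek
                    + gh * pyr_eh
                    + ge_p[j, k]
                )
                vinf = GE / G
                v_pyr[j, k] = vinf + (v - vinf) * np.exp(-dt * G / pyr_c[k])

        # basket cells
        for j in range(n_bas):
            v = v_bas[j]
            ti = (v - v_min) * inv_dv
            if ti < 0.0:
                ti = 0.0
            elif ti > nv2:
                ti = float(nv2)
            i0 = int(ti)
            fr = ti - i0
            m = g_bas[j, 0]
            h = g_bas[j, 1]
            n = g_bas[j, 2]
            m += (_lin(bas_tab, i0, fr, 0) - m) * (1.0 - _lin(bas_tab, i0, fr, 1))
            h += (_lin(bas_tab, i0, fr, 2) - h) * (1.0 - _lin(bas_tab, i0, fr, 3))
            n += (_lin(bas_tab, i0, fr, 4) - n) * (1.0 - _lin(bas_tab, i0, fr, 5))
            if m < 0.0:
                m = 0.0
            elif m > 1.0:
                m = 1.0
            if h < 0.0:
                h = 0.0
            elif h > 1.0:
                h = 1.0
            if n < 0.0:
                n = 0.0
            elif n > 1.0:
                n = 1.0
            g_bas[j, 0] = m
            g_bas[j, 1] = h
            g_bas[j, 2] = n
            gna = bas_gna * m * m * m * h
            gk = bas_gkdr * n * n * n * n
            G = bas_gleak + gna + gk + gs_b[j]
            GE = bas_gleak * bas_eleak + gna * bas_ena + gk * bas_ek + ge_b[j]
            vinf = GE / G
            v_bas[j] = vinf + (v - vinf) * np.exp(-dt * G / bas_c)

        # OLM cells
        for j in range(n_olm):
            v = v_olm[j]
            ti = (v - v_min) * inv_dv
            if ti < 0.0:
                ti = 0.0
            elif ti > nv2:
                ti = float(nv2)
            i0 = int(ti)
            fr = ti - i0
            m = g_olm[j, 0]
            h = g_olm[j, 1]
            n = g_olm[j, 2]
            q = g_olm[j, 3]
            s = g_olm[j, 4]
            m += (_lin(olm_tab, i0, fr, 0) - m) * (1.0 - _lin(olm_tab, i0, fr, 1))
            h += (_lin(olm_tab, i0, fr, 2) - h) * (1.0 - _lin(olm_tab, i0, fr, 3))
            n += (_lin(olm_tab, i0, fr, 4) - n) * (1.0 - _lin(olm_tab, i0, fr, 5))
            q += (_lin(olm_tab, i0, fr, 6) - q) * (1.0 - _lin(olm_tab, i0, fr, 7))
            s += (_lin(olm_tab, i0, fr, 8) - s) * (1.0 - cal_s_dec)
            if m < 0.0:
                m = 0.0
            elif m > 1.0:
                m = 1.0
            if h < 0.0:
                h = 0.0
            elif h > 1.0:
                h = 1.0
            if n < 0.0:
                n = 0.0
            elif n > 1.0:
                n = 1.0
            if q < 0.0:
                q = 0.0
            elif q > 1.0:
                q = 1.0
            if s < 0.0:
                s = 0.0
            elif s > 1.0:
                s = 1.0
            g_olm[j, 0] = m
            g_olm[j, 1] = h
            g_olm[j, 2] = n
            g_olm[j, 3] = q
            g_olm[j, 4] = s
            gna = olm_gna * m * m * m * h
            gca = olm_gcal * s * s
            gkca = olm_gkca * (ca_olm[j] / (ca_olm[j] + kca_kd))
            gk = olm_gkdr * n * n * n * n + gkca
            gh = olm_gih * q
            G = olm_gleak + gna + gk + gh + gca + gs_o[j]
            GE = (
                olm_gleak * olm_eleak
                + gna * olm_ena
                + gk * olm_ek
                + gh * olm_eh
                + gca * olm_eca
                + ge_o[j]
            )
            vinf = GE / G
            v_olm[j] = vinf + (v - vinf) * np.exp(-dt * G / olm_c)
            i_ca = gca * (v - olm_eca)  # nA, outward positive (inward < 0)
            ca_inf = ca_rest - ca_alpha * ca_tau * i_ca
            ca = ca_inf + (ca_olm[j] - ca_inf) * ca_dec
            ca_olm[j] = ca if ca > 0.0 else 0.0

        # ---- spike detection & propagation ----
        # detection uses the post-step voltage crossing with refractoriness;
        # because exponential-Euler updates are monotone between states, a
        # crossing is flagged when v >= 0 and the refractory window expired.
        for j in range(n_pyr):
            if v_pyr[j, 0] >= 0.0 and step - last_spk_p[j] > refrac_steps:
                last_spk_p[j] = step
                if n_spk < max_spikes:
                    spike_t[n_spk] = step * dt
                    spike_gid[n_spk] = j
                    n_spk += 1
                else:
                    overflow = 1
                fired[n_fired] = j
                n_fired += 1
        n_fired_pyr = n_fired
        for j in range(n_bas):
            if v_bas[j] >= 0.0 and step - last_spk_b[j] > refrac_steps:
                last_spk_b[j] = step
                if n_spk < max_spikes:
                    spike_t[n_spk] = step * dt
                    spike_gid[n_spk] = n_pyr + j
                    n_spk += 1
                else:
                    overflow = 1
                fired[n_fired] = j
                n_fired += 1
        n_fired_bas = n_fired
        for j in range(n_olm):
            if v_olm[j] >= 0.0 and step - last_spk_o[j] > refrac_steps:
                last_spk_o[j] = step
                if n_spk < max_spikes:
                    spike_t[n_spk] = step * dt
                    spike_gid[n_spk] = n_pyr + n_bas + j
                    n_spk += 1
                else:
                    overflow = 1
                fired[n_fired] = j
                n_fired += 1

        if n_fired > 0:
            for p in range(n_proj):
                pop = proj_pre_pop[p]
                if pop == POP_PYR:
                    lo, hi = 0, n_fired_pyr
                elif pop == POP_BAS:
                    lo, hi = n_fired_pyr, n_fired_bas
                else:
                    lo, hi = n_fired_bas, n_fired
                if lo == hi:
                    continue
                b = proj_bucket[p]
                off = bucket_off[b]
                rrow = (step + proj_delay[p]) % buflen
                w = proj_g[p]
                ip0 = proj_ip0[p]
                tg0 = proj_tg0[p]
                for f in range(lo, hi):
                    pre = fired[f]
                    e0 = indptr_all[ip0 + pre]
                    e1 = indptr_all[ip0 + pre + 1]
                    for e in range(e0, e1):
                        ring[rrow, off + targets_all[tg0 + e]] += w

        # ---- synaptic state decay ----
        for b in range(n_buckets):
            off = bucket_off[b]
            d1 = bucket_d1[b]
            d2 = bucket_d2[b]
            for c in range(bucket_size[b]):
                syn_a[off + c] *= d1
                syn_b[off + c] *= d2

        # ---- divergence check every 10 ms ----
        if step % 400 == 0:
            ok = True
            for j in range(n_pyr):
                if not np.isfinite(v_pyr[j, 0]):
                    ok = False
            for j in range(n_bas):
                if not np.isfinite(v_bas[j]):
                    ok = False
            for j in range(n_olm):
                if not np.isfinite(v_olm[j]):
                    ok = False
            if not ok:
                err_step = step
                return n_spk, overflow, err_step

    return n_spk, overflow, err_step
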