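"""Numba-compiled numerical kernels shared by the simulator and the
single-cell response analyses.

Everything here is a private implementation detail: fixed-step RK4 cores
operating on plain float64 arrays, with the reduced Traub-Miles and
Wang-Buzsáki rate functions written out numerically. When numba is not
installed the same functions run uncompiled (slow but identical).
"""

from __future__ import annotations

import numpy as np

try:  # optional acceleration
    from numba import njit as _njit

    def _jit(f):
        return _njit(cache=True, fastmath=False)(f)
except ImportError:  # pragma: no cover - numba is a soft dependency
    def _jit(f):
        return f


@_jit
def _vtrap_arr(x, y):
    out = np.empty_like(x)
    for k in range(x.size):
        d = 1.0 - np.exp(-x[k] / y)
        out[k] = y if abs(d) < 1e-12 else x[k] / d
    return out


@_jit
def _deriv_rtm(v, h, n, i_in):
    """Reduced Traub-Miles right-hand side (E-cells)."""
    am = 0.32 * _vtrap_arr(v + 54.0, 4.0)
    bm = 0.28 * _vtrap_arr(-(v + 27.0), 5.0)
    ah = 0.128 * np.exp(-(v + 50.0) / 18.0)
    bh = 4.0 / (1.0 + np.exp(-(v + 27.0) / 5.0))
    an = 0.032 * _vtrap_arr(v + 52.0, 5.0)
    bn = 0.5 * np.exp(-(v + 57.0) / 40.0)
    m = am / (am + bm)
    dv = (100.0 * m ** 3 * h * (50.0 - v) + 80.0 * n ** 4 * (-100.0 - v)
          + 0.1 * (-67.0 - v) + i_in)
    dh = ah * (1.0 - h) - bh * h
    dn = an * (1.0 - n) - bn * n
    return dv, dh, dn


@_jit
def _deriv_wb(v, h, n, i_in):
    """Wang-Buzsáki right-hand side (I-cells), φ = 5."""
    am = 0.1 * _vtrap_arr(v + 35.0, 10.0)
    bm = 4.0 * np.exp(-(v + 60.0) / 18.0)
    ah = 0.35 * np.exp(-(v + 58.0) / 20.0)
    bh = 5.0 / (1.0 + np.exp(-(v + 28.0) / 10.0))
    an = 0.05 * _vtrap_arr(v + 34.0, 10.0)
    bn = 0.625 * np.exp(-(v + 44.0) / 80.0)
    m = am / (am + bm)
    dv = (35.0 * m ** 3 * h * (55.0 - v) + 9.0 * n ** 4 * (-90.0 - v)
          + 0.1 * (-65.0 - v) + i_in)
    dh = ah * (1.0 - h) - bh * h
    dn = an * (1.0 - n) - bn * n
    return dv, dh, dn


@_jit
def _net_rhs(ve, he, ne, se, vi, hi, ni, si, q,
             w_ei_T, w_ie_T, w_ii_T, w_ee_T, use_ee,
             drive_e, drive_i, g_q, tau_q,
             tau_re, tau_de, tau_ri, tau_di, e_exc, e_inh):
    g_exc_on_i = w_ei_T @ se
    g_inh_on_i = w_ii_T @ si
    g_inh_on_e = w_ie_T @ si
    i_e = drive_e + g_q * q * (e_exc - ve) + g_inh_on_e * (e_inh - ve)
    if use_ee:
        i_e = i_e + (w_ee_T @ se) * (e_exc - ve)
    i_i = drive_i + g_exc_on_i * (e_exc - vi) + g_inh_on_i * (e_inh - vi)
    dve, dhe, dne = _deriv_rtm(ve, he, ne, i_e)
    dvi, dhi, dni = _deriv_wb(vi, hi, ni, i_i)
    rho_e = 0.5 * (1.0 + np.tanh(ve / 10.0))
    rho_i = 0.5 * (1.0 + np.tanh(vi / 10.0))
    dse = rho_e * (1.0 - se) / tau_re - se / tau_de
    dsi = rho_i * (1.0 - si) / tau_ri - si / tau_di
    dq = -q / tau_q
    return dve, dhe, dne, dse, dvi, dhi, dni, dsi, dq


@_jit
def _integrate_core(ve, he, ne, se, vi, hi, ni, si, q,
                    w_ei_T, w_ie_T, w_ii_T, w_ee_T, use_ee,
                    drive_e, drive_i, g_q, tau_q,
                    dt, n_steps, ev_t, ev_cell,
                    thresh, refr,
                    s_bar, rec_idx, v_rec,
                    st_rec_start, st_v, st_h, st_n,
                    sp_cell, sp_time, last_spike):
    """RK4 network integration. Fills the output buffers in place and
    returns (number of spikes, index of a non-finite cell or -1, blow-up time)."""
    n_e = ve.size
    n_i = vi.size
    n_sp = 0
    ev_ptr = 0
    tau_re, tau_de, e_exc = 0.1, 3.0, 0.0
    tau_ri, tau_di, e_inh = 0.3, 9.0, -75.0
    s_bar[0] = se.mean()
    for r in range(rec_idx.size):
        c = rec_idx[r]
        v_rec[0, r] = ve[c] if c < n_e else vi[c - n_e]
    if st_rec_start == 0 and st_v.shape[0] > 0:
        for j in range(n_e):
            st_v[0, j], st_h[0, j], st_n[0, j] = ve[j], he[j], ne[j]
        for j in range(n_i):
            st_v[0, n_e + j], st_h[0, n_e + j], st_n[0, n_e + j] = vi[j], hi[j], ni[j]

    for k in range(n_steps):
        t = k * dt
        while ev_ptr < ev_t.size and ev_t[ev_ptr] < t + dt:
            q[ev_cell[ev_ptr]] += 1.0
            ev_ptr += 1

        a1 = _net_rhs(ve, he, ne, se, vi, hi, ni, si, q,
                      w_ei_T, w_ie_T, w_ii_T, w_ee_T, use_ee,
                      drive_e, drive_i, g_q, tau_q,
                      tau_re, tau_de, tau_ri, tau_di, e_exc, e_inh)
        hd = 0.5 * dt
        a2 = _net_rhs(ve + hd * a1[0], he + hd * a1[1], ne + hd * a1[2], se + hd * a1[3],
                      vi + hd * a1[4], hi + hd * a1[5], ni + hd * a1[6], si + hd * a1[7],
                      q + hd * a1[8],
                      w_ei_T, w_ie_T, w_ii_T, w_ee_T, use_ee,
                      drive_e, drive_i, g_q, tau_q,
                      tau_re, tau_de, tau_ri, tau_di, e_exc, e_inh)
        a3 = _net_rhs(ve + hd * a2[0], he + hd * a2[1], ne + hd * a2[2], se + hd * a2[3],
                      vi + hd * a2[4], hi + hd * a2[5], ni + hd * a2[6], si + hd * a2[7],
                      q + hd * a2[8],
                      w_ei_T, w_ie_T, w_ii_T, w_ee_T, use_ee,
                      drive_e, drive_i, g_q, tau_q,
                      tau_re, tau_de, tau_ri, tau_di, e_exc, e_inh)
        a4 = _net_rhs(ve + dt * a3[0], he + dt * a3[1], ne + dt * a3[2], se + dt * a3[3],
                      vi + dt * a3[4], hi + dt * a3[5], ni + dt * a3[6], si + dt * a3[7],
                      q + dt * a3[8],
                      w_ei_T, w_ie_T, w_ii_T, w_ee_T, use_ee,
                      drive_e, drive_i, g_q, tau_q,
                      tau_re, tau_de, tau_ri, tau_di, e_exc, e_inh)

        sx = dt / 6.0
        ve_new = ve + sx * (a1[0] + 2 * a2[0] + 2 * a3[0] + a4[0])
        he = np.minimum(np.maximum(he + sx * (a1[1] + 2 * a2[1] + 2 * a3[1] + a4[1]), 0.0), 1.0)
        ne = np.minimum(np.maximum(ne + sx * (a1[2] + 2 * a2[2] + 2 * a3[2] + a4[2]), 0.0), 1.0)
        se = np.minimum(np.maximum(se + sx * (a1[3] + 2 * a2[3] + 2 * a3[3] + a4[3]), 0.0), 1.0)
        vi_new = vi + sx * (a1[4] + 2 * a2[4] + 2 * a3[4] + a4[4])
        hi = np.minimum(np.maximum(hi + sx * (a1[5] + 2 * a2[5] + 2 * a3[5] + a4[5]), 0.0), 1.0)
        ni = np.minimum(np.maximum(ni + sx * (a1[6] + 2 * a2[6] + 2 * a3[6] + a4[6]), 0.0), 1.0)
        si = np.minimum(np.maximum(si + sx * (a1[7] + 2 * a2[7] + 2 * a3[7] + a4[7]), 0.0), 1.0)
        q = np.maximum(q + sx * (a1[8] + 2 * a2[8] + 2 * a3[8] + a4[8]), 0.0)

        t_next = t + dt
        for j in range(n_e + n_i):
            vp = ve[j] if j < n_e else vi[j - n_e]
            vn = ve_new[j] if j < n_e else vi_new[j - n_e]
            if not np.isfinite(vn):
                return n_sp, j, t_next
            if vp < thresh and vn >= thresh:
                t_sp = t + (thresh - vp) / (vn - vp) * dt
                if t_sp - last_spike[j] >= refr:
                    if n_sp < sp_cell.size:
                        sp_cell[n_sp] = j
                        sp_time[n_sp] = t_sp
                        n_sp += 1
                    last_spike[j] = t_sp

        ve, vi = ve_new, vi_new
        s_bar[k + 1] = se.mean()
        for r in range(rec_idx.size):
            c = rec_idx[r]
            v_rec[k + 1, r] = ve[c] if c < n_e else vi[c - n_e]
        if st_v.shape[0] > 0 and k + 1 >= st_rec_start:
            row = k + 1 - st_rec_start
            if row < st_v.shape[0]:
                for j in range(n_e):
                    st_v[row, j], st_h[row, j], st_n[row, j] = ve[j], he[j], ne[j]
                for j in range(n_i):
                    st_v[row, n_e + j] = vi[j]
                    st_h[row, n_e + j] = hi[j]
                    st_n[row, n_e + j] = ni[j]
    return n_sp, -1, 0.0


@_jit
def _pulse_core(is_ecell, v, h, n, drive,
                gx, tx, taux, gi, ti, taui,
                dt, n_steps, thresh, refr,
                sp_cell, sp_time,
                cross_v, cross_h, cross_n, cross_t):
    """RK4 integration of uncoupled cells with per-cell conductance pulses.

    Each cell j receives an excitatory pulse gx[j]·exp(−(t−tx[j])/taux) for
    t ≥ tx[j] (reversal 0 mV) and an inhibitory pulse gi[j]·exp(−(t−ti[j])/taui)
    (reversal −75 mV). Spike (threshold-crossing) times are appended to the
    buffers; the state at each cell's most recent crossing step is stored in
    cross_* (for limit-cycle phase extraction). Returns the spike count.
    """
    n_cells = v.size
    n_sp = 0
    last = np.full(n_cells, -1.0e18)
    for k in range(n_steps):
        t = k * dt
        vp = v.copy()

        # four RK4 stages; pulse conductances evaluated at stage times
        dv = np.empty(n_cells)
        hh = h
        nn = n
        vv = v
        acc_v = np.zeros(n_cells)
        acc_h = np.zeros(n_cells)
        acc_n = np.zeros(n_cells)
        for stage in range(4):
            if stage == 0:
                ts = t
                wt = 1.0
            elif stage == 3:
                ts = t + dt
                wt = 1.0
            else:
                ts = t + 0.5 * dt
                wt = 2.0
            i_in = drive.copy()
            for j in range(n_cells):
                if gx[j] > 0.0 and ts >= tx[j]:
                    i_in[j] += gx[j] * np.exp(-(ts - tx[j]) / taux) * (0.0 - vv[j])
                if gi[j] > 0.0 and ts >= ti[j]:
                    i_in[j] += gi[j] * np.exp(-(ts - ti[j]) / taui) * (-75.0 - vv[j])
            if is_ecell:
                dv, dh, dn = _deriv_rtm(vv, hh, nn, i_in)
            else:
                dv, dh, dn = _deriv_wb(vv, hh, nn, i_in)
            acc_v += wt * dv
            acc_h += wt * dh
            acc_n += wt * dn
            if stage == 0 or stage == 1:
                vv = v + 0.5 * dt * dv
                hh = h + 0.5 * dt * dh
                nn = n + 0.5 * dt * dn
            elif stage == 2:
                vv = v + dt * dv
                hh = h + dt * dh
                nn = n + dt * dn
        v = v + dt / 6.0 * acc_v
        h = np.minimum(np.maximum(h + dt / 6.0 * acc_h, 0.0), 1.0)
        n = np.minimum(np.maximum(n + dt / 6.0 * acc_n, 0.0), 1.0)

        for j in range(n_cells):
            if vp[j] < thresh and v[j] >= thresh:
                t_sp = t + (thresh - vp[j]) / (v[j] - vp[j]) * dt
                if t_sp - last[j] >= refr:
                    if n_sp < sp_cell.size:
                        sp_cell[n_sp] = j
                        sp_time[n_sp] = t_sp
                        n_sp += 1
                    last[j] = t_sp
                    cross_v[j] = v[j]
                    cross_h[j] = h[j]
                    cross_n[j] = n[j]
                    cross_t[j] = t + dt
    return n_sp
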