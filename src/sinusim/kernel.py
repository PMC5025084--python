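"""Compiled RK4 integration kernel.

Classic fixed-step 4th-order Runge-Kutta over the full state vector
(body pool + N compartments x (blood + hepatocyte)).  A step that would
drive any concentration negative is rejected and retried with locally
halved sub-steps rather than clipped, so the conservation audits remain
exact.  Per-part process rates are accumulated alongside the state for
cycle-average observables.

The rate-law mathematics here intentionally mirrors
:mod:`sinusim.ratelaws`; the object layer is the readable reference and
the test suite cross-checks the two on random states.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .state import N_BLOOD, N_HEP, N_PER_COMP

#: Absolute tolerance below zero accepted as round-off and clamped.
NEG_TOL = 1e-9
MAX_REFINE_LEVELS = 7


@njit(cache=True, inline="always")
def _act(c, K, n):
    if c <= 0.0:
        return 0.0
    if n == 1.0:
        x = c / K
    elif n == 2.0:
        r = c / K
        x = r * r
    else:
        x = (c / K) ** n
    return x / (1.0 + x)


@njit(cache=True, inline="always")
def _factor(kind, c, K, n, base, amp, ins_eff, gln_eff, o2):
    if kind <= 1:                      # substrate / allosteric activation
        return _act(c, K, n)
    elif kind == 2:                    # allosteric inhibition
        return 1.0 - _act(c, K, n)
    elif kind == 3:                    # linear (first-order removal)
        return c / K
    elif kind == 4:
        return base + amp * _act(ins_eff, K, n)
    elif kind == 5:
        return base + amp * (1.0 - _act(ins_eff, K, n))
    elif kind == 6:
        return base + amp * _act(gln_eff, K, n)
    elif kind == 7:
        return base + amp * (1.0 - _act(gln_eff, K, n))
    else:                              # oxygen dependence
        return _act(o2, K, n)


@njit(cache=True)
def rhs(t_s, y, dy, r_parts, r_body,
        phys, z_ins, z_gln, scen,
        vb, basis, srebp, m2, s_ptr, s_idx, s_coef,
        t_ptr, t_kind, t_sp, t_K, t_n, t_base, t_amp,
        b_vb, bs_ptr, bs_idx, bs_coef,
        bt_ptr, bt_kind, bt_sp, bt_K, bt_n, bt_base, bt_amp):
    n = int(phys[0])
    Q = phys[1]
    Vs = phys[2]
    Vb = phys[4]
    rho = phys[5]
    k_ir = scen[0]
    srebp_on = scen[1] > 0.5

    for j in range(y.shape[0]):
        dy[j] = 0.0

    # ---- body pool -------------------------------------------------------
    ins_b = y[5]
    gln_b = y[6]
    ieff_b = k_ir * ins_b
    for p in range(b_vb.shape[0]):
        r = b_vb[p]
        for k in range(bt_ptr[p], bt_ptr[p + 1]):
            sp = bt_sp[k]
            c = y[sp] if sp >= 0 else 0.0
            r *= _factor(bt_kind[k], c, bt_K[k], bt_n[k], bt_base[k],
                         bt_amp[k], ieff_b, gln_b, y[7])
        r_body[p] = r
        for k in range(bs_ptr[p], bs_ptr[p + 1]):
            dy[bs_idx[k]] += bs_coef[k] * r

    # pancreatic secretion, systemic hormone clearance, oxygen input
    g = y[0] if y[0] > 0.0 else 0.0
    xi = (g / phys[7]) ** phys[8]
    xg = (g / phys[11]) ** phys[12]
    dy[5] += phys[9] + phys[6] * xi / (1.0 + xi) - phys[14] * ins_b
    dy[6] += phys[13] + phys[10] / (1.0 + xg) - phys[15] * gln_b
    dy[7] += phys[16]

    # feeding inputs
    if scen[4] > 0.5:
        s = np.sin(np.pi * t_s / scen[5])
        w = s * s * s * s * s * s
    else:
        w = 1.0
    dy[0] += scen[6] * scen[2] * w / Vb
    dy[2] += scen[7] * scen[3] * w / Vb

    # ---- plug-flow advection --------------------------------------------
    qvs = Q / Vs
    for i in range(n):
        b0 = N_BLOOD + i * N_PER_COMP
        up0 = 0 if i == 0 else N_BLOOD + (i - 1) * N_PER_COMP
        for s_ in range(N_BLOOD):
            dy[b0 + s_] += qvs * (y[up0 + s_] - y[b0 + s_])
    last0 = N_BLOOD + (n - 1) * N_PER_COMP
    qvb = Q / Vb
    for s_ in range(N_BLOOD):
        dy[s_] += qvb * (y[last0 + s_] - y[s_])

    # ---- hepatic compartments -------------------------------------------
    P = vb.shape[0]
    for i in range(n):
        b0 = N_BLOOD + i * N_PER_COMP
        h0 = b0 + N_BLOOD
        ins_l = y[b0 + 5]
        gln_l = y[b0 + 6]
        o2_l = y[b0 + 7]
        ieff0 = k_ir * ins_l * z_ins[i]
        geff = gln_l * z_gln[i]
        for p in range(P):
            r = vb[p] * m2[p, i]
            if srebp_on and srebp[p] == 1:
                ieff = phys[17]
            else:
                ieff = ieff0
            for k in range(t_ptr[p], t_ptr[p + 1]):
                sp = t_sp[k]
                if sp < 0:
                    c = 0.0
                elif sp < N_HEP:
                    c = y[h0 + sp]
                else:
                    c = y[b0 + sp - N_HEP]
                r *= _factor(t_kind[k], c, t_K[k], t_n[k], t_base[k],
                             t_amp[k], ieff, geff, o2_l)
            r_parts[p, i] = r
            if basis[p] == 0:
                for k in range(s_ptr[p], s_ptr[p + 1]):
                    sp = s_idx[k]
                    if sp < N_HEP:
                        dy[h0 + sp] += s_coef[k] * r
                    else:
                        dy[b0 + sp - N_HEP] += s_coef[k] * r * rho
            else:
                for k in range(s_ptr[p], s_ptr[p + 1]):
                    dy[b0 + s_idx[k] - N_HEP] += s_coef[k] * r


@njit(cache=True)
def _rk4_step(y, t, h, ynew, k1, k2, k3, k4, ytmp, r_parts, r_body,
              phys, z_ins, z_gln, scen,
              vb, basis, srebp, m2, s_ptr, s_idx, s_coef,
              t_ptr, t_kind, t_sp, t_K, t_n, t_base, t_amp,
              b_vb, bs_ptr, bs_idx, bs_coef,
              bt_ptr, bt_kind, bt_sp, bt_K, bt_n, bt_base, bt_amp):
    nst = y.shape[0]
    rhs(t, y, k1, r_parts, r_body, phys, z_ins, z_gln, scen,
        vb, basis, srebp, m2, s_ptr, s_idx, s_coef,
        t_ptr, t_kind, t_sp, t_K, t_n, t_base, t_amp,
        b_vb, bs_ptr, bs_idx, bs_coef,
        bt_ptr, bt_kind, bt_sp, bt_K, bt_n, bt_base, bt_amp)
    for j in range(nst):
        ytmp[j] = y[j] + 0.5 * h * k1[j]
    rhs(t + 0.5 * h, ytmp, k2, r_parts, r_body, phys, z_ins, z_gln, scen,
        vb, basis, srebp, m2, s_ptr, s_idx, s_coef,
        t_ptr, t_kind, t_sp, t_K, t_n, t_base, t_amp,
        b_vb, bs_ptr, bs_idx, bs_coef,
        bt_ptr, bt_kind, bt_sp, bt_K, bt_n, bt_base, bt_amp)
    for j in range(nst):
        ytmp[j] = y[j] + 0.5 * h * k2[j]
    rhs(t + 0.5 * h, ytmp, k3, r_parts, r_body, phys, z_ins, z_gln, scen,
        vb, basis, srebp, m2, s_ptr, s_idx, s_coef,
        t_ptr, t_kind, t_sp, t_K, t_n, t_base, t_amp,
        b_vb, bs_ptr, bs_idx, bs_coef,
        bt_ptr, bt_kind, bt_sp, bt_K, bt_n, bt_base, bt_amp)
    for j in range(nst):
        ytmp[j] = y[j] + h * k3[j]
    rhs(t + h, ytmp, k4, r_parts, r_body, phys, z_ins, z_gln, scen,
        vb, basis, srebp, m2, s_ptr, s_idx, s_coef,
        t_ptr, t_kind, t_sp, t_K, t_n, t_base, t_amp,
        b_vb, bs_ptr, bs_idx, bs_coef,
        bt_ptr, bt_kind, bt_sp, bt_K, bt_n, bt_base, bt_amp)
    h6 = h / 6.0
    ok = True
    for j in range(nst):
        v = y[j] + h6 * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
        if v < 0.0:
            if v < -NEG_TOL:
                ok = False
            v = 0.0
        ynew[j] = v
    return ok


@njit(cache=True)
def integrate_kernel(y, t0, dt, n_steps, sample_every,
                     acc_y, acc_rp, acc_rb, traj, traj_t,
                     phys, z_ins, z_gln, scen,
                     vb, basis, srebp, m2, s_ptr, s_idx, s_coef,
                     t_ptr, t_kind, t_sp, t_K, t_n, t_base, t_amp,
                     b_vb, bs_ptr, bs_idx, bs_coef,
                     bt_ptr, bt_kind, bt_sp, bt_K, bt_n, bt_base, bt_amp):
    """Advance ``y`` in place by ``n_steps`` of size ``dt`` from ``t0``.

    Accumulates state and per-part rate sums for averaging, samples the
    trajectory every ``sample_every`` steps, and returns
    (status, n_accumulated, n_sampled); status is -1 on success or the
    index of the first species that could not be kept non-negative.
    """
    nst = y.shape[0]
    P = vb.shape[0]
    n = int(phys[0])
    k1 = np.zeros(nst)
    k2 = np.zeros(nst)
    k3 = np.zeros(nst)
    k4 = np.zeros(nst)
    ytmp = np.zeros(nst)
    ynew = np.zeros(nst)
    ycur = np.zeros(nst)
    r_parts = np.zeros((P, n))
    r_body = np.zeros(b_vb.shape[0])
    n_acc = 0
    n_samp = 0
    t = t0
    for step in range(n_steps):
        ok = _rk4_step(y, t, dt, ynew, k1, k2, k3, k4, ytmp, r_parts, r_body,
                       phys, z_ins, z_gln, scen,
                       vb, basis, srebp, m2, s_ptr, s_idx, s_coef,
                       t_ptr, t_kind, t_sp, t_K, t_n, t_base, t_amp,
                       b_vb, bs_ptr, bs_idx, bs_coef,
                       bt_ptr, bt_kind, bt_sp, bt_K, bt_n, bt_base, bt_amp)
        if ok:
            for j in range(nst):
                y[j] = ynew[j]
        else:
            # negative-concentration guard: retry with halved sub-steps
            success = False
            for lvl in range(1, MAX_REFINE_LEVELS + 1):
                nsub = 1 << lvl
                h = dt / nsub
                for j in range(nst):
                    ycur[j] = y[j]
                good = True
                tt = t
                for _ss in range(nsub):
                    if not _rk4_step(ycur, tt, h, ynew, k1, k2, k3, k4, ytmp,
                                     r_parts, r_body,
                                     phys, z_ins, z_gln, scen,
                                     vb, basis, srebp, m2, s_ptr, s_idx,
                                     s_coef, t_ptr, t_kind, t_sp, t_K, t_n,
                                     t_base, t_amp,
                                     b_vb, bs_ptr, bs_idx, bs_coef,
                                     bt_ptr, bt_kind, bt_sp, bt_K, bt_n,
                                     bt_base, bt_amp):
                        good = False
                        break
                    for j in range(nst):
                        ycur[j] = ynew[j]
                    tt += h
                if good:
                    success = True
                    break
            if not success:
                worst = 0
                vmin = ynew[0]
                for j in range(nst):
                    if ynew[j] < vmin:
                        vmin = ynew[j]
                        worst = j
                return worst, n_acc, n_samp
            for j in range(nst):
                y[j] = ycur[j]
        t = t0 + (step + 1) * dt
        # accumulate state and the k4-stage rates (evaluated ~ at t)
        for j in range(nst):
            acc_y[j] += y[j]
        for p in range(P):
            for i in range(n):
                acc_rp[p, i] += r_parts[p, i]
        for p in range(r_body.shape[0]):
            acc_rb[p] += r_body[p]
        n_acc += 1
        if sample_every > 0 and (step + 1) % sample_every == 0 \
                and n_samp < traj.shape[0]:
            for j in range(nst):
                traj[n_samp, j] = y[j]
            traj_t[n_samp] = t
            n_samp += 1
    return -1, n_acc, n_samp
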