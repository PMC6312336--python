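"""Compiled integration kernels.

Unit conventions used throughout the compiled code:

==============  =========
quantity        unit
==============  =========
time            ms
voltage         mV
capacitance     uF (absolute, per compartment)
conductance     mS (absolute); synaptic inputs arrive in nS
current         uA (g [mS] * V [mV]); injected currents arrive in nA
charge          nC (uA * ms)
==============  =========

The cable is an open chain (dendrite 1 tip ... base, soma, dendrite 2
base ... tip), so the Crank-Nicolson system is tridiagonal and solved
with the Thomas algorithm at every step.  The KLT activation gate w is
kept on a staggered (half-step) time grid and advanced with an
exponential integrator, so the conductance entering each voltage step
is a midpoint value and the scheme stays second-order accurate.

The gating functions w_inf(V) and exp(-dt / tau_w(V)) are evaluated
through linearly interpolated lookup tables built by the caller; the
table grid is chosen so that the resting potential falls exactly on a
node, which keeps the calibrated resting state an exact fixed point.
"""

import numpy as np
from numba import njit

# Normalization of the adopted KLT activation time-constant curve so
# that its value at -60 mV equals 1 ms (see model_core for the gating
# calibration).
TAU_W_NORM = 6.045454545454546


@njit(cache=True, inline="always")
def _lerp(tab, vmin, inv_dv, nmax, v):
    x = (v - vmin) * inv_dv
    if x <= 0.0:
        return tab[0]
    if x >= nmax:
        return tab[nmax]
    i = int(x)
    f = x - i
    return tab[i] * (1.0 - f) + tab[i + 1] * f


@njit(cache=True)
def integrate_cable(v, w, n_steps, dt,
                    cap, g_leak, g_klt_max,
                    e_l, e_k, e_na, e_syn,
                    vmin_tab, inv_dv_tab, winf_tab, wdecay_tab,
                    coup,
                    syn_idx, syn_g, syn_scale,
                    inj_idx, inj,
                    f_leak_na, f_syn_na,
                    rec_idx, v_rec, w_rec, record_w):
    """Crank-Nicolson step loop.  Mutates ``v`` and ``w`` in place.

    Returns (fluxes[5], v_peak, w_min, w_max, ok) where fluxes are the
    time-integrated charges [nC] in the order (leak Na in, leak K out,
    syn Na in, syn K out, KLT K out), summed over the whole cell, and
    v_peak is the per-compartment maximum voltage reached.
    """
    n = v.shape[0]
    m = syn_idx.shape[0]
    p = inj_idx.shape[0]
    nrec = rec_idx.shape[0]
    ntab = winf_tab.shape[0] - 1

    lo = np.empty(n)
    di = np.empty(n)
    up = np.empty(n)
    rhs = np.empty(n)
    cp = np.empty(n)
    dp = np.empty(n)
    gk = np.empty(n)
    gs_mid = np.zeros(n)
    b_ext = np.zeros(n)
    v_old = np.empty(n)

    csum = np.zeros(n)
    for i in range(n - 1):
        csum[i] += coup[i]
        csum[i + 1] += coup[i]

    v_peak = v.copy()
    w_min = 1.0
    w_max = 0.0
    for i in range(n):
        if w[i] < w_min:
            w_min = w[i]
        if w[i] > w_max:
            w_max = w[i]

    # nodal ionic flux rates [uA] at the current time point
    acc_ln = 0.0
    acc_lk = 0.0
    for i in range(n):
        acc_ln += g_leak[i] * (e_na - v[i])
        acc_lk += g_leak[i] * (v[i] - e_k)
    rate_ln = f_leak_na * acc_ln
    rate_lk = (1.0 - f_leak_na) * acc_lk
    rate_sn = 0.0
    rate_sk = 0.0
    for j in range(m):
        gs = syn_g[j, 0] * syn_scale * 1e-6  # nS -> mS
        rate_sn += f_syn_na * gs * (e_na - v[syn_idx[j]])
        rate_sk += (1.0 - f_syn_na) * gs * (v[syn_idx[j]] - e_k)

    q_ln = 0.0
    q_lk = 0.0
    q_sn = 0.0
    q_sk = 0.0
    q_kk = 0.0

    for r in range(nrec):
        v_rec[r, 0] = v[rec_idx[r]]

    ok = True
    for step in range(n_steps):
        # gate advance to the half step using the current voltage
        for i in range(n):
            winf = _lerp(winf_tab, vmin_tab, inv_dv_tab, ntab, v[i])
            a = _lerp(wdecay_tab, vmin_tab, inv_dv_tab, ntab, v[i])
            w[i] = winf + (w[i] - winf) * a
            if w[i] < w_min:
                w_min = w[i]
            if w[i] > w_max:
                w_max = w[i]
            gk[i] = g_klt_max[i] * w[i] ** 4

        # midpoint synaptic conductances and external currents
        for j in range(m):
            i = syn_idx[j]
            g = 0.5 * (syn_g[j, step] + syn_g[j, step + 1]) \
                * syn_scale * 1e-6
            gs_mid[i] += g
            b_ext[i] += g * e_syn
        for j in range(p):
            i = inj_idx[j]
            b_ext[i] += 0.5 * (inj[j, step] + inj[j, step + 1]) * 1e-3

        # assemble and solve the tridiagonal CN system
        for i in range(n):
            g_i = g_leak[i] + gk[i] + gs_mid[i]
            b_i = g_leak[i] * e_l + gk[i] * e_k + b_ext[i]
            ax = 0.0
            if i > 0:
                ax += coup[i - 1] * (v[i - 1] - v[i])
                lo[i] = -0.5 * coup[i - 1]
            if i < n - 1:
                ax += coup[i] * (v[i + 1] - v[i])
                up[i] = -0.5 * coup[i]
            rhs[i] = (cap[i] / dt - 0.5 * g_i) * v[i] + 0.5 * ax + b_i
            di[i] = cap[i] / dt + 0.5 * g_i + 0.5 * csum[i]
            v_old[i] = v[i]
            gs_mid[i] = 0.0
            b_ext[i] = 0.0

        cp[0] = up[0] / di[0]
        dp[0] = rhs[0] / di[0]
        for i in range(1, n):
            denom = di[i] - lo[i] * cp[i - 1]
            cp[i] = up[i] / denom
            dp[i] = (rhs[i] - lo[i] * dp[i - 1]) / denom
        v[n - 1] = dp[n - 1]
        for i in range(n - 2, -1, -1):
            v[i] = dp[i] - cp[i] * v[i + 1]

        for i in range(n):
            if not np.isfinite(v[i]):
                ok = False
            if v[i] > v_peak[i]:
                v_peak[i] = v[i]
            # KLT K efflux, midpoint rule
            q_kk += dt * gk[i] * (0.5 * (v_old[i] + v[i]) - e_k)
        if not ok:
            break

        # trapezoidal accumulation of nodal leak/synaptic fluxes
        new_ln = 0.0
        new_lk = 0.0
        for i in range(n):
            new_ln += g_leak[i] * (e_na - v[i])
            new_lk += g_leak[i] * (v[i] - e_k)
        new_ln *= f_leak_na
        new_lk *= (1.0 - f_leak_na)
        new_sn = 0.0
        new_sk = 0.0
        for j in range(m):
            gs = syn_g[j, step + 1] * syn_scale * 1e-6
            new_sn += f_syn_na * gs * (e_na - v[syn_idx[j]])
            new_sk += (1.0 - f_syn_na) * gs * (v[syn_idx[j]] - e_k)
        q_ln += 0.5 * dt * (rate_ln + new_ln)
        q_lk += 0.5 * dt * (rate_lk + new_lk)
        q_sn += 0.5 * dt * (rate_sn + new_sn)
        q_sk += 0.5 * dt * (rate_sk + new_sk)
        rate_ln = new_ln
        rate_lk = new_lk
        rate_sn = new_sn
        rate_sk = new_sk

        for r in range(nrec):
            v_rec[r, step + 1] = v[rec_idx[r]]
        if record_w:
            for i in range(n):
                w_rec[i, step] = w[i]

    fluxes = np.empty(5)
    fluxes[0] = q_ln
    fluxes[1] = q_lk
    fluxes[2] = q_sn
    fluxes[3] = q_sk
    fluxes[4] = q_kk
    return fluxes, v_peak, w_min, w_max, ok


@njit(cache=True)
def axon_spikes(v_soma, dt, tau_m, tau_c, threshold, reset, refractory,
                v_rest):
    """Feed-forward axonal threshold unit driven by the somatic voltage.

    dVa/dt = -(Va - v_rest)/tau_m + (V_soma - Va)/tau_c, integrated with
    an exact exponential update per step (soma held at its endpoint
    value).  Upward threshold crossings emit spikes, reset Va, and
    suppress detection for the refractory period.
    """
    tau_eff = 1.0 / (1.0 / tau_m + 1.0 / tau_c)
    decay = np.exp(-dt / tau_eff)
    va = tau_eff * (v_rest / tau_m + v_soma[0] / tau_c)
    n = v_soma.shape[0]
    max_spikes = int(n * dt / refractory) + 2
    times = np.empty(max_spikes)
    count = 0
    t_last = -1e30
    for step in range(1, n):
        vinf = tau_eff * (v_rest / tau_m + v_soma[step] / tau_c)
        va_prev = va
        va = vinf + (va - vinf) * decay
        t = step * dt
        if t - t_last < refractory:
            continue
        if va >= threshold and va_prev < threshold:
            times[count] = t
            count += 1
            t_last = t
            va = reset
    return times[:count].copy()
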