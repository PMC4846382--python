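"""Compiled inner loops for the two models.

The large-scale network uses the exponential-Euler scheme: every variable with
dynamics dx/dt = (x_inf - x)/tau is advanced by

    x <- x_inf + (x - x_inf) * exp(-dt/tau),

with x_inf and tau frozen at the step's start.  The voltage equation is cast
in the same form via the conductance decomposition tau_V = C / sum(g) and
V_inf = sum(g*E) / sum(g).  Synaptic conductances decay exactly and receive
instantaneous increments from spikes detected on the previous step.

The reduced 3-neuron model is integrated with fixed-step classical RK4.

Everything here works on plain float64 arrays; the dataclass-level API lives
in ``engine`` and ``reduced``.
"""

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_NONFINITE = 1


@njit(cache=True)
def hh_network_loop(
    dt,
    n_steps,
    V, m_Na, h_Na, m_NaP, h_NaP, m_K, g_syn,  # state arrays, modified in place
    E_L, gbar_NaP,                              # heterogeneous parameters
    W,                                          # W[j, i]: weight j -> i
    C, gbar_Na, gbar_K, gbar_L, E_Na, E_K, E_SynE,
    gbar_SynE, tau_SynE, threshold,
    spike_neuron, spike_step, max_spikes,       # preallocated spike buffers
    rec_ids, record_every, V_rec, h_rec,        # trace recording
    slave_m_nap,                                # bool: m_NaP at steady state
):
    N = V.shape[0]
    n_rec = rec_ids.shape[0]
    decay_syn = np.exp(-dt / tau_SynE)
    spiked = np.zeros(N, np.bool_)
    n_spikes = 0
    rec_row = 0
    for step in range(n_steps):
        # increments from spikes detected on the previous step
        for j in range(N):
            if spiked[j]:
                for i in range(N):
                    w = W[j, i]
                    if w > 0.0:
                        g_syn[i] += gbar_SynE * w
        for i in range(N):
            v = V[i]
            # gate kinetics at step start
            mNa_inf = 1.0 / (1.0 + np.exp(-(v + 43.8) / 6.0))
            tau_mNa = 0.25 / np.cosh((v + 43.8) / 14.0)
            hNa_inf = 1.0 / (1.0 + np.exp((v + 67.5) / 10.8))
            tau_hNa = 8.46 / np.cosh((v + 67.5) / 12.8)
            mNaP_inf = 1.0 / (1.0 + np.exp(-(v + 47.1) / 3.1))
            tau_mNaP = 1.0 / np.cosh((v + 47.1) / 6.2)
            hNaP_inf = 1.0 / (1.0 + np.exp((v + 60.0) / 9.0))
            tau_hNaP = 6000.0 / np.cosh((v + 60.0) / 9.0)
            x = v + 45.0
            if x > 1e-7 or x < -1e-7:
                aK = 0.01 * x / (1.0 - np.exp(-x / 5.0))
            else:
                aK = 0.05
            bK = 0.17 * np.exp(-(v + 49.0) / 40.0)
            mK_inf = aK / (aK + bK)
            tau_mK = 1.0 / (aK + bK)

            # gates advance first (steady states/taus frozen at the step's
            # start); the voltage update then uses the fresh gate values --
            # the Gauss-Seidel sweep that keeps spike shapes accurate at the
            # 0.1 ms step (verified against an adaptive reference integrator)
            m_Na[i] = mNa_inf + (m_Na[i] - mNa_inf) * np.exp(-dt / tau_mNa)
            h_Na[i] = hNa_inf + (h_Na[i] - hNa_inf) * np.exp(-dt / tau_hNa)
            m_NaP[i] = mNaP_inf + (m_NaP[i] - mNaP_inf) * np.exp(-dt / tau_mNaP)
            h_NaP[i] = hNaP_inf + (h_NaP[i] - hNaP_inf) * np.exp(-dt / tau_hNaP)
            m_K[i] = mK_inf + (m_K[i] - mK_inf) * np.exp(-dt / tau_mK)

            # conductance decomposition of the voltage equation
            m_nap = mNaP_inf if slave_m_nap else m_NaP[i]
            g_na = gbar_Na * m_Na[i] * m_Na[i] * m_Na[i] * h_Na[i]
            g_nap = gbar_NaP[i] * m_nap * h_NaP[i]
            g_k = gbar_K * m_K[i] * m_K[i] * m_K[i] * m_K[i]
            g_tot = g_na + g_nap + g_k + gbar_L + g_syn[i]
            v_inf = (
                g_na * E_Na + g_nap * E_Na + g_k * E_K
                + gbar_L * E_L[i] + g_syn[i] * E_SynE
            ) / g_tot
            v_new = v_inf + (v - v_inf) * np.exp(-dt * g_tot / C)
            g_syn[i] *= decay_syn

            if not np.isfinite(v_new) or v_new > 200.0 or v_new < -200.0:
                return STATUS_NONFINITE, n_spikes, step
            # upward threshold crossing: V_prev < thr <= V_new
            sp = v < threshold and v_new >= threshold
            spiked[i] = sp
            if sp and n_spikes < max_spikes:
                spike_neuron[n_spikes] = i
                spike_step[n_spikes] = step + 1
                n_spikes += 1
            V[i] = v_new

        if record_every > 0 and (step + 1) % record_every == 0:
            for k in range(n_rec):
                V_rec[rec_row, k] = V[rec_ids[k]]
                h_rec[rec_row, k] = h_NaP[rec_ids[k]]
            rec_row += 1
    return STATUS_OK, n_spikes, n_steps


@njit(cache=True, inline="always")
def _reduced_rhs(
    V, h, dV, dh, f_buf,
    E_L_eff, W,
    C, gbar_NaP, gbar_L, gbar_SynE, E_Na, E_SynE,
    V_m, k_m, V_h, k_h, V_tau, k_tau, tau_max, V_min, V_max,
):
    n = V.shape[0]
    for j in range(n):
        vj = V[j]
        if vj < V_min:
            f_buf[j] = 0.0
        elif vj >= V_max:
            f_buf[j] = 1.0
        else:
            f_buf[j] = (vj - V_min) / (V_max - V_min)
    for i in range(n):
        v = V[i]
        drive = 0.0
        for j in range(n):
            if j != i:
                drive += W[j, i] * f_buf[j]
        m_inf = 1.0 / (1.0 + np.exp((v - V_m) / k_m))
        i_nap = gbar_NaP * m_inf * h[i] * (v - E_Na)
        i_l = gbar_L * (v - E_L_eff[i])
        i_syn = drive * gbar_SynE * (v - E_SynE)
        dV[i] = -(i_nap + i_l + i_syn) / C
        h_inf = 1.0 / (1.0 + np.exp((v - V_h) / k_h))
        tau_h = tau_max / np.cosh((v - V_tau) / k_tau)
        dh[i] = (h_inf - h[i]) / tau_h


@njit(cache=True)
def reduced_rk4_loop(
    dt, n_steps,
    V, h,                       # state arrays, modified in place
    E_L, W,
    C, gbar_NaP, gbar_L, gbar_SynE, E_Na, E_SynE,
    V_m, k_m, V_h, k_h, V_tau, k_tau, tau_max, V_min, V_max,
    record_every, V_rec, h_rec,
    pert_start_step, pert_end_step, pert_factor,
):
    """Classical RK4 for the activity-based model.

    ``pert_*`` implement a time-windowed multiplicative scaling of all E_L
    values (the excitability-perturbation protocol); with pert_factor = 1 or
    an empty window the baseline model is integrated.
    """
    n = V.shape[0]
    E_L_eff = E_L.copy()
    k1v = np.empty(n); k1h = np.empty(n)
    k2v = np.empty(n); k2h = np.empty(n)
    k3v = np.empty(n); k3h = np.empty(n)
    k4v = np.empty(n); k4h = np.empty(n)
    Vt = np.empty(n); ht = np.empty(n)
    f_buf = np.empty(n)
    rec_row = 0
    for step in range(n_steps):
        if pert_start_step <= step < pert_end_step:
            for i in range(n):
                E_L_eff[i] = E_L[i] * pert_factor
        else:
            for i in range(n):
                E_L_eff[i] = E_L[i]
        _reduced_rhs(V, h, k1v, k1h, f_buf, E_L_eff, W, C, gbar_NaP, gbar_L,
                     gbar_SynE, E_Na, E_SynE, V_m, k_m, V_h, k_h, V_tau,
                     k_tau, tau_max, V_min, V_max)
        for i in range(n):
            Vt[i] = V[i] + 0.5 * dt * k1v[i]
            ht[i] = h[i] + 0.5 * dt * k1h[i]
        _reduced_rhs(Vt, ht, k2v, k2h, f_buf, E_L_eff, W, C, gbar_NaP, gbar_L,
                     gbar_SynE, E_Na, E_SynE, V_m, k_m, V_h, k_h, V_tau,
                     k_tau, tau_max, V_min, V_max)
        for i in range(n):
            Vt[i] = V[i] + 0.5 * dt * k2v[i]
            ht[i] = h[i] + 0.5 * dt * k2h[i]
        _reduced_rhs(Vt, ht, k3v, k3h, f_buf, E_L_eff, W, C, gbar_NaP, gbar_L,
                     gbar_SynE, E_Na, E_SynE, V_m, k_m, V_h, k_h, V_tau,
                     k_tau, tau_max, V_min, V_max)
        for i in range(n):
            Vt[i] = V[i] + dt * k3v[i]
            ht[i] = h[i] + dt * k3h[i]
        _reduced_rhs(Vt, ht, k4v, k4h, f_buf, E_L_eff, W, C, gbar_NaP, gbar_L,
                     gbar_SynE, E_Na, E_SynE, V_m, k_m, V_h, k_h, V_tau,
                     k_tau, tau_max, V_min, V_max)
        bad = False
        for i in range(n):
            V[i] += dt / 6.0 * (k1v[i] + 2.0 * k2v[i] + 2.0 * k3v[i] + k4v[i])
            h[i] += dt / 6.0 * (k1h[i] + 2.0 * k2h[i] + 2.0 * k3h[i] + k4h[i])
            if not np.isfinite(V[i]):
                bad = True
        if bad:
            return STATUS_NONFINITE, step
        if record_every > 0 and (step + 1) % record_every == 0:
            for i in range(n):
                V_rec[rec_row, i] = V[i]
                h_rec[rec_row, i] = h[i]
            rec_row += 1
    return STATUS_OK, n_steps
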