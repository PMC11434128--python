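"""Numba kernels for the fixed-step network integration.

State is stored structure-of-arrays: one (n_vars, n_cells) float64 matrix per
population and flat per-edge arrays per projection.  Gating variables use the
exponential update x ← x∞ + (x − x∞)·e^(−dt/τ) (exact for frozen voltage, so
fractions can never leave [0, 1]); voltages use a semi-implicit update in
which all conductances are frozen at the start of the step and the resulting
linear system (2×2 per cortical cell) is solved exactly.

Index layouts below are the single source of truth; `engine.py` packs
parameter vectors against them.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .channels import (_ca_step, _it_re, _it_tc, _nernst_eca, exp_gate_update,
                       hva_rates, kca_rates, km_rates, sigmoid_inf,
                       traub_k_rates, traub_na_rates)
from .synapses import (depression_update, gabab_activation, gabab_step,
                       kinetic_open_step, mini_next_time, nmda_mg_block)

# --- cortical population state rows ---------------------------------------
C_VS, C_VD, C_MS, C_HS, C_NS, C_MNAPS, C_MD, C_HD, C_MNAPD, C_MKM, \
    C_MKCA, C_MHVA, C_HHVA, C_CA, C_LAST = range(15)
N_CORT_STATE = 15

# --- cortical parameter vector --------------------------------------------
(CP_CM, CP_AS, CP_AD, CP_GC, CP_VTRAUB, CP_ENA, CP_EK,
 CP_GS_NA, CP_GS_K, CP_GS_NAP, CP_GS_LEAK, CP_ES_LEAK, CP_GS_KL,
 CP_GD_NA, CP_GD_NAP, CP_GD_KM, CP_GD_KCA, CP_GD_HVA, CP_GD_LEAK,
 CP_ED_LEAK, CP_GD_KL,
 CP_KM_Q, CP_KM_RATE, CP_KM_VHALF, CP_KM_VSLOPE,
 CP_KCA_Q, CP_KCA_A, CP_KCA_B,
 CP_NAP_VHALF, CP_NAP_SLOPE, CP_NAP_TAU, CP_HVA_Q,
 CP_CA_REST, CP_CA_TAU, CP_CA_INFLUX, CP_CA_OUT, CP_CA_TEMP,
 CP_THRESH, CP_REFRACT) = range(39)
N_CORT_PARAMS = 39

# --- thalamic population state rows ---------------------------------------
T_V, T_M, T_H, T_N, T_MT, T_HT, T_CA, T_O, T_OL, T_P1, T_LAST = range(11)
N_THAL_STATE = 11

# --- thalamic parameter vector --------------------------------------------
(TP_CM, TP_AREA, TP_VTRAUB, TP_ENA, TP_EK, TP_G_NA, TP_G_K, TP_G_T, TP_G_H,
 TP_G_LEAK, TP_E_LEAK, TP_G_KL,
 TP_IT_MVH, TP_IT_MSL, TP_IT_HVH, TP_IT_HSL, TP_IT_PHIM, TP_IT_PHIH,
 TP_IH_VH, TP_IH_SL, TP_IH_K1, TP_IH_K2, TP_IH_K3, TP_IH_K4,
 TP_IH_GINC, TP_IH_EREV,
 TP_CA_REST, TP_CA_TAU, TP_CA_INFLUX, TP_CA_OUT, TP_CA_TEMP,
 TP_THRESH, TP_REFRACT, TP_IS_TC) = range(34)
N_THAL_PARAMS = 34

# --- excitatory projection scalar params ----------------------------------
(EP_ALPHA_A, EP_BETA_A, EP_E_A, EP_ALPHA_N, EP_BETA_N, EP_E_N, EP_MG,
 EP_PULSE_AMP, EP_PULSE_DUR, EP_DELAY, EP_U, EP_TAU_D, EP_USE_DEP,
 EP_USE_MINIS, EP_MINI_RATE, EP_MINI_TAU, EP_MINI_JUMP, EP_HAS_NMDA) = range(18)
N_EXC_PARAMS = 18

# --- inhibitory projection scalar params ----------------------------------
(IP_ALPHA_A, IP_BETA_A, IP_E_GABAA, IP_K1, IP_K2, IP_K3, IP_K4, IP_KD,
 IP_E_GABAB, IP_PULSE_AMP, IP_PULSE_DUR, IP_DELAY, IP_HAS_GABAB) = range(13)
N_INH_PARAMS = 13


@njit(cache=True)
def exc_projection_step(t, dt, pp, pre, post, g_ampa, g_nmda,
                        pre_last, edge_last, edge_e, o_ampa, o_nmda,
                        mini_next, mini_counter, mini_stream,
                        v_post, gbuf, gebuf, ampa_scale):
    """Advance AMPA(+NMDA) edges one step; accumulate conductance (µS) and
    conductance·reversal sums onto the target compartment buffers."""
    for k in range(pre.size):
        ip = pre[k]
        t_sp = pre_last[ip]
        if t_sp > edge_last[k]:
            if pp[EP_USE_DEP] != 0.0:
                edge_e[k] = depression_update(edge_e[k], t_sp - edge_last[k],
                                              pp[EP_U], pp[EP_TAU_D])
            edge_last[k] = t_sp
            if pp[EP_USE_MINIS] != 0.0:
                nt, nc = mini_next_time(mini_stream[k], mini_counter[k], t_sp,
                                        t_sp, pp[EP_MINI_RATE], pp[EP_MINI_TAU])
                mini_next[k] = nt
                mini_counter[k] = nc
        if pp[EP_USE_MINIS] != 0.0:
            while mini_next[k] <= t + dt:
                o_ampa[k] += pp[EP_MINI_JUMP] * (1.0 - o_ampa[k])
                nt, nc = mini_next_time(mini_stream[k], mini_counter[k],
                                        edge_last[k], mini_next[k],
                                        pp[EP_MINI_RATE], pp[EP_MINI_TAU])
                mini_next[k] = nt
                mini_counter[k] = nc
        s = t - (edge_last[k] + pp[EP_DELAY])
        t_conc = pp[EP_PULSE_AMP] if (0.0 <= s < pp[EP_PULSE_DUR]) else 0.0
        o_ampa[k] = kinetic_open_step(o_ampa[k], t_conc, pp[EP_ALPHA_A],
                                      pp[EP_BETA_A], dt)
        jp = post[k]
        dep = edge_e[k] if pp[EP_USE_DEP] != 0.0 else 1.0
        g = g_ampa[k] * ampa_scale * dep * o_ampa[k]
        ge = g * pp[EP_E_A]
        if pp[EP_HAS_NMDA] != 0.0:
            o_nmda[k] = kinetic_open_step(o_nmda[k], t_conc, pp[EP_ALPHA_N],
                                          pp[EP_BETA_N], dt)
            gn = g_nmda[k] * o_nmda[k] * nmda_mg_block(v_post[jp], pp[EP_MG])
            g += gn
            ge += gn * pp[EP_E_N]
        gbuf[jp] += g
        gebuf[jp] += ge


@njit(cache=True)
def inh_projection_step(t, dt, pp, pre, post, g_gabaa, g_gabab,
                        pre_last, edge_last, o_gabaa, r_gb, g_gb,
                        gbuf, gebuf, gaba_scale):
    """Advance GABA-A (+ second-messenger GABA-B) edges one step."""
    for k in range(pre.size):
        ip = pre[k]
        t_sp = pre_last[ip]
        if t_sp > edge_last[k]:
            edge_last[k] = t_sp
        s = t - (edge_last[k] + pp[IP_DELAY])
        t_conc = pp[IP_PULSE_AMP] if (0.0 <= s < pp[IP_PULSE_DUR]) else 0.0
        o_gabaa[k] = kinetic_open_step(o_gabaa[k], t_conc, pp[IP_ALPHA_A],
                                       pp[IP_BETA_A], dt)
        jp = post[k]
        g = g_gabaa[k] * gaba_scale * o_gabaa[k]
        ge = g * pp[IP_E_GABAA]
        if pp[IP_HAS_GABAB] != 0.0:
            r_gb[k], g_gb[k] = gabab_step(r_gb[k], g_gb[k], t_conc, dt,
                                          pp[IP_K1], pp[IP_K2], pp[IP_K3],
                                          pp[IP_K4])
            gb = g_gabab[k] * gabab_activation(g_gb[k], pp[IP_KD])
            g += gb
            ge += gb * pp[IP_E_GABAB]
        gbuf[jp] += g
        gebuf[jp] += ge


@njit(cache=True)
def cortical_step(S, P, gbuf_d, gebuf_d, kl_scale, t_new, dt, spike_idx):
    """One step of a cortical (two-compartment) population.

    ``gbuf_d``/``gebuf_d`` hold the dendritic synaptic conductance sums (µS)
    accumulated by the projection kernels.  Returns the number of somatic
    spikes; their cell indices are written into ``spike_idx``.
    """
    n = S.shape[1]
    cm_dt = P[CP_CM] / dt
    a_s = P[CP_AS]
    a_d = P[CP_AD]
    gcs = P[CP_GC] * 1e-3 / a_s  # axial conductance density (mS/cm²)
    gcd = P[CP_GC] * 1e-3 / a_d
    n_spikes = 0
    for i in range(n):
        vs = S[C_VS, i]
        vd = S[C_VD, i]
        # -- gating: exponential updates at start-of-step voltages
        am, bm, ah, bh = traub_na_rates(vs, P[CP_VTRAUB])
        an, bn = traub_k_rates(vs, P[CP_VTRAUB])
        S[C_MS, i] = exp_gate_update(S[C_MS, i], am / (am + bm), 1.0 / (am + bm), dt)
        S[C_HS, i] = exp_gate_update(S[C_HS, i], ah / (ah + bh), 1.0 / (ah + bh), dt)
        S[C_NS, i] = exp_gate_update(S[C_NS, i], an / (an + bn), 1.0 / (an + bn), dt)
        nap_inf_s = sigmoid_inf(vs, P[CP_NAP_VHALF], P[CP_NAP_SLOPE])
        S[C_MNAPS, i] = exp_gate_update(S[C_MNAPS, i], nap_inf_s, P[CP_NAP_TAU], dt)

        am, bm, ah, bh = traub_na_rates(vd, P[CP_VTRAUB])
        S[C_MD, i] = exp_gate_update(S[C_MD, i], am / (am + bm), 1.0 / (am + bm), dt)
        S[C_HD, i] = exp_gate_update(S[C_HD, i], ah / (ah + bh), 1.0 / (ah + bh), dt)
        nap_inf_d = sigmoid_inf(vd, P[CP_NAP_VHALF], P[CP_NAP_SLOPE])
        S[C_MNAPD, i] = exp_gate_update(S[C_MNAPD, i], nap_inf_d, P[CP_NAP_TAU], dt)
        akm, bkm = km_rates(vd, P[CP_KM_Q], P[CP_KM_RATE], P[CP_KM_VHALF],
                            P[CP_KM_VSLOPE])
        S[C_MKM, i] = exp_gate_update(S[C_MKM, i], akm / (akm + bkm),
                                      1.0 / (akm + bkm), dt)
        akca, bkca = kca_rates(S[C_CA, i], P[CP_KCA_Q], P[CP_KCA_A], P[CP_KCA_B])
        S[C_MKCA, i] = exp_gate_update(S[C_MKCA, i], akca / (akca + bkca),
                                       1.0 / (akca + bkca), dt)
        amh, bmh, ahh, bhh = hva_rates(vd, P[CP_HVA_Q])
        S[C_MHVA, i] = exp_gate_update(S[C_MHVA, i], amh / (amh + bmh),
                                       1.0 / (amh + bmh), dt)
        S[C_HHVA, i] = exp_gate_update(S[C_HHVA, i], ahh / (ahh + bhh),
                                       1.0 / (ahh + bhh), dt)

        # -- calcium pool driven by the high-voltage-activated Ca current
        e_ca = _nernst_eca(S[C_CA, i], P[CP_CA_OUT], P[CP_CA_TEMP])
        g_hva = P[CP_GD_HVA] * S[C_MHVA, i] * S[C_MHVA, i] * S[C_HHVA, i]
        i_hva = g_hva * (vd - e_ca)
        S[C_CA, i] = _ca_step(S[C_CA, i], P[CP_CA_REST], P[CP_CA_TAU],
                              P[CP_CA_INFLUX], i_hva, dt)

        # -- conductance sums (mS/cm²) and driving terms (µA/cm²)
        g_na_s = P[CP_GS_NA] * S[C_MS, i] ** 3 * S[C_HS, i]
        g_k_s = P[CP_GS_K] * S[C_NS, i] ** 4
        g_nap_s = P[CP_GS_NAP] * S[C_MNAPS, i]
        g_s = g_na_s + g_k_s + g_nap_s + P[CP_GS_LEAK] + kl_scale * P[CP_GS_KL]
        b_s = (g_na_s * P[CP_ENA] + g_k_s * P[CP_EK] + g_nap_s * P[CP_ENA]
               + P[CP_GS_LEAK] * P[CP_ES_LEAK]
               + kl_scale * P[CP_GS_KL] * P[CP_EK])

        g_na_d = P[CP_GD_NA] * S[C_MD, i] ** 3 * S[C_HD, i]
        g_nap_d = P[CP_GD_NAP] * S[C_MNAPD, i]
        g_km = P[CP_GD_KM] * S[C_MKM, i]
        g_kca = P[CP_GD_KCA] * S[C_MKCA, i]
        g_kl_d = kl_scale * P[CP_GD_KL]
        g_syn = gbuf_d[i] * 1e-3 / a_d
        ge_syn = gebuf_d[i] * 1e-3 / a_d
        g_d = (g_na_d + g_nap_d + g_km + g_kca + g_hva + P[CP_GD_LEAK]
               + g_kl_d + g_syn)
        b_d = ((g_na_d + g_nap_d) * P[CP_ENA]
               + (g_km + g_kca + g_kl_d) * P[CP_EK]
               + g_hva * e_ca + P[CP_GD_LEAK] * P[CP_ED_LEAK] + ge_syn)

        # -- semi-implicit 2×2 voltage solve
        a11 = cm_dt + g_d + gcd
        a12 = -gcd
        a21 = -gcs
        a22 = cm_dt + g_s + gcs
        r1 = cm_dt * vd + b_d
        r2 = cm_dt * vs + b_s
        det = a11 * a22 - a12 * a21
        vd_new = (r1 * a22 - a12 * r2) / det
        vs_new = (a11 * r2 - a21 * r1) / det
        S[C_VD, i] = vd_new
        S[C_VS, i] = vs_new

        if vs < P[CP_THRESH] <= vs_new and t_new - S[C_LAST, i] > P[CP_REFRACT]:
            S[C_LAST, i] = t_new
            spike_idx[n_spikes] = i
            n_spikes += 1
    return n_spikes


@njit(cache=True)
def thalamic_step(S, P, gbuf, gebuf, kl_scale, t_new, dt, spike_idx):
    """One step of a thalamic (single-compartment) population (TC or RE)."""
    n = S.shape[1]
    cm_dt = P[TP_CM] / dt
    area = P[TP_AREA]
    is_tc = P[TP_IS_TC] != 0.0
    n_spikes = 0
    for i in range(n):
        v = S[T_V, i]
        am, bm, ah, bh = traub_na_rates(v, P[TP_VTRAUB])
        an, bn = traub_k_rates(v, P[TP_VTRAUB])
        S[T_M, i] = exp_gate_update(S[T_M, i], am / (am + bm), 1.0 / (am + bm), dt)
        S[T_H, i] = exp_gate_update(S[T_H, i], ah / (ah + bh), 1.0 / (ah + bh), dt)
        S[T_N, i] = exp_gate_update(S[T_N, i], an / (an + bn), 1.0 / (an + bn), dt)
        if is_tc:
            minf, tau_m, hinf, tau_h = _it_tc(v, P[TP_IT_MVH], P[TP_IT_MSL],
                                              P[TP_IT_HVH], P[TP_IT_HSL],
                                              P[TP_IT_PHIM], P[TP_IT_PHIH])
        else:
            minf, tau_m, hinf, tau_h = _it_re(v, P[TP_IT_MVH], P[TP_IT_MSL],
                                              P[TP_IT_HVH], P[TP_IT_HSL],
                                              P[TP_IT_PHIM], P[TP_IT_PHIH])
        S[T_MT, i] = exp_gate_update(S[T_MT, i], minf, tau_m, dt)
        S[T_HT, i] = exp_gate_update(S[T_HT, i], hinf, tau_h, dt)

        e_ca = _nernst_eca(S[T_CA, i], P[TP_CA_OUT], P[TP_CA_TEMP])
        g_t = P[TP_G_T] * S[T_MT, i] * S[T_MT, i] * S[T_HT, i]
        i_t = g_t * (v - e_ca)
        S[T_CA, i] = _ca_step(S[T_CA, i], P[TP_CA_REST], P[TP_CA_TAU],
                              P[TP_CA_INFLUX], i_t, dt)

        g_h_open = 0.0
        if is_tc and P[TP_G_H] > 0.0:
            # regulated I_h: voltage gate C<->O, Ca binding P0<->P1, locking O<->OL
            hinf_ih = sigmoid_inf(v, P[TP_IH_VH], P[TP_IH_SL])
            tau_s = 20.0 + 1000.0 / (math.exp((v + 71.5) / 14.2)
                                     + math.exp(-(v + 89.0) / 11.6))
            alpha = hinf_ih / tau_s
            beta = (1.0 - hinf_ih) / tau_s
            ca4 = S[T_CA, i] ** 4
            o = S[T_O, i]
            ol = S[T_OL, i]
            p1 = S[T_P1, i]
            c = 1.0 - o - ol
            o_new = o + dt * (alpha * c - beta * o
                              - P[TP_IH_K3] * p1 * o + P[TP_IH_K4] * ol)
            ol_new = ol + dt * (P[TP_IH_K3] * p1 * o - P[TP_IH_K4] * ol)
            p1_new = p1 + dt * (P[TP_IH_K1] * ca4 * (1.0 - p1) - P[TP_IH_K2] * p1)
            if o_new < 0.0:
                o_new = 0.0
            if ol_new < 0.0:
                ol_new = 0.0
            if p1_new < 0.0:
                p1_new = 0.0
            elif p1_new > 1.0:
                p1_new = 1.0
            tot = o_new + ol_new
            if tot > 1.0:
                o_new /= tot
                ol_new /= tot
            S[T_O, i] = o_new
            S[T_OL, i] = ol_new
            S[T_P1, i] = p1_new
            g_h_open = o_new + P[TP_IH_GINC] * ol_new

        g_na = P[TP_G_NA] * S[T_M, i] ** 3 * S[T_H, i]
        g_k = P[TP_G_K] * S[T_N, i] ** 4
        g_kl = kl_scale * P[TP_G_KL]
        g_h = P[TP_G_H] * g_h_open
        g_syn = gbuf[i] * 1e-3 / area
        ge_syn = gebuf[i] * 1e-3 / area
        g_tot = g_na + g_k + g_t + g_kl + g_h + P[TP_G_LEAK] + g_syn
        b = (g_na * P[TP_ENA] + (g_k + g_kl) * P[TP_EK] + g_t * e_ca
             + g_h * P[TP_IH_EREV] + P[TP_G_LEAK] * P[TP_E_LEAK] + ge_syn)
        v_new = (cm_dt * v + b) / (cm_dt + g_tot)
        S[T_V, i] = v_new

        if v < P[TP_THRESH] <= v_new and t_new - S[T_LAST, i] > P[TP_REFRACT]:
            S[T_LAST, i] = t_new
            spike_idx[n_spikes] = i
            n_spikes += 1
    return n_spikes
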