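"""Per-cell compartmental models.

Cortical PY/INH cells are two-compartment (dendrite + axosomatic) with the
spike-generating Na/K machinery concentrated in the axosomatic compartment
and the slow currents (I_Km, I_KCa, I_HVA, I_Nap, leak, K-leak) in the
dendrite; the compartments are coupled by an axial conductance g_c.  In the
``capacitive`` soma variant the axosomatic compartment carries membrane
capacitance and every axosomatic maximal conductance is rescaled by 3/4
relative to its legacy (capacitance-free algebraic solver) value, which
preserves the qualitative firing behaviour of the original parameter set.
Thalamic TC and RE cells are single-compartment; TC cells carry the
low-threshold calcium current I_T plus the calcium-regulated I_h that
together produce post-hyperpolarisation rebound bursts — the cellular
engine of spindle oscillations.

This module assembles single-cell states (gates initialised at steady state
for the initial voltage) and provides a direct, readable evaluation of the
membrane equations used by tests as an independent reference for the fast
integration kernels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from . import channels
from .channels import (CalciumPool, IhState, channel_constants, nernst_eca,
                       sigmoid_inf, traub_k_rates, traub_na_rates)
from .config import CorticalCellParams, ThalamicCellParams

SOMA_RESCALE = 0.75  # capacitive-variant axosomatic conductance factor


def axosomatic_rescale(soma_variant: str) -> float:
    """Factor applied to legacy axosomatic densities for the given variant."""
    if soma_variant == "capacitive":
        return SOMA_RESCALE
    if soma_variant == "legacy_algebraic":
        return 1.0
    raise ValueError(f"unknown soma variant {soma_variant!r}")


# --------------------------------------------------------------------------
# cell states
# --------------------------------------------------------------------------

@dataclass
class CorticalCellState:
    v_soma: float
    v_dend: float
    # axosomatic gates
    m_na_s: float
    h_na_s: float
    n_k_s: float
    m_nap_s: float
    # dendritic gates
    m_na_d: float
    h_na_d: float
    m_nap_d: float
    m_km: float
    m_kca: float
    m_hva: float
    h_hva: float
    ca: CalciumPool
    last_spike_ms: float = -1e9


@dataclass
class ThalamicCellState:
    v: float
    m_na: float
    h_na: float
    n_k: float
    m_t: float
    h_t: float
    ca: CalciumPool
    ih: IhState = field(default_factory=IhState)
    last_spike_ms: float = -1e9


def _traub_steady(v: float, vtraub: float) -> tuple[float, float, float]:
    am, bm, ah, bh = traub_na_rates(v, vtraub)
    an, bn = traub_k_rates(v, vtraub)
    return am / (am + bm), ah / (ah + bh), an / (an + bn)


def build_cell(cell_type: str, params, soma_variant: str = "capacitive",
               consts: dict[str, float] | None = None):
    """Initialise a cell near rest with every gate at its steady state.

    For cortical types the returned state pairs with *effective* axosomatic
    densities ``axosomatic_rescale(soma_variant) × legacy`` — use
    :func:`effective_soma_densities` when evaluating currents.
    """
    c = consts or channel_constants()
    if cell_type in ("PY", "INH"):
        if not isinstance(params, CorticalCellParams):
            raise ValueError(f"{cell_type} requires CorticalCellParams (with area ratio rho)")
        v0 = params.v_init
        m, h, n = _traub_steady(v0, params.vtraub)
        kin = channels.km_kca_nap_hva_kinetics(v0, c["ca_cortex.rest_mM"], c)
        return CorticalCellState(
            v_soma=v0, v_dend=v0,
            m_na_s=m, h_na_s=h, n_k_s=n,
            m_nap_s=kin["nap"]["m_inf"],
            m_na_d=m, h_na_d=h, m_nap_d=kin["nap"]["m_inf"],
            m_km=kin["km"]["m_inf"], m_kca=kin["kca"]["m_inf"],
            m_hva=kin["hva"]["m_inf"], h_hva=kin["hva"]["h_inf"],
            ca=CalciumPool(ca_mM=c["ca_cortex.rest_mM"], rest_mM=c["ca_cortex.rest_mM"],
                           tau_ms=c["ca_cortex.tau_ms"], influx=c["ca_cortex.influx"]),
        )
    if cell_type in ("TC", "RE"):
        if not isinstance(params, ThalamicCellParams):
            raise ValueError(f"{cell_type} requires ThalamicCellParams")
        v0 = params.v_init
        m, h, n = _traub_steady(v0, params.vtraub)
        if cell_type == "TC":
            minf, _, hinf, _ = channels.it_tc_kinetics(v0, c)
        else:
            minf, _, hinf, _ = channels.it_re_kinetics(v0, c)
        state = ThalamicCellState(
            v=v0, m_na=m, h_na=h, n_k=n, m_t=minf, h_t=hinf,
            ca=CalciumPool(ca_mM=c["ca.rest_mM"], rest_mM=c["ca.rest_mM"],
                           tau_ms=c["ca.tau_ms"], influx=c["ca.influx"]),
        )
        if cell_type == "TC":
            hinf_ih = sigmoid_inf(v0, c["ih.h_vhalf"], c["ih.h_slope"])
            k1 = c["ih.k2"] / c["ih.cac"] ** 4
            ca4 = c["ca.rest_mM"] ** 4
            p1 = k1 * ca4 / (k1 * ca4 + c["ih.k2"])
            state.ih = IhState(O=hinf_ih, OL=0.0, P1=p1)
        return state
    raise ValueError(f"unknown cell type {cell_type!r}")


def effective_soma_densities(params: CorticalCellParams, soma_variant: str):
    """Axosomatic densities after the variant rescale (mS/cm²)."""
    f = axosomatic_rescale(soma_variant)
    s = params.soma
    return {"g_na": f * s.g_na, "g_k": f * s.g_k, "g_nap": f * s.g_nap,
            "g_km": f * s.g_km, "g_kca": f * s.g_kca, "g_hva": f * s.g_hva,
            "g_leak": f * s.g_leak, "g_kl": f * s.g_kl, "e_leak": s.e_leak}


# --------------------------------------------------------------------------
# reference membrane equations (readable, per-cell; tests and diagnostics)
# --------------------------------------------------------------------------

def cortical_membrane_currents(state: CorticalCellState, params: CorticalCellParams,
                               soma_variant: str = "capacitive",
                               consts: dict[str, float] | None = None,
                               kl_factor: float = 1.0):
    """Area-specific ionic membrane currents (µA/cm²) per compartment."""
    c = consts or channel_constants()
    soma = effective_soma_densities(params, soma_variant)
    d = params.dend
    vs, vd = state.v_soma, state.v_dend
    e_ca = nernst_eca(state.ca.ca_mM, c["ca.out_mM"], c["ca.temp_K"])
    i_soma = (
        soma["g_na"] * state.m_na_s ** 3 * state.h_na_s * (vs - params.e_na)
        + soma["g_k"] * state.n_k_s ** 4 * (vs - params.e_k)
        + soma["g_nap"] * state.m_nap_s * (vs - params.e_na)
    )
    i_dend = (
        d.g_na * state.m_na_d ** 3 * state.h_na_d * (vd - params.e_na)
        + d.g_nap * state.m_nap_d * (vd - params.e_na)
        + d.g_km * state.m_km * (vd - params.e_k)
        + d.g_kca * state.m_kca * (vd - params.e_k)
        + d.g_hva * state.m_hva ** 2 * state.h_hva * (vd - e_ca)
        + d.g_leak * (vd - d.e_leak)
        + kl_factor * d.g_kl * (vd - params.e_k)
    )
    return i_soma, i_dend


def cortical_membrane_derivatives(state: CorticalCellState, params: CorticalCellParams,
                                  i_syn_dend: float = 0.0,
                                  soma_variant: str = "capacitive",
                                  consts: dict[str, float] | None = None,
                                  kl_factor: float = 1.0) -> tuple[float, float]:
    """(dV_soma/dt, dV_dend/dt) in mV/ms; ``i_syn_dend`` in µA/cm² (dendrite).

    The axial current g_c·(V_d − V_s) enters the two compartments with equal
    magnitude and opposite sign before area scaling, so total charge is
    conserved (area-weighted capacitive currents balance the area-weighted
    membrane currents exactly).
    """
    i_soma, i_dend = cortical_membrane_currents(state, params, soma_variant,
                                                consts, kl_factor)
    a_s = params.soma_area_cm2
    a_d = params.dend_area_cm2
    # g_c in µS → mS = 1e-3; axial current density in µA/cm²
    i_ax = params.g_c_uS * 1e-3 * (state.v_dend - state.v_soma)  # µA, + into soma
    dvs = (-i_soma + i_ax / a_s) / params.cm
    dvd = (-i_dend - i_syn_dend - i_ax / a_d) / params.cm
    return dvs, dvd


def thalamic_membrane_derivative(state: ThalamicCellState, params: ThalamicCellParams,
                                 cell_type: str, i_syn: float = 0.0,
                                 consts: dict[str, float] | None = None,
                                 kl_factor: float = 1.0) -> float:
    """dV/dt (mV/ms) of a single-compartment thalamic cell."""
    c = consts or channel_constants()
    v = state.v
    e_ca = nernst_eca(state.ca.ca_mM, c["ca.out_mM"], c["ca.temp_K"])
    i = (params.g_na * state.m_na ** 3 * state.h_na * (v - params.e_na)
         + params.g_k * state.n_k ** 4 * (v - params.e_k)
         + params.g_t * state.m_t ** 2 * state.h_t * (v - e_ca)
         + params.g_leak * (v - params.e_leak)
         + kl_factor * params.g_kl * (v - params.e_k))
    if cell_type == "TC" and params.g_h > 0:
        gf = state.ih.O + c["ih.ginc"] * state.ih.OL
        i += params.g_h * gf * (v - c["ih.e_rev"])
    return (-i - i_syn) / params.cm


def detect_spike(v_prev: float, v_now: float, t: float, refractory: float,
                 last_spike: float, threshold: float = 0.0) -> tuple[bool, float]:
    """Somatic threshold-crossing event: V crosses ``threshold`` from below
    and the previous spike is more than ``refractory`` ms in the past."""
    if v_prev < threshold <= v_now and t - last_spike > refractory:
        return True, t
    return False, last_spike


def rate_to_inf_tau(alpha: float, beta: float) -> tuple[float, float]:
    """Convert α/β rates to (x∞, τ)."""
    s = alpha + beta
    if s <= 0:
        return 0.0, math.inf
    return alpha / s, 1.0 / s
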