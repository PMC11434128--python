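"""Intrinsic membrane current kinetics and intracellular calcium dynamics.

All voltage-gated currents are written as g·x^p·(V − E) with gating variables
obeying dx/dt = (x∞(V) − x)/τ(V) or the equivalent α/β form.  Three kinetic
families are used:

* ``sigmoid_inf_tau`` — Boltzmann steady state with an explicit τ(V)
  (T-type calcium currents, I_h voltage gate, persistent sodium);
* ``alpha_beta`` — classical rate-function form (fast spiking Na/K in the
  Traub m³h/n⁴ convention shared by all cell types, dendritic I_Km and
  I_HVA); removable singularities are evaluated by series limit;
* ``calcium_dependent`` — rates proportional to [Ca]ᵢ (I_KCa, and the
  binding step of the regulated I_h).

The hyperpolarisation-activated current I_h of TC cells carries a
calcium-dependent upregulation: a voltage-gated transition C ↔ O, a calcium
binding step P0 ↔ P1 (forward rate k1·[Ca]⁴), and a locking step
O + P1 ↔ OL in which the locked-open state conducts ``ginc`` times more.
This is what makes spindle sequences wax and wane.

Kinetic constants are not hard-wired: they ship in one machine-readable
table (``data/channels.tsv``, columns key/value/units/description) and can be
overridden per key from the ``channels:`` section of the simulation config.
"""

from __future__ import annotations

import csv
import importlib.resources
import math
from dataclasses import dataclass, replace

import numpy as np
from numba import njit

FARADAY = 96485.332  # C/mol
GAS_R = 8.31446  # J/(mol K)


# --------------------------------------------------------------------------
# constant table
# --------------------------------------------------------------------------

def load_channel_table() -> dict[str, float]:
    """Read the shipped channel-constant table into a flat {key: value} dict."""
    path = importlib.resources.files("somnotc.data") / "channels.tsv"
    out: dict[str, float] = {}
    with path.open() as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out[row["key"]] = float(row["value"])
    return out


def channel_constants(overrides: dict[str, float] | None = None) -> dict[str, float]:
    """Shipped channel constants merged with config overrides (unknown keys rejected)."""
    table = load_channel_table()
    if overrides:
        unknown = set(overrides) - set(table)
        if unknown:
            raise KeyError(f"unknown channel constant keys: {sorted(unknown)}")
        table.update({k: float(v) for k, v in overrides.items()})
    return table


# --------------------------------------------------------------------------
# elementary forms
# --------------------------------------------------------------------------

@njit(cache=True)
def sigmoid_inf(v: float, vhalf: float, slope: float) -> float:
    """Boltzmann steady state 1/(1 + exp(−(V − V_half)/slope)).

    Monotone increasing in V for slope > 0, decreasing for slope < 0.
    """
    return 1.0 / (1.0 + math.exp(-(v - vhalf) / slope))


@njit(cache=True)
def vtrap(x: float, y: float) -> float:
    """x / (exp(x/y) − 1) with the removable singularity at x = 0 filled by limit."""
    if abs(x / y) < 1e-6:
        return y - x / 2.0
    return x / (math.exp(x / y) - 1.0)


@njit(cache=True)
def exp_gate_update(x: float, xinf: float, tau: float, dt: float) -> float:
    """Exponential (exact for frozen V) gating update x ← x∞ + (x − x∞)·e^(−dt/τ)."""
    return xinf + (x - xinf) * math.exp(-dt / tau)


# --------------------------------------------------------------------------
# fast spiking currents: Traub m³h / n⁴ rate functions, shared by all types
# --------------------------------------------------------------------------

@njit(cache=True)
def traub_na_rates(v: float, vtraub: float) -> tuple[float, float, float, float]:
    """(α_m, β_m, α_h, β_h) of the transient sodium current, V shifted by vtraub."""
    v2 = v - vtraub
    am = 0.32 * vtrap(13.0 - v2, 4.0)
    bm = 0.28 * vtrap(v2 - 40.0, 5.0)
    ah = 0.128 * math.exp((17.0 - v2) / 18.0)
    bh = 4.0 / (1.0 + math.exp((40.0 - v2) / 5.0))
    return am, bm, ah, bh


@njit(cache=True)
def traub_k_rates(v: float, vtraub: float) -> tuple[float, float]:
    """(α_n, β_n) of the delayed-rectifier potassium current."""
    v2 = v - vtraub
    an = 0.032 * vtrap(15.0 - v2, 5.0)
    bn = 0.5 * math.exp((10.0 - v2) / 40.0)
    return an, bn


# --------------------------------------------------------------------------
# low-threshold (T-type) calcium currents
# --------------------------------------------------------------------------

@njit(cache=True)
def _it_tc(v, m_vhalf, m_slope, h_vhalf, h_slope, phi_m, phi_h):
    minf = sigmoid_inf(v, m_vhalf, m_slope)
    hinf = sigmoid_inf(v, h_vhalf, h_slope)
    tau_m = (0.612 + 1.0 / (math.exp(-(v + 132.0) / 16.7)
                            + math.exp((v + 16.8) / 18.2))) / phi_m
    if v < -80.0:
        tau_h = math.exp((v + 467.0) / 66.6) / phi_h
    else:
        tau_h = (28.0 + math.exp(-(v + 22.0) / 10.5)) / phi_h
    return minf, tau_m, hinf, tau_h


@njit(cache=True)
def _it_re(v, m_vhalf, m_slope, h_vhalf, h_slope, phi_m, phi_h):
    minf = sigmoid_inf(v, m_vhalf, m_slope)
    hinf = sigmoid_inf(v, h_vhalf, h_slope)
    tau_m = (3.0 + 1.0 / (math.exp((v + 27.0) / 10.0)
                          + math.exp(-(v + 102.0) / 15.0))) / phi_m
    tau_h = (85.0 + 1.0 / (math.exp((v + 48.0) / 4.0)
                           + math.exp(-(v + 407.0) / 50.0))) / phi_h
    return minf, tau_m, hinf, tau_h


def it_tc_kinetics(v: float, consts: dict[str, float] | None = None):
    """TC-variant T current: (m∞, τ_m, h∞, τ_h); I_T = g_T·m²·h·(V − E_Ca)."""
    c = consts or channel_constants()
    return _it_tc(v, c["it_tc.m_vhalf"], c["it_tc.m_slope"], c["it_tc.h_vhalf"],
                  c["it_tc.h_slope"], c["it_tc.phi_m"], c["it_tc.phi_h"])


def it_re_kinetics(v: float, consts: dict[str, float] | None = None):
    """RE-variant T current: (m∞, τ_m, h∞, τ_h); I_T = g_T·m²·h·(V − E_Ca)."""
    c = consts or channel_constants()
    return _it_re(v, c["it_re.m_vhalf"], c["it_re.m_slope"], c["it_re.h_vhalf"],
                  c["it_re.h_slope"], c["it_re.phi_m"], c["it_re.phi_h"])


# --------------------------------------------------------------------------
# calcium-regulated I_h
# --------------------------------------------------------------------------

@dataclass
class IhState:
    """Open fractions of the regulated I_h scheme; C = 1 − O − OL, P0 = 1 − P1."""

    O: float = 0.0
    OL: float = 0.0
    P1: float = 0.0


@njit(cache=True)
def _ih_step(o, ol, p1, v, ca, dt, h_vhalf, h_slope, k1, k2, k3, k4):
    hinf = sigmoid_inf(v, h_vhalf, h_slope)
    tau_s = 20.0 + 1000.0 / (math.exp((v + 71.5) / 14.2)
                             + math.exp(-(v + 89.0) / 11.6))
    alpha = hinf / tau_s
    beta = (1.0 - hinf) / tau_s
    ca4 = ca * ca * ca * ca
    c = 1.0 - o - ol
    do = alpha * c - beta * o - k3 * p1 * o + k4 * ol
    dol = k3 * p1 * o - k4 * ol
    dp1 = k1 * ca4 * (1.0 - p1) - k2 * p1
    o_new = o + dt * do
    ol_new = ol + dt * dol
    p1_new = p1 + dt * dp1
    if o_new < 0.0:
        o_new = 0.0
    if ol_new < 0.0:
        ol_new = 0.0
    if p1_new < 0.0:
        p1_new = 0.0
    elif p1_new > 1.0:
        p1_new = 1.0
    if o_new + ol_new > 1.0:
        s = 1.0 / (o_new + ol_new)
        o_new *= s
        ol_new *= s
    return o_new, ol_new, p1_new


def ih_regulated_step(state: IhState, v: float, ca: float, dt: float,
                      consts: dict[str, float] | None = None) -> IhState:
    """Advance the four-process regulated I_h scheme one step.

    Conductance factor is O + ginc·OL; I_h = g_h·(O + ginc·OL)·(V − E_h).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    c = consts or channel_constants()
    k1 = c["ih.k2"] / c["ih.cac"] ** 4
    o, ol, p1 = _ih_step(state.O, state.OL, state.P1, v, ca, dt,
                         c["ih.h_vhalf"], c["ih.h_slope"],
                         k1, c["ih.k2"], c["ih.k4"] / c["ih.pc"], c["ih.k4"])
    return IhState(O=o, OL=ol, P1=p1)


# --------------------------------------------------------------------------
# dendritic current set of the cortical cells
# --------------------------------------------------------------------------

@njit(cache=True)
def km_rates(v: float, q: float, rate: float, vhalf: float, vslope: float):
    """Slow non-inactivating K current (muscarinic-type): (α, β).

    α = q·rate·(V−V½)/(1−exp(−(V−V½)/k)), β the mirror image; both expressed
    through ``vtrap`` so the removable singularity at V = V½ takes its limit
    value q·rate·k.
    """
    a = q * rate * vtrap(-(v - vhalf), vslope)
    b = q * rate * vtrap(v - vhalf, vslope)
    return a, b


@njit(cache=True)
def kca_rates(ca: float, q: float, alpha_per_mm: float, beta: float):
    """Calcium-activated K current: α = k_f·[Ca], β constant."""
    return q * alpha_per_mm * ca, q * beta


@njit(cache=True)
def hva_rates(v: float, q: float):
    """High-voltage-activated Ca current (m²h): (α_m, β_m, α_h, β_h)."""
    am = q * 0.055 * vtrap(-27.0 - v, 3.8)
    bm = q * 0.94 * math.exp((-75.0 - v) / 17.0)
    ah = q * 0.000457 * math.exp((-13.0 - v) / 50.0)
    bh = q * 0.0065 / (math.exp((-15.0 - v) / 28.0) + 1.0)
    return am, bm, ah, bh


def km_kca_nap_hva_kinetics(v: float, ca: float,
                            consts: dict[str, float] | None = None) -> dict:
    """Activation terms of the dendritic current set at (V, [Ca]ᵢ).

    Returns a dict of per-current steady states and time constants:
    I_Km (single α/β gate), I_KCa (calcium-dependent α), I_Nap (fast sigmoid
    activation, I = g·m·(V − E_Na)), I_HVA (m²h α/β kinetics).
    """
    c = consts or channel_constants()
    a_km, b_km = km_rates(v, c["km.q"], c["km.rate"], c["km.vhalf"], c["km.vslope"])
    a_kca, b_kca = kca_rates(ca, c["kca.q"], c["kca.alpha_per_mM"], c["kca.beta"])
    am, bm, ah, bh = hva_rates(v, c["hva.q"])
    nap_inf = sigmoid_inf(v, c["nap.vhalf"], c["nap.slope"])
    return {
        "km": {"alpha": a_km, "beta": b_km,
               "m_inf": a_km / (a_km + b_km), "tau": 1.0 / (a_km + b_km)},
        "kca": {"alpha": a_kca, "beta": b_kca,
                "m_inf": a_kca / (a_kca + b_kca) if a_kca + b_kca > 0 else 0.0,
                "tau": 1.0 / (a_kca + b_kca) if a_kca + b_kca > 0 else math.inf},
        "nap": {"m_inf": nap_inf, "tau": c["nap.tau_ms"]},
        "hva": {"m_inf": am / (am + bm), "tau_m": 1.0 / (am + bm),
                "h_inf": ah / (ah + bh), "tau_h": 1.0 / (ah + bh)},
    }


# --------------------------------------------------------------------------
# calcium pool and Nernst reversal
# --------------------------------------------------------------------------

@dataclass
class CalciumPool:
    """Intracellular calcium in a thin submembrane shell.

    d[Ca]/dt = −k·I_Ca + ([Ca]_rest − [Ca])/τ_Ca with inward calcium current
    I_Ca < 0 raising the concentration (k > 0 in mM·cm²/(ms·µA)).
    """

    ca_mM: float = 2.4e-4
    rest_mM: float = 2.4e-4
    tau_ms: float = 5.0
    influx: float = 5.18e-5

    def __post_init__(self) -> None:
        if self.ca_mM <= 0 or self.rest_mM <= 0:
            raise ValueError("calcium concentrations must be > 0")
        if self.tau_ms <= 0:
            raise ValueError("tau_ms must be > 0")


@njit(cache=True)
def _ca_step(ca, rest, tau, influx, i_ca, dt):
    drive = -influx * i_ca  # inward (negative) current raises [Ca]
    if drive < 0.0:
        drive = 0.0
    ca_new = ca + dt * (drive + (rest - ca) / tau)
    if ca_new < 1e-8:
        ca_new = 1e-8
    return ca_new


def update_calcium(pool: CalciumPool, i_ca: float, dt: float) -> CalciumPool:
    """Advance the calcium pool one step (I_Ca in µA/cm²; efflux is ignored)."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    return replace(pool, ca_mM=float(_ca_step(pool.ca_mM, pool.rest_mM,
                                              pool.tau_ms, pool.influx, i_ca, dt)))


@njit(cache=True)
def _nernst_eca(ca_in, ca_out, temp_k):
    return 1000.0 * GAS_R * temp_k / (2.0 * FARADAY) * math.log(ca_out / ca_in)


def nernst_eca(ca_in: float, ca_out: float, temp_k: float = 309.15) -> float:
    """Calcium reversal potential (mV) from the Nernst equation (valence 2)."""
    if ca_in <= 0 or ca_out <= 0:
        raise ValueError("calcium concentrations must be > 0")
    return float(_nernst_eca(ca_in, ca_out, temp_k))
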