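"""Kinetic synapse models and miniature-EPSP scheduling.

Receptors follow the first-order transmitter-gated scheme
dO/dt = α·T·(1 − O) − β·O driven by rectangular transmitter pulses released
at presynaptic spikes (pulses saturate — T is a concentration, not a count).
The synaptic current is I = g·E·O·(V − E_rev), where E is the short-term
depression resource of the depressing cortical AMPA synapse (E ≡ 1
elsewhere).  Depression is applied at each presynaptic spike:

    E ← 1 − (1 − E·(1 − U))·exp(−Δt/τ_D)

with use fraction U and recovery constant τ_D — this use-dependent rundown
of recurrent cortical excitation is what terminates Up states and hence
paces the slow oscillation.

GABA-B uses the second-messenger cascade (receptor R, G-protein G) with a
quartic activation G⁴/(G⁴ + K_d) gating a potassium conductance.

Miniature EPSPs are spontaneous releases drawn from a renewal process whose
hazard rises with time since the last presynaptic spike and saturates at a
configured maximum rate; sampling is counter-based per connection so runs
are reproducible and insensitive to unrelated network edits.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


# --------------------------------------------------------------------------
# short-term depression
# --------------------------------------------------------------------------

@njit(cache=True)
def depression_update(e_prev: float, delta_t: float, u: float, tau_d: float) -> float:
    """Resource at a presynaptic spike, Δt after the previous spike."""
    return 1.0 - (1.0 - e_prev * (1.0 - u)) * math.exp(-delta_t / tau_d)


def depression_fixed_point(delta_t: float, u: float, tau_d: float) -> float:
    """Fixed point E* of the periodic-train depression map (closed form)."""
    q = math.exp(-delta_t / tau_d)
    return (1.0 - q) / (1.0 - (1.0 - u) * q)


# --------------------------------------------------------------------------
# first-order receptor kinetics
# --------------------------------------------------------------------------

@njit(cache=True)
def kinetic_open_step(o: float, t_conc: float, alpha: float, beta: float,
                      dt: float) -> float:
    """Advance dO/dt = α·T·(1−O) − β·O one step, exactly for constant T."""
    rate = alpha * t_conc + beta
    if rate <= 0.0:
        return o
    o_inf = alpha * t_conc / rate
    return o_inf + (o - o_inf) * math.exp(-rate * dt)


@njit(cache=True)
def nmda_mg_block(v: float, mg_mM: float = 1.0) -> float:
    """Voltage-dependent magnesium block B(V) = 1/(1 + exp(−0.062·V)·[Mg]/3.57)."""
    return 1.0 / (1.0 + math.exp(-0.062 * v) * mg_mM / 3.57)


@njit(cache=True)
def gabab_step(r: float, g: float, t_conc: float, dt: float,
               k1: float, k2: float, k3: float, k4: float) -> tuple[float, float]:
    """Second-messenger update: receptor R then G-protein G (exponential steps)."""
    rate_r = k1 * t_conc + k2
    r_inf = k1 * t_conc / rate_r if rate_r > 0 else 0.0
    r_new = r_inf + (r - r_inf) * math.exp(-rate_r * dt)
    g_inf = k3 * r_new / k4
    g_new = g_inf + (g - g_inf) * math.exp(-k4 * dt)
    return r_new, g_new


@njit(cache=True)
def gabab_activation(g: float, kd: float) -> float:
    """Conductance fraction G⁴/(G⁴ + K_d) of the GABA-B potassium channel."""
    g4 = g * g * g * g
    return g4 / (g4 + kd)


def transmitter_pulse(spike_times, t: float, amplitude: float, duration: float) -> float:
    """Transmitter concentration at time t: ``amplitude`` while any pulse is
    active (0 ≤ t − t_spike < duration), else 0.  Overlapping pulses saturate."""
    for ts in spike_times:
        if 0.0 <= t - ts < duration:
            return amplitude
    return 0.0


# --------------------------------------------------------------------------
# miniature-EPSP renewal process (counter-based per-connection streams)
# --------------------------------------------------------------------------

@njit(cache=True)
def splitmix64(x: np.uint64) -> np.uint64:
    x = np.uint64(x) + np.uint64(0x9E3779B97F4A7C15)
    z = x
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


@njit(cache=True)
def _uniform(stream: np.uint64, counter: np.uint64) -> float:
    """Deterministic uniform in (0, 1) from a (stream, counter) pair."""
    z = splitmix64(splitmix64(stream) ^ np.uint64(counter))
    return (float(z >> np.uint64(11)) + 0.5) / 9007199254740992.0


@njit(cache=True)
def mini_hazard(s: float, rate_max: float, tau_recover: float) -> float:
    """Mini release hazard (ms⁻¹) at time s since the last presynaptic spike:
    suppressed right after a spike, saturating at rate_max as s grows."""
    return rate_max * (1.0 - math.exp(-s / tau_recover))


@njit(cache=True)
def mini_next_time(stream: np.uint64, counter: np.uint64, t_last_spike: float,
                   t_from: float, rate_max_per_ms: float,
                   tau_recover: float) -> tuple[float, np.uint64]:
    """Draw the next mini time after ``t_from`` by thinning against rate_max.

    Returns (event time, advanced counter).  rate 0 → never (inf).
    """
    if rate_max_per_ms <= 0.0:
        return math.inf, counter
    t = t_from
    c = counter
    for _ in range(10000):
        u1 = _uniform(stream, c)
        c += np.uint64(1)
        t += -math.log(u1) / rate_max_per_ms
        u2 = _uniform(stream, c)
        c += np.uint64(1)
        s = t - t_last_spike
        if s > 0.0 and u2 * rate_max_per_ms < mini_hazard(s, rate_max_per_ms, tau_recover):
            return t, c
    return math.inf, c


def mini_scheduler_next(stream: int, counter: int, t_last_presyn_spike: float,
                        t_now: float, rate_max_hz: float,
                        tau_recover_ms: float) -> tuple[float, int]:
    """Next spontaneous-release time for one connection (ms), deterministic in
    (stream, counter).  ``rate_max_hz`` is the saturated per-connection rate."""
    if t_now < t_last_presyn_spike:
        raise ValueError("t_now must be >= t_last_presyn_spike")
    t, c = mini_next_time(np.uint64(stream), np.uint64(counter),
                          t_last_presyn_spike, t_now,
                          rate_max_hz / 1000.0, tau_recover_ms)
    return float(t), int(c)
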