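"""Mapping from neuromodulator levels to effective cellular/synaptic parameters.

Acetylcholine and histamine act by closing a potassium leak conductance:
lower levels open more K-leak and hyperpolarise cells, which is the cellular
switch that moves the network from activated (wake/REM) into spindling (N2)
and slow-oscillation (N3) regimes.  Histamine acts on the thalamic K-leak
only.  Acetylcholine additionally scales cortical AMPA weights (lower ach →
stronger recurrent excitation), and the GABA level scales every GABA-A
weight directly.  All mappings are linear in the levels and are exactly the
identity at the wake reference (ach = ha = gaba = 1).
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import ModulationMap, NeuromodulatorLevels

__all__ = ["ModulationMap", "EffectiveScales", "effective_params", "kl_scale"]


@dataclass(frozen=True)
class EffectiveScales:
    """Multiplicative factors applied to base parameters at one instant."""

    g_kl: dict[str, float]  # per population
    ampa_cortical: float
    gaba: float


def kl_scale(levels: NeuromodulatorLevels, kappa_ach: float, kappa_ha: float) -> float:
    """K-leak factor 1 + κ_ach·(1−ach) + κ_ha·(1−ha), floored at 0."""
    return max(0.0, 1.0 + kappa_ach * (1.0 - levels.ach) + kappa_ha * (1.0 - levels.ha))


def effective_params(levels: NeuromodulatorLevels, mod: ModulationMap) -> EffectiveScales:
    """Pure mapping levels → multiplicative scales; wake levels give all 1s."""
    g_kl = {
        pop: kl_scale(levels, mod.kl_ach[pop], mod.kl_ha[pop])
        for pop in mod.kl_ach
    }
    ampa = max(0.0, 1.0 + mod.ampa_ach_gain * (1.0 - levels.ach))
    return EffectiveScales(g_kl=g_kl, ampa_cortical=ampa, gaba=max(0.0, levels.gaba))
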