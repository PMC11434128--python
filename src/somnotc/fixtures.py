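"""Reduced desk-scale configurations for fast, deterministic experiments.

Each scenario is a complete, validated SimulationConfig exercising one
mechanism of the full model:

* ``single_tc_rebound`` — one isolated TC cell taken through a
  hyperpolarise-and-release protocol (neuromodulator levels open the K-leak,
  then return to wake), probing the I_T/I_h rebound burst;
* ``re_tc_spindle_pair`` — a small RE+TC loop at N2 levels, the spindle
  pacemaker circuit;
* ``cortical_slab_n3`` — a PY/INH slab at N3 levels with depressing
  recurrent AMPA and miniature EPSPs, the slow-oscillation circuit
  (thalamic populations are present at minimal size with all
  thalamocortical conductances zeroed);
* ``full_reduced_cycle`` — the whole network at 1/10 scale run through the
  five-stage sequence (wake, N2, N3, REM, N2) at 1/10 duration.

``scale`` multiplies population counts relative to the scenario's full-size
reference; counts never drop below 1.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import (NeuromodulatorLevels, SimulationConfig, Stage,
                     StageSchedule, default_schedule)

SCENARIOS = ("single_tc_rebound", "re_tc_spindle_pair", "cortical_slab_n3",
             "full_reduced_cycle")


@dataclass
class FixtureSpec:
    scenario: str
    scale: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}")
        if not 0.0 < self.scale <= 1.0:
            raise ValueError("scale must be in (0, 1]")


def _scaled(n_full: int, scale: float) -> int:
    return max(1, int(round(n_full * scale)))


def _zero_thalamocortical(cfg: SimulationConfig) -> None:
    for name in ("PY_TC", "PY_RE", "TC_PY", "TC_INH", "TC_RE", "RE_TC", "RE_RE"):
        p = cfg.connectivity.projections[name]
        p.g_ampa = p.g_nmda = p.g_gabaa = p.g_gabab = 0.0


def _zero_cortical(cfg: SimulationConfig) -> None:
    for name in ("PY_PY", "PY_INH", "INH_PY", "PY_TC", "PY_RE", "TC_PY", "TC_INH"):
        p = cfg.connectivity.projections[name]
        p.g_ampa = p.g_nmda = p.g_gabaa = p.g_gabab = 0.0


def make_fixture(spec: FixtureSpec, stage: str | None = None) -> SimulationConfig:
    """Build and validate the configuration of one scenario.

    ``stage`` overrides the scenario's single-stage label (e.g. run the
    spindle pair under ``wake`` levels as a negative control); it is ignored
    by ``full_reduced_cycle``.
    """
    spec.validate()
    builder = {
        "single_tc_rebound": _single_tc_rebound,
        "re_tc_spindle_pair": _re_tc_spindle_pair,
        "cortical_slab_n3": _cortical_slab_n3,
        "full_reduced_cycle": _full_reduced_cycle,
    }[spec.scenario]
    cfg = builder(spec, stage)
    cfg.integration.seed = spec.seed
    cfg.validate()
    return cfg


def _single_stage_schedule(stage: str, duration_ms: float) -> StageSchedule:
    sched = StageSchedule(stages=[Stage(stage, duration_ms)], ramp_ms=0.0)
    sched.levels = default_schedule().levels
    return sched


def _single_tc_rebound(spec: FixtureSpec, stage: str | None) -> SimulationConfig:
    cfg = SimulationConfig(populations={"PY": 1, "INH": 1, "TC": 1, "RE": 1})
    _zero_thalamocortical(cfg)
    _zero_cortical(cfg)
    # hyperpolarising phase: zero ach/ha fully opens the TC K-leak; the wake
    # phase closes it again, releasing the cell into a rebound burst.
    sched = StageSchedule(
        stages=[Stage("N3", 2000.0), Stage("wake", 1000.0)],
        levels={
            "N3": NeuromodulatorLevels(ach=0.0, ha=0.0, gaba=1.0),
            "wake": NeuromodulatorLevels(1.0, 1.0, 1.0),
        },
        ramp_ms=0.0,
    )
    cfg.schedule = sched
    # strong K-leak swing so the hyperpolarising phase parks the cell below
    # the T-current activation range (~-82 mV) instead of delta-oscillating
    cfg.modulation.kl_ach["TC"] = 10.0
    cfg.outputs.voltage_traces = {"TC": [0]}
    return cfg


def _re_tc_spindle_pair(spec: FixtureSpec, stage: str | None) -> SimulationConfig:
    n = max(4, _scaled(40, spec.scale))
    cfg = SimulationConfig(populations={"PY": 1, "INH": 1, "TC": n, "RE": n})
    _zero_cortical(cfg)
    for name in ("PY_TC", "PY_RE", "TC_PY", "TC_INH"):
        p = cfg.connectivity.projections[name]
        p.g_ampa = p.g_nmda = p.g_gabaa = p.g_gabab = 0.0
    # in the full network spindles are re-kindled by cortical input; in the
    # isolated pair, sparse miniature releases on TC->RE play that role
    # (weak enough not to entrain the loop at wake levels)
    cfg.connectivity.projections["TC_RE"].minis = True
    # the isolated 4+4 loop needs a stronger fast IPSP than the embedded
    # full-network loop to sustain rebound cycling
    cfg.connectivity.projections["RE_TC"].g_gabaa = 0.05
    cfg.connectivity.projections["RE_TC"].g_gabab = 0.002
    cfg.synapses.mini_rate_max_hz = 1.5
    cfg.synapses.mini_amp_fraction = 0.2
    cfg.synapses.mini_tau_recover_ms = 300.0
    cfg.schedule = _single_stage_schedule(stage or "N2", 10_000.0)
    cfg.outputs.voltage_traces = {"TC": list(range(n))}
    return cfg


def _cortical_slab_n3(spec: FixtureSpec, stage: str | None) -> SimulationConfig:
    n_py = _scaled(400, spec.scale)
    n_inh = _scaled(100, spec.scale)
    cfg = SimulationConfig(populations={"PY": n_py, "INH": n_inh, "TC": 1, "RE": 1})
    _zero_thalamocortical(cfg)
    cfg.schedule = _single_stage_schedule(stage or "N3", 12_000.0)
    cfg.outputs.record_cortex_voltages = True
    return cfg


def _full_reduced_cycle(spec: FixtureSpec, stage: str | None) -> SimulationConfig:
    cfg = SimulationConfig(populations={
        "PY": _scaled(500, spec.scale), "INH": _scaled(100, spec.scale),
        "TC": _scaled(100, spec.scale), "RE": _scaled(100, spec.scale),
    })
    cfg.schedule = default_schedule(total_ms=36_000.0, ramp_ms=500.0)
    return cfg
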