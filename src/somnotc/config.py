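"""Simulation configuration: parameter tree, validation, and the sleep-stage schedule.

The configuration is a versioned YAML document (``schema: 1``).  Every model
parameter — population sizes, channel densities, synaptic conductances,
connectivity radii, the stage schedule with neuromodulator levels, integration
settings — lives in this tree and nowhere else.  Unknown keys are a hard error
so that typos cannot silently fall back to defaults.

Neuromodulator levels are dimensionless concentrations with the wake state as
the reference (ach = ha = gaba = 1 leaves every cellular and synaptic
parameter at its base value).  The schedule is piecewise-constant per stage
with a linear ramp of configurable width centred on each stage boundary.
"""

from __future__ import annotations

import copy
import dataclasses
import importlib.resources
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import yaml

SCHEMA_VERSION = 1

POPULATIONS = ("PY", "INH", "TC", "RE")
STAGES = ("wake", "N2", "N3", "REM")
SOMA_VARIANTS = ("capacitive", "legacy_algebraic")

# Projections of the thalamocortical loop.  Receptor sets are fixed per
# projection; conductances/radii are configurable.
PROJECTION_NAMES = (
    "PY_PY", "PY_INH", "INH_PY", "PY_TC", "PY_RE",
    "TC_PY", "TC_INH", "TC_RE", "RE_TC", "RE_RE",
)


class ConfigError(ValueError):
    """Raised when a configuration file fails to parse or validate."""


@dataclass
class NeuromodulatorLevels:
    """Dimensionless neuromodulator concentrations (wake reference = 1)."""

    ach: float = 1.0
    ha: float = 1.0
    gaba: float = 1.0

    def as_array(self) -> np.ndarray:
        return np.array([self.ach, self.ha, self.gaba], dtype=float)

    def validate(self, prefix: str, errors: list[str]) -> None:
        if not 0.0 <= self.ach <= 2.0:
            errors.append(f"{prefix}.ach must be in [0, 2], got {self.ach}")
        if not 0.0 <= self.ha <= 2.0:
            errors.append(f"{prefix}.ha must be in [0, 2], got {self.ha}")
        if self.gaba < 0.0:
            errors.append(f"{prefix}.gaba must be >= 0, got {self.gaba}")


@dataclass
class Stage:
    stage: str
    duration_ms: float


@dataclass
class StageSchedule:
    """Ordered sleep-stage sequence with per-stage neuromodulator levels.

    ``ramp_ms`` is the width of the linear interpolation window centred on
    each internal stage boundary; outside ramps the levels are the plateau
    values of the current stage.
    """

    stages: list[Stage] = field(default_factory=list)
    levels: dict[str, NeuromodulatorLevels] = field(default_factory=dict)
    ramp_ms: float = 5000.0

    @property
    def total_duration_ms(self) -> float:
        return float(sum(s.duration_ms for s in self.stages))

    def boundaries(self) -> np.ndarray:
        """Cumulative stage end times (ms), length == number of stages."""
        return np.cumsum([s.duration_ms for s in self.stages])

    def stage_at(self, t: float) -> str:
        """Label of the stage containing time ``t`` (boundaries belong to the later stage)."""
        if not 0.0 <= t <= self.total_duration_ms:
            raise ValueError(f"t={t} outside schedule [0, {self.total_duration_ms}]")
        ends = self.boundaries()
        idx = int(np.searchsorted(ends, t, side="right"))
        return self.stages[min(idx, len(self.stages) - 1)].stage

    def validate(self, errors: list[str]) -> None:
        if not self.stages:
            errors.append("schedule.stages must be non-empty")
            return
        for i, s in enumerate(self.stages):
            if s.stage not in STAGES:
                errors.append(f"schedule.stages[{i}].stage unknown: {s.stage!r}")
            if not s.duration_ms > 0:
                errors.append(f"schedule.stages[{i}].duration_ms must be > 0")
        for name in {s.stage for s in self.stages}:
            if name in STAGES and name not in self.levels:
                errors.append(f"schedule.levels missing entry for stage {name!r}")
        for name, lev in self.levels.items():
            if name not in STAGES:
                errors.append(f"schedule.levels has unknown stage {name!r}")
            else:
                lev.validate(f"schedule.levels.{name}", errors)
        if self.ramp_ms < 0:
            errors.append("schedule.ramp_ms must be >= 0")
        elif self.stages and self.ramp_ms > 0:
            min_dur = min(s.duration_ms for s in self.stages)
            if self.ramp_ms >= min_dur:
                errors.append(
                    f"schedule.ramp_ms ({self.ramp_ms}) must be < shortest stage duration ({min_dur})"
                )


def neuromod_at(schedule: StageSchedule, t: float) -> NeuromodulatorLevels:
    """Neuromodulator levels at time ``t`` (ms): stage plateaus with linear ramps.

    Continuous in ``t``; at a boundary with ramp > 0 the value is the
    arithmetic mean of the two adjacent stages' levels.
    """
    arr = neuromod_track(schedule, np.array([t], dtype=float))
    return NeuromodulatorLevels(ach=float(arr[0, 0]), ha=float(arr[0, 1]), gaba=float(arr[0, 2]))


def neuromod_track(schedule: StageSchedule, times: np.ndarray) -> np.ndarray:
    """Vectorised ``neuromod_at``: (n_times, 3) array of (ach, ha, gaba)."""
    total = schedule.total_duration_ms
    times = np.asarray(times, dtype=float)
    if times.size and (times.min() < 0 or times.max() > total):
        raise ValueError(f"time outside schedule range [0, {total}]")
    plateau = np.array(
        [schedule.levels[s.stage].as_array() for s in schedule.stages]
    )  # (n_stages, 3)
    ends = schedule.boundaries()
    idx = np.minimum(np.searchsorted(ends, times, side="right"), len(schedule.stages) - 1)
    out = plateau[idx].copy()
    half = schedule.ramp_ms / 2.0
    if half > 0:
        # interior boundaries only: ramp from level[i] to level[i+1]
        for i, b in enumerate(ends[:-1]):
            mask = np.abs(times - b) < half
            if np.any(mask):
                frac = (times[mask] - (b - half)) / schedule.ramp_ms
                out[mask] = (1 - frac[:, None]) * plateau[i] + frac[:, None] * plateau[i + 1]
    return out


@dataclass
class CompartmentDensities:
    """Maximal conductances (mS/cm²) for one cortical compartment."""

    g_na: float = 0.0
    g_k: float = 0.0
    g_nap: float = 0.0
    g_km: float = 0.0
    g_kca: float = 0.0
    g_hva: float = 0.0
    g_leak: float = 0.0
    e_leak: float = -70.0
    g_kl: float = 0.0


@dataclass
class CorticalCellParams:
    """Two-compartment (dendrite + axosomatic) cortical cell.

    ``rho`` is the dendrite/soma area ratio; ``g_c_uS`` the axial coupling
    conductance.  Densities are the legacy (capacitance-free solver) values;
    in the capacitive soma variant every axosomatic density is rescaled by
    3/4 at build time.
    """

    cm: float = 0.75
    rho: float = 165.0
    soma_area_cm2: float = 1.0e-6
    g_c_uS: float = 0.1
    vtraub: float = -55.0
    v_init: float = -68.0
    e_na: float = 50.0
    e_k: float = -95.0
    soma: CompartmentDensities = field(default_factory=CompartmentDensities)
    dend: CompartmentDensities = field(default_factory=CompartmentDensities)

    @property
    def dend_area_cm2(self) -> float:
        return self.rho * self.soma_area_cm2

    def validate(self, prefix: str, errors: list[str]) -> None:
        if not self.cm > 0:
            errors.append(f"{prefix}.cm must be > 0")
        if not self.rho > 0:
            errors.append(f"{prefix}.rho must be > 0")
        if not self.soma_area_cm2 > 0:
            errors.append(f"{prefix}.soma_area_cm2 must be > 0")
        if self.g_c_uS < 0:
            errors.append(f"{prefix}.g_c_uS must be >= 0")
        for comp_name in ("soma", "dend"):
            comp = getattr(self, comp_name)
            for f in dataclasses.fields(comp):
                if f.name.startswith("g_") and getattr(comp, f.name) < 0:
                    errors.append(f"{prefix}.{comp_name}.{f.name} must be >= 0")


@dataclass
class ThalamicCellParams:
    """Single-compartment thalamic cell (TC relay or RE reticular)."""

    cm: float = 1.0
    area_cm2: float = 2.9e-4
    vtraub: float = -52.0
    v_init: float = -68.0
    e_na: float = 50.0
    e_k: float = -95.0
    g_na: float = 90.0
    g_k: float = 10.0
    g_t: float = 2.2
    g_h: float = 0.0
    g_leak: float = 0.01
    e_leak: float = -70.0
    g_kl: float = 0.005

    def validate(self, prefix: str, errors: list[str]) -> None:
        if not self.cm > 0:
            errors.append(f"{prefix}.cm must be > 0")
        if not self.area_cm2 > 0:
            errors.append(f"{prefix}.area_cm2 must be > 0")
        for name in ("g_na", "g_k", "g_t", "g_h", "g_leak", "g_kl"):
            if getattr(self, name) < 0:
                errors.append(f"{prefix}.{name} must be >= 0")


@dataclass
class ProjectionConfig:
    """Topographic projection: radius-based fan-out with per-target conductance.

    ``g_*`` are maximal conductances in µS; when
    ``connectivity.normalize_by_indegree`` is on they are the *total* per
    target cell (divided by actual in-degree), so boundary cells receive
    comparable drive.
    """

    radius: int = 5
    g_ampa: float = 0.0
    g_nmda: float = 0.0
    g_gabaa: float = 0.0
    g_gabab: float = 0.0
    e_gabaa: float = -70.0
    depressing: bool = False
    minis: bool = False
    allow_self: bool = False
    delay_ms: float = 0.0

    def validate(self, prefix: str, errors: list[str]) -> None:
        if self.radius < 0:
            errors.append(f"{prefix}.radius must be >= 0")
        for name in ("g_ampa", "g_nmda", "g_gabaa", "g_gabab"):
            if getattr(self, name) < 0:
                errors.append(f"{prefix}.{name} must be >= 0")
        if self.delay_ms < 0:
            errors.append(f"{prefix}.delay_ms must be >= 0")


@dataclass
class SynapseKinetics:
    """Shared receptor kinetics (rate constants in ms⁻¹, mM⁻¹ms⁻¹)."""

    ampa_alpha: float = 1.1
    ampa_beta: float = 0.19
    ampa_e_rev: float = 0.0
    nmda_alpha: float = 0.072
    nmda_beta: float = 0.0066
    nmda_e_rev: float = 0.0
    nmda_mg_mM: float = 1.0
    gabaa_alpha: float = 5.0
    gabaa_beta: float = 0.18
    gabab_k1: float = 0.52
    gabab_k2: float = 0.0013
    gabab_k3: float = 0.098
    gabab_k4: float = 0.033
    gabab_kd: float = 100.0
    gabab_e_rev: float = -95.0
    pulse_amp_mM: float = 0.5
    pulse_dur_ms: float = 0.3
    depression_U: float = 0.07
    depression_tau_ms: float = 700.0
    mini_amp_fraction: float = 0.5
    mini_rate_max_hz: float = 35.0
    mini_tau_recover_ms: float = 1100.0

    def validate(self, errors: list[str]) -> None:
        if not 0.0 <= self.depression_U < 1.0:
            errors.append("synapses.depression_U must be in [0, 1)")
        if not self.depression_tau_ms > 0:
            errors.append("synapses.depression_tau_ms must be > 0")
        if not self.pulse_dur_ms > 0:
            errors.append("synapses.pulse_dur_ms must be > 0")
        if self.pulse_amp_mM < 0:
            errors.append("synapses.pulse_amp_mM must be >= 0")
        if self.mini_rate_max_hz < 0:
            errors.append("synapses.mini_rate_max_hz must be >= 0")
        if not 0.0 <= self.mini_amp_fraction:
            errors.append("synapses.mini_amp_fraction must be >= 0")


@dataclass
class ModulationMap:
    """Gains mapping neuromodulator levels to effective parameters.

    K-leak: g_KL_eff = g_KL · (1 + κ_ach·(1−ach) + κ_ha·(1−ha)); histamine
    acts on thalamic K-leak only (cortical κ_ha = 0 by default).  Cortical
    AMPA: w_eff = w · (1 + λ·(1−ach)).  GABA-A: w_eff = w · gaba.
    """

    kl_ach: dict[str, float] = field(
        default_factory=lambda: {"PY": 2.0, "INH": 2.0, "TC": 5.0, "RE": 0.5}
    )
    kl_ha: dict[str, float] = field(
        default_factory=lambda: {"PY": 0.0, "INH": 0.0, "TC": 2.5, "RE": 0.5}
    )
    ampa_ach_gain: float = 0.6

    def validate(self, errors: list[str]) -> None:
        for name in ("kl_ach", "kl_ha"):
            d = getattr(self, name)
            for pop in POPULATIONS:
                if pop not in d:
                    errors.append(f"modulation.{name} missing population {pop}")
                elif d[pop] < 0:
                    errors.append(f"modulation.{name}.{pop} must be >= 0")
        if self.ampa_ach_gain < 0:
            errors.append("modulation.ampa_ach_gain must be >= 0")


@dataclass
class IntegrationConfig:
    dt_ms: float = 0.025
    seed: int = 0
    record_dt_ms: float = 1.0
    settle_ms: float = 500.0
    refractory_ms: float = 2.0
    spike_threshold_mV: float = 0.0

    def validate(self, errors: list[str]) -> None:
        if not self.dt_ms > 0:
            errors.append("integration.dt_ms must be > 0")
        if not self.record_dt_ms > 0:
            errors.append("integration.record_dt_ms must be > 0")
        if self.settle_ms < 0:
            errors.append("integration.settle_ms must be >= 0")


@dataclass
class LfpConfig:
    """Electrode geometry for the biophysical (transfer-resistance) LFP.

    Cells are laid out in 1-D at ``pitch_um`` spacing; cortical dendrites sit
    ``dend_offset_um`` above the somata.  ``electrode_um`` defaults to the
    mid-point of the PY layer, half-way between the soma and dendrite planes.
    """

    sigma_S_per_m: float = 0.3
    pitch_um: float = 20.0
    dend_offset_um: float = 500.0
    electrode_um: list[float] | None = None
    min_distance_um: float = 10.0

    def validate(self, errors: list[str]) -> None:
        if not self.sigma_S_per_m > 0:
            errors.append("lfp.sigma_S_per_m must be > 0")
        if not self.pitch_um > 0:
            errors.append("lfp.pitch_um must be > 0")
        if self.electrode_um is not None and len(self.electrode_um) != 3:
            errors.append("lfp.electrode_um must be a 3-vector (µm)")


@dataclass
class OutputConfig:
    record_cortex_voltages: bool = False
    voltage_traces: dict[str, list[int]] = field(default_factory=dict)

    def validate(self, errors: list[str]) -> None:
        for pop in self.voltage_traces:
            if pop not in POPULATIONS:
                errors.append(f"outputs.voltage_traces has unknown population {pop!r}")


def _default_projections() -> dict[str, ProjectionConfig]:
    # Thalamic/thalamocortical footprints broader than intracortical ones.
    return {
        "PY_PY": ProjectionConfig(radius=5, g_ampa=0.3, g_nmda=0.02,
                                  depressing=True, minis=True),
        "PY_INH": ProjectionConfig(radius=1, g_ampa=0.05, g_nmda=0.008,
                                   depressing=True, minis=True),
        "INH_PY": ProjectionConfig(radius=5, g_gabaa=0.05, e_gabaa=-70.0),
        "PY_TC": ProjectionConfig(radius=10, g_ampa=0.025),
        "PY_RE": ProjectionConfig(radius=8, g_ampa=0.05),
        "TC_PY": ProjectionConfig(radius=10, g_ampa=0.1),
        "TC_INH": ProjectionConfig(radius=2, g_ampa=0.1),
        "TC_RE": ProjectionConfig(radius=8, g_ampa=0.05),
        "RE_TC": ProjectionConfig(radius=8, g_gabaa=0.03, g_gabab=0.004, e_gabaa=-85.0),
        "RE_RE": ProjectionConfig(radius=5, g_gabaa=0.07, e_gabaa=-70.0),
    }


def _default_levels() -> dict[str, NeuromodulatorLevels]:
    # calibration defaults (wake is the reference): N2 keeps the cortex close
    # to its activated state while the thalamic K-leak gains (see
    # ModulationMap) already put TC cells in the spindle-permissive range;
    # N3 hyperpolarises cortex into the slow-oscillation regime.
    return {
        "wake": NeuromodulatorLevels(1.0, 1.0, 1.0),
        "N2": NeuromodulatorLevels(0.7, 0.7, 1.2),
        "N3": NeuromodulatorLevels(0.3, 0.3, 1.3),
        "REM": NeuromodulatorLevels(1.2, 0.1, 0.9),
    }


def default_schedule(total_ms: float = 360_000.0, ramp_ms: float = 5000.0) -> StageSchedule:
    """The headline protocol: wake, N2, N3, REM, N2 in equal shares of ``total_ms``."""
    seq = ["wake", "N2", "N3", "REM", "N2"]
    dur = total_ms / len(seq)
    return StageSchedule(
        stages=[Stage(s, dur) for s in seq],
        levels=_default_levels(),
        ramp_ms=ramp_ms,
    )


@dataclass
class ConnectivityConfig:
    normalize_by_indegree: bool = True
    projections: dict[str, ProjectionConfig] = field(default_factory=_default_projections)

    def validate(self, errors: list[str]) -> None:
        for name, proj in self.projections.items():
            if name not in PROJECTION_NAMES:
                errors.append(f"connectivity.projections has unknown projection {name!r}")
            proj.validate(f"connectivity.projections.{name}", errors)


@dataclass
class SimulationConfig:
    """Complete parameter tree for one simulation run."""

    populations: dict[str, int] = field(
        default_factory=lambda: {"PY": 500, "INH": 100, "TC": 100, "RE": 100}
    )
    soma_variant: str = "capacitive"
    cells: dict[str, Any] = field(default_factory=dict)
    connectivity: ConnectivityConfig = field(default_factory=ConnectivityConfig)
    synapses: SynapseKinetics = field(default_factory=SynapseKinetics)
    modulation: ModulationMap = field(default_factory=ModulationMap)
    schedule: StageSchedule = field(default_factory=default_schedule)
    integration: IntegrationConfig = field(default_factory=IntegrationConfig)
    lfp: LfpConfig = field(default_factory=LfpConfig)
    outputs: OutputConfig = field(default_factory=OutputConfig)
    channels: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        defaults: dict[str, Any] = {
            "PY": _default_py(),
            "INH": _default_inh(),
            "TC": _default_tc(),
            "RE": _default_re(),
        }
        for pop, d in defaults.items():
            self.cells.setdefault(pop, d)

    @property
    def total_duration_ms(self) -> float:
        return self.schedule.total_duration_ms

    def validate(self) -> None:
        """Raise ConfigError listing *every* violated invariant."""
        errors: list[str] = []
        for pop in POPULATIONS:
            n = self.populations.get(pop)
            if n is None:
                errors.append(f"populations missing count for {pop}")
            elif not (isinstance(n, int) and n >= 1):
                errors.append(f"populations.{pop} must be an integer >= 1, got {n!r}")
        for pop in self.populations:
            if pop not in POPULATIONS:
                errors.append(f"populations has unknown population {pop!r}")
        if self.soma_variant not in SOMA_VARIANTS:
            errors.append(f"soma_variant must be one of {SOMA_VARIANTS}, got {self.soma_variant!r}")
        for pop in ("PY", "INH"):
            if pop in self.cells:
                self.cells[pop].validate(f"cells.{pop}", errors)
        for pop in ("TC", "RE"):
            if pop in self.cells:
                self.cells[pop].validate(f"cells.{pop}", errors)
        self.connectivity.validate(errors)
        self.synapses.validate(errors)
        self.modulation.validate(errors)
        self.schedule.validate(errors)
        self.integration.validate(errors)
        self.lfp.validate(errors)
        self.outputs.validate(errors)
        if errors:
            raise ConfigError(
                "invalid configuration:\n" + "\n".join(f"  - {e}" for e in errors)
            )

    # -- (de)serialisation ---------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        def conv(obj: Any) -> Any:
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: conv(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
            if isinstance(obj, dict):
                return {k: conv(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [conv(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        d = conv(self)
        d["schema"] = SCHEMA_VERSION
        return d

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "SimulationConfig":
        raw = copy.deepcopy(raw)
        schema = raw.pop("schema", None)
        if schema != SCHEMA_VERSION:
            raise ConfigError(f"config schema must be {SCHEMA_VERSION}, got {schema!r}")
        try:
            cfg = _build_dataclass(cls, raw, "")
        except ConfigError:
            raise
        cfg.validate()
        return cfg


def _build_dataclass(cls: type, raw: dict[str, Any], prefix: str) -> Any:
    """Construct a dataclass from a nested dict; unknown keys are hard errors."""
    if not isinstance(raw, dict):
        raise ConfigError(f"{prefix or cls.__name__}: expected a mapping, got {type(raw).__name__}")
    field_map = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(raw) - set(field_map)
    if unknown:
        raise ConfigError(
            f"unknown keys under {prefix or 'config root'}: {sorted(unknown)}"
        )
    kwargs: dict[str, Any] = {}
    for name, value in raw.items():
        kwargs[name] = _coerce_field(cls, name, value, f"{prefix}{name}")
    return cls(**kwargs)


_CELL_CLASSES = {"PY": CorticalCellParams, "INH": CorticalCellParams,
                 "TC": ThalamicCellParams, "RE": ThalamicCellParams}


def _coerce_field(cls: type, name: str, value: Any, path: str) -> Any:
    nested: dict[tuple[type, str], type] = {
        (SimulationConfig, "connectivity"): ConnectivityConfig,
        (SimulationConfig, "synapses"): SynapseKinetics,
        (SimulationConfig, "modulation"): ModulationMap,
        (SimulationConfig, "schedule"): StageSchedule,
        (SimulationConfig, "integration"): IntegrationConfig,
        (SimulationConfig, "lfp"): LfpConfig,
        (SimulationConfig, "outputs"): OutputConfig,
        (CorticalCellParams, "soma"): CompartmentDensities,
        (CorticalCellParams, "dend"): CompartmentDensities,
    }
    key = (cls, name)
    if key in nested:
        return _build_dataclass(nested[key], value, f"{path}.")
    if cls is SimulationConfig and name == "cells":
        out = {}
        for pop, sub in value.items():
            if pop not in _CELL_CLASSES:
                raise ConfigError(f"cells has unknown population {pop!r}")
            out[pop] = _build_dataclass(_CELL_CLASSES[pop], sub, f"cells.{pop}.")
        return out
    if cls is ConnectivityConfig and name == "projections":
        return {pname: _build_dataclass(ProjectionConfig, sub, f"connectivity.projections.{pname}.")
                for pname, sub in value.items()}
    if cls is StageSchedule and name == "stages":
        return [_build_dataclass(Stage, s, f"schedule.stages[{i}].") for i, s in enumerate(value)]
    if cls is StageSchedule and name == "levels":
        return {sname: _build_dataclass(NeuromodulatorLevels, sub, f"schedule.levels.{sname}.")
                for sname, sub in value.items()}
    return value


def _default_py() -> CorticalCellParams:
    return CorticalCellParams(
        cm=0.75, rho=165.0, soma_area_cm2=1.0e-6, g_c_uS=0.1,
        vtraub=-55.0, v_init=-68.0,
        soma=CompartmentDensities(g_na=3000.0, g_k=200.0, g_nap=0.0),
        dend=CompartmentDensities(g_na=1.5, g_nap=0.02, g_km=0.1, g_kca=0.3,
                                  g_hva=0.012, g_leak=0.033, e_leak=-68.0, g_kl=0.002),
    )


def _default_inh() -> CorticalCellParams:
    return CorticalCellParams(
        cm=0.75, rho=50.0, soma_area_cm2=1.0e-6, g_c_uS=0.1,
        vtraub=-55.0, v_init=-68.0,
        soma=CompartmentDensities(g_na=2500.0, g_k=200.0),
        dend=CompartmentDensities(g_na=1.5, g_km=0.05, g_kca=0.3,
                                  g_hva=0.012, g_leak=0.033, e_leak=-68.0, g_kl=0.002),
    )


def _default_tc() -> ThalamicCellParams:
    return ThalamicCellParams(
        cm=1.0, area_cm2=2.9e-4, vtraub=-52.0, v_init=-68.0,
        g_na=90.0, g_k=10.0, g_t=2.2, g_h=0.017,
        g_leak=0.01, e_leak=-70.0, g_kl=0.005,
    )


def _default_re() -> ThalamicCellParams:
    return ThalamicCellParams(
        cm=1.0, area_cm2=1.43e-4, vtraub=-52.0, v_init=-70.0,
        g_na=100.0, g_k=10.0, g_t=2.3, g_h=0.0,
        g_leak=0.05, e_leak=-77.0, g_kl=0.003,
    )


def load_config(path: str) -> SimulationConfig:
    """Load and validate a YAML configuration file.

    Raises ConfigError on parse failure (with the line from the YAML parser)
    or on validation failure (listing every violated invariant).
    """
    with open(path) as fh:
        text = fh.read()
    return loads_config(text)


def loads_config(text: str) -> SimulationConfig:
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"config parse error: {exc}") from exc
    if raw is None:
        raw = {}
    return SimulationConfig.from_dict(raw)


def save_config(cfg: SimulationConfig, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(dumps_config(cfg))


def dumps_config(cfg: SimulationConfig) -> str:
    return yaml.safe_dump(cfg.to_dict(), sort_keys=False)


def default_config() -> SimulationConfig:
    """The shipped headline configuration (500/100/100/100 cells, 360 s protocol)."""
    cfg = SimulationConfig()
    cfg.validate()
    return cfg


def packaged_config_path() -> str:
    """Path of the shipped default YAML config."""
    return str(importlib.resources.files("somnotc.data") / "default_config.yaml")
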