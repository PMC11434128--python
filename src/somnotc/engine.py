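"""Fixed-step network integration: event handling, seeding, output capture.

One global step advances, in order: (1) neuromodulator levels from the stage
schedule and the effective-parameter scales derived from them; (2) synapse
kinetics, miniature-release events due in (t, t+dt], and the accumulation of
synaptic conductances onto each target compartment; (3) gating variables and
calcium pools (exponential / exact updates); (4) membrane voltages via a
semi-implicit linear solve; (5) somatic spike detection, which schedules the
transmitter pulses seen by the next step.

A run is fully determined by (config, seed): the only stochastic element —
miniature release — draws from counter-based per-connection streams, and
checkpoint/restore round-trips the complete state bit-exactly.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from . import kernels as K
from .cells import axosomatic_rescale
from .channels import channel_constants
from .config import (POPULATIONS, SimulationConfig, dumps_config, loads_config,
                     neuromod_track)
from .lfp import electrode_position, transfer_resistance_array
from .network import Network, build_network
from .synapses import mini_next_time, splitmix64

CHECKPOINT_VERSION = 1

CORTICAL = ("PY", "INH")
THALAMIC = ("TC", "RE")


class IntegrationError(RuntimeError):
    """Voltage left the finite range — reports population, cell and time."""


class CheckpointError(RuntimeError):
    """Checkpoint blob is unreadable or from an incompatible schema."""


@dataclass
class RunResult:
    """Output container of one run (raster, LFP traces, stage track)."""

    config_yaml: str
    seed: int
    dt_ms: float
    record_dt_ms: float
    settle_ms: float
    duration_ms: float
    pop_offsets: dict[str, int]
    pop_counts: dict[str, int]
    spike_ids: np.ndarray  # global cell ids
    spike_times: np.ndarray  # ms
    t_ms: np.ndarray  # shared sampling grid of all traces
    lfp_summed: np.ndarray  # mV (mean PY dendritic voltage)
    lfp_bio: np.ndarray  # µV (transfer-resistance forward model)
    levels: np.ndarray  # (n_rec, 3) ach/ha/gaba track
    stage_labels: list[str]
    stage_index: np.ndarray  # per-sample index into stage_labels
    voltage_traces: dict[str, np.ndarray] = field(default_factory=dict)
    cortex_vd: np.ndarray | None = None  # (n_rec, n_PY) when requested
    cortex_vs: np.ndarray | None = None
    incomplete: bool = False

    def spikes_of(self, pop: str) -> tuple[np.ndarray, np.ndarray]:
        """(local ids, times) of one population's spikes."""
        lo = self.pop_offsets[pop]
        hi = lo + self.pop_counts[pop]
        m = (self.spike_ids >= lo) & (self.spike_ids < hi)
        return self.spike_ids[m] - lo, self.spike_times[m]

    @property
    def fs_hz(self) -> float:
        return 1000.0 / self.record_dt_ms


def _pack_cortical_params(cfg: SimulationConfig, pop: str,
                          consts: dict[str, float]) -> np.ndarray:
    p = cfg.cells[pop]
    f = axosomatic_rescale(cfg.soma_variant)
    out = np.zeros(K.N_CORT_PARAMS)
    out[K.CP_CM] = p.cm
    out[K.CP_AS] = p.soma_area_cm2
    out[K.CP_AD] = p.dend_area_cm2
    out[K.CP_GC] = p.g_c_uS
    out[K.CP_VTRAUB] = p.vtraub
    out[K.CP_ENA] = p.e_na
    out[K.CP_EK] = p.e_k
    out[K.CP_GS_NA] = f * p.soma.g_na
    out[K.CP_GS_K] = f * p.soma.g_k
    out[K.CP_GS_NAP] = f * p.soma.g_nap
    out[K.CP_GS_LEAK] = f * p.soma.g_leak
    out[K.CP_ES_LEAK] = p.soma.e_leak
    out[K.CP_GS_KL] = f * p.soma.g_kl
    out[K.CP_GD_NA] = p.dend.g_na
    out[K.CP_GD_NAP] = p.dend.g_nap
    out[K.CP_GD_KM] = p.dend.g_km
    out[K.CP_GD_KCA] = p.dend.g_kca
    out[K.CP_GD_HVA] = p.dend.g_hva
    out[K.CP_GD_LEAK] = p.dend.g_leak
    out[K.CP_ED_LEAK] = p.dend.e_leak
    out[K.CP_GD_KL] = p.dend.g_kl
    out[K.CP_KM_Q] = consts["km.q"]
    out[K.CP_KM_RATE] = consts["km.rate"]
    out[K.CP_KM_VHALF] = consts["km.vhalf"]
    out[K.CP_KM_VSLOPE] = consts["km.vslope"]
    out[K.CP_KCA_Q] = consts["kca.q"]
    out[K.CP_KCA_A] = consts["kca.alpha_per_mM"]
    out[K.CP_KCA_B] = consts["kca.beta"]
    out[K.CP_NAP_VHALF] = consts["nap.vhalf"]
    out[K.CP_NAP_SLOPE] = consts["nap.slope"]
    out[K.CP_NAP_TAU] = consts["nap.tau_ms"]
    out[K.CP_HVA_Q] = consts["hva.q"]
    out[K.CP_CA_REST] = consts["ca_cortex.rest_mM"]
    out[K.CP_CA_TAU] = consts["ca_cortex.tau_ms"]
    out[K.CP_CA_INFLUX] = consts["ca_cortex.influx"]
    out[K.CP_CA_OUT] = consts["ca.out_mM"]
    out[K.CP_CA_TEMP] = consts["ca.temp_K"]
    out[K.CP_THRESH] = cfg.integration.spike_threshold_mV
    out[K.CP_REFRACT] = cfg.integration.refractory_ms
    return out


def _pack_thalamic_params(cfg: SimulationConfig, pop: str,
                          consts: dict[str, float]) -> np.ndarray:
    p = cfg.cells[pop]
    it = "it_tc" if pop == "TC" else "it_re"
    out = np.zeros(K.N_THAL_PARAMS)
    out[K.TP_CM] = p.cm
    out[K.TP_AREA] = p.area_cm2
    out[K.TP_VTRAUB] = p.vtraub
    out[K.TP_ENA] = p.e_na
    out[K.TP_EK] = p.e_k
    out[K.TP_G_NA] = p.g_na
    out[K.TP_G_K] = p.g_k
    out[K.TP_G_T] = p.g_t
    out[K.TP_G_H] = p.g_h
    out[K.TP_G_LEAK] = p.g_leak
    out[K.TP_E_LEAK] = p.e_leak
    out[K.TP_G_KL] = p.g_kl
    out[K.TP_IT_MVH] = consts[f"{it}.m_vhalf"]
    out[K.TP_IT_MSL] = consts[f"{it}.m_slope"]
    out[K.TP_IT_HVH] = consts[f"{it}.h_vhalf"]
    out[K.TP_IT_HSL] = consts[f"{it}.h_slope"]
    out[K.TP_IT_PHIM] = consts[f"{it}.phi_m"]
    out[K.TP_IT_PHIH] = consts[f"{it}.phi_h"]
    out[K.TP_IH_VH] = consts["ih.h_vhalf"]
    out[K.TP_IH_SL] = consts["ih.h_slope"]
    out[K.TP_IH_K1] = consts["ih.k2"] / consts["ih.cac"] ** 4
    out[K.TP_IH_K2] = consts["ih.k2"]
    out[K.TP_IH_K3] = consts["ih.k4"] / consts["ih.pc"]
    out[K.TP_IH_K4] = consts["ih.k4"]
    out[K.TP_IH_GINC] = consts["ih.ginc"]
    out[K.TP_IH_EREV] = consts["ih.e_rev"]
    out[K.TP_CA_REST] = consts["ca.rest_mM"]
    out[K.TP_CA_TAU] = consts["ca.tau_ms"]
    out[K.TP_CA_INFLUX] = consts["ca.influx"]
    out[K.TP_CA_OUT] = consts["ca.out_mM"]
    out[K.TP_CA_TEMP] = consts["ca.temp_K"]
    out[K.TP_THRESH] = cfg.integration.spike_threshold_mV
    out[K.TP_REFRACT] = cfg.integration.refractory_ms
    out[K.TP_IS_TC] = 1.0 if pop == "TC" else 0.0
    return out


def _init_cortical_state(cfg: SimulationConfig, pop: str, n: int,
                         consts: dict[str, float]) -> np.ndarray:
    from .cells import build_cell

    cell = build_cell(pop, cfg.cells[pop], cfg.soma_variant, consts)
    S = np.zeros((K.N_CORT_STATE, n))
    S[K.C_VS] = cell.v_soma
    S[K.C_VD] = cell.v_dend
    S[K.C_MS] = cell.m_na_s
    S[K.C_HS] = cell.h_na_s
    S[K.C_NS] = cell.n_k_s
    S[K.C_MNAPS] = cell.m_nap_s
    S[K.C_MD] = cell.m_na_d
    S[K.C_HD] = cell.h_na_d
    S[K.C_MNAPD] = cell.m_nap_d
    S[K.C_MKM] = cell.m_km
    S[K.C_MKCA] = cell.m_kca
    S[K.C_MHVA] = cell.m_hva
    S[K.C_HHVA] = cell.h_hva
    S[K.C_CA] = cell.ca.ca_mM
    S[K.C_LAST] = -1e9
    return S


def _init_thalamic_state(cfg: SimulationConfig, pop: str, n: int,
                         consts: dict[str, float]) -> np.ndarray:
    from .cells import build_cell

    cell = build_cell(pop, cfg.cells[pop], cfg.soma_variant, consts)
    S = np.zeros((K.N_THAL_STATE, n))
    S[K.T_V] = cell.v
    S[K.T_M] = cell.m_na
    S[K.T_H] = cell.h_na
    S[K.T_N] = cell.n_k
    S[K.T_MT] = cell.m_t
    S[K.T_HT] = cell.h_t
    S[K.T_CA] = cell.ca.ca_mM
    S[K.T_O] = cell.ih.O
    S[K.T_OL] = cell.ih.OL
    S[K.T_P1] = cell.ih.P1
    S[K.T_LAST] = -1e9
    return S


class _ProjState:
    """Runtime arrays of one projection (kind 'exc' or 'inh')."""

    def __init__(self, proj, cfg: SimulationConfig, proj_index: int, seed: int):
        self.proj = proj
        self.name = proj.name
        syn = cfg.synapses
        e = proj.n_edges
        excitatory = proj.params.g_ampa > 0 or proj.params.g_nmda > 0
        self.kind = "exc" if excitatory else "inh"
        self.edge_last = np.full(e, -1e9)
        if self.kind == "exc":
            self.o_ampa = np.zeros(e)
            self.o_nmda = np.zeros(e)
            self.edge_e = np.ones(e)
            self.mini_next = np.full(e, np.inf)
            self.mini_counter = np.zeros(e, dtype=np.uint64)
            self.mini_stream = np.zeros(e, dtype=np.uint64)
            pp = np.zeros(K.N_EXC_PARAMS)
            pp[K.EP_ALPHA_A] = syn.ampa_alpha
            pp[K.EP_BETA_A] = syn.ampa_beta
            pp[K.EP_E_A] = syn.ampa_e_rev
            pp[K.EP_ALPHA_N] = syn.nmda_alpha
            pp[K.EP_BETA_N] = syn.nmda_beta
            pp[K.EP_E_N] = syn.nmda_e_rev
            pp[K.EP_MG] = syn.nmda_mg_mM
            pp[K.EP_PULSE_AMP] = syn.pulse_amp_mM
            pp[K.EP_PULSE_DUR] = syn.pulse_dur_ms
            pp[K.EP_DELAY] = proj.params.delay_ms
            pp[K.EP_U] = syn.depression_U
            pp[K.EP_TAU_D] = syn.depression_tau_ms
            pp[K.EP_USE_DEP] = 1.0 if proj.params.depressing else 0.0
            pp[K.EP_USE_MINIS] = 1.0 if proj.params.minis else 0.0
            pp[K.EP_MINI_RATE] = syn.mini_rate_max_hz / 1000.0
            pp[K.EP_MINI_TAU] = syn.mini_tau_recover_ms
            # mini jump: fraction of the open-fraction increment of a full pulse
            full_jump = 1.0 - np.exp(-syn.ampa_alpha * syn.pulse_amp_mM
                                     * syn.pulse_dur_ms)
            pp[K.EP_MINI_JUMP] = syn.mini_amp_fraction * full_jump
            pp[K.EP_HAS_NMDA] = 1.0 if proj.params.g_nmda > 0 else 0.0
            self.pp = pp
            if proj.params.minis:
                with np.errstate(over="ignore"):
                    base = np.uint64(seed) * np.uint64(0x9E3779B97F4A7C15) \
                        ^ (np.uint64(proj_index) << np.uint64(40))
                    for k in range(e):
                        self.mini_stream[k] = splitmix64(base + np.uint64(k))
                        nt, nc = mini_next_time(self.mini_stream[k],
                                                self.mini_counter[k], -1e9, 0.0,
                                                pp[K.EP_MINI_RATE],
                                                pp[K.EP_MINI_TAU])
                        self.mini_next[k] = nt
                        self.mini_counter[k] = nc
        else:
            self.o_gabaa = np.zeros(e)
            self.r_gb = np.zeros(e)
            self.g_gb = np.zeros(e)
            pp = np.zeros(K.N_INH_PARAMS)
            pp[K.IP_ALPHA_A] = syn.gabaa_alpha
            pp[K.IP_BETA_A] = syn.gabaa_beta
            pp[K.IP_E_GABAA] = proj.params.e_gabaa
            pp[K.IP_K1] = syn.gabab_k1
            pp[K.IP_K2] = syn.gabab_k2
            pp[K.IP_K3] = syn.gabab_k3
            pp[K.IP_K4] = syn.gabab_k4
            pp[K.IP_KD] = syn.gabab_kd
            pp[K.IP_E_GABAB] = syn.gabab_e_rev
            pp[K.IP_PULSE_AMP] = syn.pulse_amp_mM
            pp[K.IP_PULSE_DUR] = syn.pulse_dur_ms
            pp[K.IP_DELAY] = proj.params.delay_ms
            pp[K.IP_HAS_GABAB] = 1.0 if proj.params.g_gabab > 0 else 0.0
            self.pp = pp

    def mutable_arrays(self) -> dict[str, np.ndarray]:
        names = (("edge_last", "o_ampa", "o_nmda", "edge_e", "mini_next",
                  "mini_counter") if self.kind == "exc"
                 else ("edge_last", "o_gabaa", "r_gb", "g_gb"))
        return {n: getattr(self, n) for n in names}


class Engine:
    """Stateful integrator for one configured network."""

    def __init__(self, cfg: SimulationConfig, seed: int | None = None,
                 duration_ms: float | None = None):
        cfg.validate()
        self.cfg = cfg
        self.seed = int(cfg.integration.seed if seed is None else seed)
        self.dt = cfg.integration.dt_ms
        total = cfg.total_duration_ms
        self.duration_ms = float(total if duration_ms is None
                                 else min(duration_ms, total))
        self.n_steps = int(round(self.duration_ms / self.dt))
        rec_every = max(1, int(round(cfg.integration.record_dt_ms / self.dt)))
        if abs(rec_every * self.dt - cfg.integration.record_dt_ms) > 1e-9:
            raise ValueError("record_dt_ms must be an integer multiple of dt_ms")
        self.rec_every = rec_every
        self.consts = channel_constants(cfg.channels)
        self.net: Network = build_network(cfg)

        self.params: dict[str, np.ndarray] = {}
        self.states: dict[str, np.ndarray] = {}
        for pop in CORTICAL:
            n = cfg.populations[pop]
            self.params[pop] = _pack_cortical_params(cfg, pop, self.consts)
            self.states[pop] = _init_cortical_state(cfg, pop, n, self.consts)
        for pop in THALAMIC:
            n = cfg.populations[pop]
            self.params[pop] = _pack_thalamic_params(cfg, pop, self.consts)
            self.states[pop] = _init_thalamic_state(cfg, pop, n, self.consts)

        self.projs = [_ProjState(p, cfg, i, self.seed)
                      for i, p in enumerate(self.net.projections)]
        self.gbuf = {p: np.zeros(cfg.populations[p]) for p in POPULATIONS}
        self.gebuf = {p: np.zeros(cfg.populations[p]) for p in POPULATIONS}
        self._scratch = {p: np.zeros(cfg.populations[p], dtype=np.int32)
                         for p in POPULATIONS}

        # modulation gains
        mod = cfg.modulation
        self._kl_gains = {p: (mod.kl_ach[p], mod.kl_ha[p]) for p in POPULATIONS}
        self._ampa_gain = mod.ampa_ach_gain

        # biophysical-LFP weights: per cortical cell, axial current (nA) maps
        # to potential via the soma/dendrite transfer-resistance difference.
        elec = electrode_position(cfg, self.net)
        self._lfp_w: dict[str, np.ndarray] = {}
        for pop in CORTICAL:
            r_s = transfer_resistance_array(elec, self.net.soma_xyz[pop],
                                            cfg.lfp.sigma_S_per_m,
                                            cfg.lfp.min_distance_um)
            r_d = transfer_resistance_array(elec, self.net.dend_xyz[pop],
                                            cfg.lfp.sigma_S_per_m,
                                            cfg.lfp.min_distance_um)
            self._lfp_w[pop] = (r_s - r_d) * 1e-3  # Ω·nA → µV

        # recording buffers
        n_rec = self.n_steps // rec_every + 1
        self.n_rec = n_rec
        self.rec_i = 0
        self.t_rec = np.zeros(n_rec)
        self.lfp_summed = np.zeros(n_rec)
        self.lfp_bio = np.zeros(n_rec)
        self.levels_rec = np.zeros((n_rec, 3))
        self.trace_keys = [(pop, idx) for pop, idxs in
                           cfg.outputs.voltage_traces.items() for idx in idxs]
        self.traces = {f"{pop}:{idx}": np.zeros(n_rec) for pop, idx in self.trace_keys}
        n_py = cfg.populations["PY"]
        if cfg.outputs.record_cortex_voltages:
            self.cortex_vd = np.zeros((n_rec, n_py))
            self.cortex_vs = np.zeros((n_rec, n_py))
        else:
            self.cortex_vd = None
            self.cortex_vs = None
        self.spike_ids: dict[str, list[np.ndarray]] = {p: [] for p in POPULATIONS}
        self.spike_times: dict[str, list[np.ndarray]] = {p: [] for p in POPULATIONS}

        self.step = 0
        self._record()  # initial sample at t = 0

    # -- stepping ----------------------------------------------------------

    @property
    def t(self) -> float:
        return self.step * self.dt

    def _scales(self, ach: float, ha: float, gaba: float):
        kl = {}
        for pop, (ka, kh) in self._kl_gains.items():
            kl[pop] = max(0.0, 1.0 + ka * (1.0 - ach) + kh * (1.0 - ha))
        ampa = max(0.0, 1.0 + self._ampa_gain * (1.0 - ach))
        return kl, ampa, max(0.0, gaba)

    def _record(self) -> None:
        i = self.rec_i
        if i >= self.n_rec:
            return
        self.t_rec[i] = self.t
        lv = neuromod_track(self.cfg.schedule,
                            np.array([min(self.t, self.cfg.total_duration_ms)]))
        self.levels_rec[i] = lv[0]
        vd_py = self.states["PY"][K.C_VD]
        self.lfp_summed[i] = vd_py.mean()
        bio = 0.0
        for pop in CORTICAL:
            S = self.states[pop]
            gc = self.cfg.cells[pop].g_c_uS
            i_ax = gc * (S[K.C_VD] - S[K.C_VS])  # nA, dendrite → soma
            bio += float(i_ax @ self._lfp_w[pop])
        self.lfp_bio[i] = bio
        for pop, idx in self.trace_keys:
            S = self.states[pop]
            row = K.C_VS if pop in CORTICAL else K.T_V
            self.traces[f"{pop}:{idx}"][i] = S[row, idx]
        if self.cortex_vd is not None:
            self.cortex_vd[i] = vd_py
            self.cortex_vs[i] = self.states["PY"][K.C_VS]
        self.rec_i += 1

    def advance(self, n_steps: int = 1, chunk: int = 4000) -> None:
        """Advance the network ``n_steps`` global steps of size dt."""
        dt = self.dt
        end = min(self.step + n_steps, self.n_steps)
        while self.step < end:
            n_chunk = min(chunk, end - self.step)
            ts = (self.step + np.arange(n_chunk)) * dt
            lv = neuromod_track(self.cfg.schedule, np.minimum(ts, self.cfg.total_duration_ms))
            for j in range(n_chunk):
                self._one_step(lv[j, 0], lv[j, 1], lv[j, 2])
                if self.step % self.rec_every == 0:
                    self._record()
            self._check_finite()

    def _one_step(self, ach: float, ha: float, gaba: float) -> None:
        dt = self.dt
        t = self.t
        t_new = t + dt
        kl, ampa_scale, gaba_scale = self._scales(ach, ha, gaba)
        for pop in POPULATIONS:
            self.gbuf[pop].fill(0.0)
            self.gebuf[pop].fill(0.0)
        for ps in self.projs:
            proj = ps.proj
            src, tgt = proj.source, proj.target
            pre_last = self.states[src][K.C_LAST if src in CORTICAL else K.T_LAST]
            if ps.kind == "exc":
                v_row = K.C_VD if tgt in CORTICAL else K.T_V
                scale = ampa_scale if (src in CORTICAL and tgt in CORTICAL) else 1.0
                K.exc_projection_step(
                    t, dt, ps.pp, proj.pre, proj.post, proj.g_ampa, proj.g_nmda,
                    pre_last, ps.edge_last, ps.edge_e, ps.o_ampa, ps.o_nmda,
                    ps.mini_next, ps.mini_counter, ps.mini_stream,
                    self.states[tgt][v_row], self.gbuf[tgt], self.gebuf[tgt],
                    scale)
            else:
                K.inh_projection_step(
                    t, dt, ps.pp, proj.pre, proj.post, proj.g_gabaa,
                    proj.g_gabab, pre_last, ps.edge_last, ps.o_gabaa,
                    ps.r_gb, ps.g_gb, self.gbuf[tgt], self.gebuf[tgt],
                    gaba_scale)
        for pop in CORTICAL:
            ns = K.cortical_step(self.states[pop], self.params[pop],
                                 self.gbuf[pop], self.gebuf[pop], kl[pop],
                                 t_new, dt, self._scratch[pop])
            if ns:
                self.spike_ids[pop].append(self._scratch[pop][:ns].copy())
                self.spike_times[pop].append(np.full(ns, t_new))
        for pop in THALAMIC:
            ns = K.thalamic_step(self.states[pop], self.params[pop],
                                 self.gbuf[pop], self.gebuf[pop], kl[pop],
                                 t_new, dt, self._scratch[pop])
            if ns:
                self.spike_ids[pop].append(self._scratch[pop][:ns].copy())
                self.spike_times[pop].append(np.full(ns, t_new))
        self.step += 1

    def _check_finite(self) -> None:
        for pop in POPULATIONS:
            row = K.C_VS if pop in CORTICAL else K.T_V
            v = self.states[pop][row]
            if not np.all(np.isfinite(v)):
                bad = int(np.flatnonzero(~np.isfinite(v))[0])
                raise IntegrationError(
                    f"non-finite voltage in {pop} cell {bad} at t = {self.t:.3f} ms")

    # -- results -----------------------------------------------------------

    def result(self, incomplete: bool = False) -> RunResult:
        offsets: dict[str, int] = {}
        off = 0
        for pop in POPULATIONS:
            offsets[pop] = off
            off += self.cfg.populations[pop]
        ids_parts, t_parts = [], []
        for pop in POPULATIONS:
            if self.spike_ids[pop]:
                ids_parts.append(np.concatenate(self.spike_ids[pop]).astype(np.int64)
                                 + offsets[pop])
                t_parts.append(np.concatenate(self.spike_times[pop]))
        if ids_parts:
            ids = np.concatenate(ids_parts)
            times = np.concatenate(t_parts)
            order = np.argsort(times, kind="stable")
            ids, times = ids[order], times[order]
        else:
            ids = np.empty(0, dtype=np.int64)
            times = np.empty(0)
        n = self.rec_i
        sched = self.cfg.schedule
        labels = [s.stage for s in sched.stages]
        ends = sched.boundaries()
        stage_idx = np.minimum(np.searchsorted(ends, self.t_rec[:n], side="right"),
                               len(labels) - 1)
        return RunResult(
            config_yaml=dumps_config(self.cfg),
            seed=self.seed,
            dt_ms=self.dt,
            record_dt_ms=self.cfg.integration.record_dt_ms,
            settle_ms=self.cfg.integration.settle_ms,
            duration_ms=self.duration_ms,
            pop_offsets=offsets,
            pop_counts=dict(self.cfg.populations),
            spike_ids=ids,
            spike_times=times,
            t_ms=self.t_rec[:n].copy(),
            lfp_summed=self.lfp_summed[:n].copy(),
            lfp_bio=self.lfp_bio[:n].copy(),
            levels=self.levels_rec[:n].copy(),
            stage_labels=labels,
            stage_index=stage_idx,
            voltage_traces={k: v[:n].copy() for k, v in self.traces.items()},
            cortex_vd=None if self.cortex_vd is None else self.cortex_vd[:n].copy(),
            cortex_vs=None if self.cortex_vs is None else self.cortex_vs[:n].copy(),
            incomplete=incomplete,
        )

    def run_to_end(self) -> RunResult:
        try:
            self.advance(self.n_steps - self.step)
        except IntegrationError:
            # flush partial results with a failure marker, then re-raise
            self.partial_result = self.result(incomplete=True)
            raise
        return self.result()

    # -- checkpointing -------------------------------------------------------

    def checkpoint(self) -> bytes:
        """Serialise the complete engine state (bit-exact restore contract)."""
        arrays: dict[str, np.ndarray] = {}
        for pop in POPULATIONS:
            arrays[f"state_{pop}"] = self.states[pop]
        for i, ps in enumerate(self.projs):
            for name, arr in ps.mutable_arrays().items():
                arrays[f"proj{i}_{name}"] = arr
        arrays["t_rec"] = self.t_rec
        arrays["lfp_summed"] = self.lfp_summed
        arrays["lfp_bio"] = self.lfp_bio
        arrays["levels_rec"] = self.levels_rec
        for k, v in self.traces.items():
            arrays[f"trace_{k}"] = v
        if self.cortex_vd is not None:
            arrays["cortex_vd"] = self.cortex_vd
            arrays["cortex_vs"] = self.cortex_vs
        for pop in POPULATIONS:
            arrays[f"spk_i_{pop}"] = (np.concatenate(self.spike_ids[pop])
                                      if self.spike_ids[pop] else np.empty(0, np.int32))
            arrays[f"spk_t_{pop}"] = (np.concatenate(self.spike_times[pop])
                                      if self.spike_times[pop] else np.empty(0))
        meta = {
            "version": CHECKPOINT_VERSION,
            "step": self.step,
            "rec_i": self.rec_i,
            "seed": self.seed,
            "duration_ms": self.duration_ms,
            "config_yaml": dumps_config(self.cfg),
        }
        buf = io.BytesIO()
        np.savez(buf, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)
        return buf.getvalue()

    @classmethod
    def restore(cls, blob: bytes) -> "Engine":
        try:
            data = np.load(io.BytesIO(blob))
            meta = json.loads(bytes(data["meta"]).decode())
        except Exception as exc:
            raise CheckpointError(f"unreadable checkpoint blob: {exc}") from exc
        if meta.get("version") != CHECKPOINT_VERSION:
            raise CheckpointError(
                f"checkpoint schema {meta.get('version')!r} != {CHECKPOINT_VERSION}")
        cfg = loads_config(meta["config_yaml"])
        eng = cls(cfg, seed=meta["seed"], duration_ms=meta["duration_ms"])
        for pop in POPULATIONS:
            eng.states[pop][...] = data[f"state_{pop}"]
        for i, ps in enumerate(eng.projs):
            for name, arr in ps.mutable_arrays().items():
                arr[...] = data[f"proj{i}_{name}"]
        eng.t_rec[...] = data["t_rec"]
        eng.lfp_summed[...] = data["lfp_summed"]
        eng.lfp_bio[...] = data["lfp_bio"]
        eng.levels_rec[...] = data["levels_rec"]
        for k in eng.traces:
            eng.traces[k][...] = data[f"trace_{k}"]
        if eng.cortex_vd is not None:
            eng.cortex_vd[...] = data["cortex_vd"]
            eng.cortex_vs[...] = data["cortex_vs"]
        for pop in POPULATIONS:
            si = data[f"spk_i_{pop}"]
            st = data[f"spk_t_{pop}"]
            eng.spike_ids[pop] = [si.astype(np.int32)] if si.size else []
            eng.spike_times[pop] = [st] if st.size else []
        eng.step = meta["step"]
        eng.rec_i = meta["rec_i"]
        return eng


def run(cfg: SimulationConfig, seed: int | None = None,
        duration_ms: float | None = None) -> RunResult:
    """Build the network from ``cfg``, integrate to the end, return the result.

    Identical (config, seed) pairs give bit-identical results.
    """
    return Engine(cfg, seed=seed, duration_ms=duration_ms).run_to_end()


# --------------------------------------------------------------------------
# result container (HDF5) and plain-text raster export
# --------------------------------------------------------------------------

def save_result(result: RunResult, path: str) -> None:
    """Write a run to one hierarchical HDF5 file (raster, traces, stage track)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["config_yaml"] = result.config_yaml
        f.attrs["seed"] = result.seed
        f.attrs["dt_ms"] = result.dt_ms
        f.attrs["record_dt_ms"] = result.record_dt_ms
        f.attrs["settle_ms"] = result.settle_ms
        f.attrs["duration_ms"] = result.duration_ms
        f.attrs["incomplete"] = result.incomplete
        f.attrs["stage_labels"] = json.dumps(result.stage_labels)
        f.attrs["pop_offsets"] = json.dumps(result.pop_offsets)
        f.attrs["pop_counts"] = json.dumps(result.pop_counts)
        g = f.create_group("raster")
        g.create_dataset("cell_id", data=result.spike_ids)
        g.create_dataset("time_ms", data=result.spike_times)
        g = f.create_group("traces")
        g.create_dataset("t_ms", data=result.t_ms)
        g.create_dataset("lfp_summed_mV", data=result.lfp_summed)
        g.create_dataset("lfp_bio_uV", data=result.lfp_bio)
        g.create_dataset("levels", data=result.levels)
        g.create_dataset("stage_index", data=result.stage_index)
        gv = g.create_group("voltage")
        for key, tr in result.voltage_traces.items():
            gv.create_dataset(key, data=tr)
        if result.cortex_vd is not None:
            g.create_dataset("cortex_vd", data=result.cortex_vd)
            g.create_dataset("cortex_vs", data=result.cortex_vs)


def load_result(path: str) -> RunResult:
    import h5py

    with h5py.File(path, "r") as f:
        g = f["traces"]
        return RunResult(
            config_yaml=f.attrs["config_yaml"],
            seed=int(f.attrs["seed"]),
            dt_ms=float(f.attrs["dt_ms"]),
            record_dt_ms=float(f.attrs["record_dt_ms"]),
            settle_ms=float(f.attrs["settle_ms"]),
            duration_ms=float(f.attrs["duration_ms"]),
            pop_offsets=json.loads(f.attrs["pop_offsets"]),
            pop_counts=json.loads(f.attrs["pop_counts"]),
            spike_ids=f["raster/cell_id"][...],
            spike_times=f["raster/time_ms"][...],
            t_ms=g["t_ms"][...],
            lfp_summed=g["lfp_summed_mV"][...],
            lfp_bio=g["lfp_bio_uV"][...],
            levels=g["levels"][...],
            stage_labels=json.loads(f.attrs["stage_labels"]),
            stage_index=g["stage_index"][...],
            voltage_traces={k: g["voltage"][k][...] for k in g["voltage"]},
            cortex_vd=g["cortex_vd"][...] if "cortex_vd" in g else None,
            cortex_vs=g["cortex_vs"][...] if "cortex_vs" in g else None,
            incomplete=bool(f.attrs["incomplete"]),
        )


def export_raster_text(result: RunResult, path: str) -> None:
    """Plain-text raster: one ``cell_id<TAB>time_ms`` line per spike."""
    with open(path, "w") as fh:
        for cid, t in zip(result.spike_ids, result.spike_times):
            fh.write(f"{cid}\t{t:.3f}\n")
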