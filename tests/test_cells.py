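"""Cell assembly: soma-variant rescale, membrane equations, spike detection."""

import numpy as np
import pytest

from somnotc import kernels as K
from somnotc.cells import (CorticalCellState, axosomatic_rescale, build_cell,
                           cortical_membrane_currents,
                           cortical_membrane_derivatives, detect_spike,
                           effective_soma_densities)
from somnotc.channels import channel_constants
from somnotc.config import default_config
from somnotc.engine import (_init_cortical_state, _init_thalamic_state,
                            _pack_cortical_params, _pack_thalamic_params)

C = channel_constants()


class TestSomaVariant:
    def test_capacitive_rescale_is_three_quarters(self):
        cfg = default_config()
        for pop in ("PY", "INH"):
            legacy = effective_soma_densities(cfg.cells[pop], "legacy_algebraic")
            capacitive = effective_soma_densities(cfg.cells[pop], "capacitive")
            for key in ("g_na", "g_k", "g_nap", "g_leak", "g_kl"):
                assert capacitive[key] == pytest.approx(0.75 * legacy[key])

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            axosomatic_rescale("nonsense")


class TestBuildCell:
    def test_tc_cell_is_single_compartment(self):
        cfg = default_config()
        cell = build_cell("TC", cfg.cells["TC"], "capacitive", C)
        assert hasattr(cell, "v") and not hasattr(cell, "v_dend")

    def test_gates_initialised_at_steady_state(self):
        # x = x∞(V_init) means zero gating derivative at t = 0: one kernel
        # step at frozen voltage must leave the gates essentially unchanged
        cfg = default_config()
        S = _init_thalamic_state(cfg, "TC", 1, C)
        before = S.copy()
        P = _pack_thalamic_params(cfg, "TC", C)
        # huge leak at V_init keeps the voltage pinned for this check
        P[K.TP_G_LEAK] = 1e4
        P[K.TP_E_LEAK] = cfg.cells["TC"].v_init
        K.thalamic_step(S, P, np.zeros(1), np.zeros(1), 1.0, 0.025, 0.025,
                        np.zeros(1, np.int32))
        for row in (K.T_M, K.T_H, K.T_N, K.T_MT, K.T_HT):
            assert S[row, 0] == pytest.approx(before[row, 0], abs=1e-6)

    def test_cortical_cell_requires_cortical_params(self):
        cfg = default_config()
        with pytest.raises(ValueError, match="rho"):
            build_cell("PY", cfg.cells["TC"], "capacitive", C)


class TestMembraneEquations:
    def test_axial_term_vanishes_when_compartments_equal(self):
        cfg = default_config()
        cell = build_cell("PY", cfg.cells["PY"], "capacitive", C)
        cell.v_soma = cell.v_dend = -65.0
        p = cfg.cells["PY"]
        dvs, dvd = cortical_membrane_derivatives(cell, p, consts=C)
        i_s, i_d = cortical_membrane_currents(cell, p, consts=C)
        # derivatives reduce to pure membrane currents — no axial exchange
        assert dvs == pytest.approx(-i_s / p.cm)
        assert dvd == pytest.approx(-i_d / p.cm)

    def test_zero_conductances_give_zero_derivative(self):
        cfg = default_config()
        p = cfg.cells["PY"]
        for comp in (p.soma, p.dend):
            for name in ("g_na", "g_k", "g_nap", "g_km", "g_kca", "g_hva",
                         "g_leak", "g_kl"):
                setattr(comp, name, 0.0)
        cell = build_cell("PY", p, "capacitive", C)
        cell.v_soma, cell.v_dend = -60.0, -60.0
        dvs, dvd = cortical_membrane_derivatives(cell, p, consts=C)
        assert dvs == 0.0 and dvd == 0.0

    def test_total_charge_bookkeeping(self):
        # A_d·C·dV_d/dt + A_s·C·dV_s/dt = −Σ area-weighted membrane currents;
        # the axial current cancels between the compartments
        cfg = default_config()
        p = cfg.cells["PY"]
        cell = build_cell("PY", p, "capacitive", C)
        cell.v_soma, cell.v_dend = -58.0, -71.0
        dvs, dvd = cortical_membrane_derivatives(cell, p, consts=C)
        i_s, i_d = cortical_membrane_currents(cell, p, consts=C)
        lhs = p.dend_area_cm2 * p.cm * dvd + p.soma_area_cm2 * p.cm * dvs
        rhs = -(p.dend_area_cm2 * i_d + p.soma_area_cm2 * i_s)
        assert lhs == pytest.approx(rhs, rel=1e-12)


class TestDetectSpike:
    def test_subthreshold_no_spike(self):
        fired, last = detect_spike(-60.0, -55.0, 10.0, 2.0, -1e9)
        assert not fired

    def test_upward_crossing_outside_refractory(self):
        fired, last = detect_spike(-5.0, 10.0, 10.0, 2.0, -1e9)
        assert fired and last == 10.0

    def test_refractory_suppresses_second_crossing(self):
        # two threshold crossings 1 ms apart with 2 ms refractory: one spike
        fired1, last = detect_spike(-5.0, 10.0, 10.0, 2.0, -1e9)
        fired2, last2 = detect_spike(-5.0, 10.0, 11.0, 2.0, last)
        assert fired1 and not fired2
        fired3, _ = detect_spike(-5.0, 10.0, 12.5, 2.0, last)
        assert fired3

    def test_downward_crossing_never_fires(self):
        fired, _ = detect_spike(10.0, -5.0, 10.0, 2.0, -1e9)
        assert not fired


class TestSingleCellBehaviour:
    def test_isolated_py_settles_to_stable_rest(self):
        # wake parameters, no synaptic input: |dV/dt| < 1e-6 mV/ms after 2 s
        cfg = default_config()
        P = _pack_cortical_params(cfg, "PY", C)
        S = _init_cortical_state(cfg, "PY", 1, C)
        dt, scratch = 0.025, np.zeros(1, np.int32)
        zero = np.zeros(1)
        for step in range(int(2000 / dt)):
            K.cortical_step(S, P, zero, zero, 1.0, (step + 1) * dt, dt, scratch)
        v1 = S[K.C_VS, 0]
        K.cortical_step(S, P, zero, zero, 1.0, 0.0, dt, scratch)
        assert abs(S[K.C_VS, 0] - v1) / dt < 1e-6
        assert -90.0 < v1 < -55.0

    def test_kleak_hyperpolarises_tc_monotonically(self):
        cfg = default_config()
        P = _pack_thalamic_params(cfg, "TC", C)
        rests = []
        for kl_scale in (1.0, 2.0, 4.0, 8.0):
            S = _init_thalamic_state(cfg, "TC", 1, C)
            dt, scratch = 0.025, np.zeros(1, np.int32)
            zero = np.zeros(1)
            for step in range(int(3000 / dt)):
                K.thalamic_step(S, P, zero, zero, kl_scale, (step + 1) * dt,
                                dt, scratch)
            rests.append(S[K.T_V, 0])
        assert all(b < a for a, b in zip(rests, rests[1:]))

    def test_tc_rebound_burst_after_release(self, rebound_result):
        # ≥ 2 spikes within 50 ms of release from hyperpolarisation — the
        # low-threshold burst underlying spindles
        _, ts = rebound_result.spikes_of("TC")
        release = 2000.0
        burst = ts[(ts >= release) & (ts < release + 50.0)]
        assert burst.size >= 2
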