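"""Channel kinetics: steady states, time constants, calcium, reversal potentials."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from somnotc.channels import (CalciumPool, IhState, channel_constants,
                              hva_rates, ih_regulated_step, it_re_kinetics,
                              it_tc_kinetics, km_kca_nap_hva_kinetics,
                              km_rates, nernst_eca, sigmoid_inf,
                              update_calcium, vtrap)

C = channel_constants()
VGRID = np.linspace(-120.0, 60.0, 181)


class TestSigmoid:
    def test_midpoint(self):
        assert sigmoid_inf(-59.0, -59.0, 6.2) == pytest.approx(0.5)

    def test_saturation(self):
        assert sigmoid_inf(500.0, -59.0, 6.2) == pytest.approx(1.0)
        assert sigmoid_inf(-500.0, -59.0, 6.2) == pytest.approx(0.0, abs=1e-12)

    def test_direct_evaluation(self):
        # 1/(1 + exp(-((-40) - (-59))/6.2))
        assert sigmoid_inf(-40.0, -59.0, 6.2) == pytest.approx(0.9554, abs=5e-4)

    @settings(deadline=None, max_examples=50)
    @given(vh=st.floats(-90, -30), k=st.floats(1.0, 12.0))
    def test_monotone_increasing_for_positive_slope(self, vh, k):
        vals = [sigmoid_inf(v, vh, k) for v in VGRID]
        # non-decreasing everywhere (flat only at saturation), rising overall
        assert np.all(np.diff(vals) >= 0)
        assert vals[0] < vals[-1]


class TestTCurrents:
    def test_tc_half_activations(self):
        minf, _, hinf, _ = it_tc_kinetics(-59.0, C)
        assert minf == pytest.approx(0.5)
        minf, _, hinf, _ = it_tc_kinetics(-83.0, C)
        assert hinf == pytest.approx(0.5)

    def test_re_half_activations(self):
        minf, _, _, _ = it_re_kinetics(-52.0, C)
        assert minf == pytest.approx(0.5)
        _, _, hinf, _ = it_re_kinetics(-80.0, C)
        assert hinf == pytest.approx(0.5)

    def test_re_activation_below_half_voltage(self):
        # closed form: 1/(1 + exp((-52 - (-60))/7.4))
        minf, _, _, _ = it_re_kinetics(-60.0, C)
        assert minf == pytest.approx(0.2535, abs=5e-4)

    @pytest.mark.parametrize("kin", [it_tc_kinetics, it_re_kinetics])
    def test_time_constants_positive_and_finite(self, kin):
        for v in VGRID:
            minf, tau_m, hinf, tau_h = kin(float(v), C)
            assert 0.0 < tau_m < math.inf
            assert 0.0 < tau_h < math.inf
            assert 0.0 <= minf <= 1.0 and 0.0 <= hinf <= 1.0

    def test_inactivation_monotone_decreasing(self):
        h = [it_tc_kinetics(float(v), C)[2] for v in VGRID]
        assert np.all(np.diff(h) < 0)


class TestRegulatedIh:
    def test_no_calcium_no_binding(self):
        s = IhState(O=0.3, OL=0.0, P1=0.0)
        for _ in range(200):
            s = ih_regulated_step(s, -75.0, 1e-8, 0.1, C)
        assert s.P1 == pytest.approx(0.0, abs=1e-6)
        assert s.OL == pytest.approx(0.0, abs=1e-6)

    def test_voltage_gate_equilibrates_at_half_activation(self):
        s = IhState(O=0.0, OL=0.0, P1=0.0)
        for _ in range(400_000):
            s = ih_regulated_step(s, -75.0, C["ca.rest_mM"], 0.25, C)
        assert s.O == pytest.approx(0.5 * (1.0 - s.OL), abs=0.02)

    def test_step_halving_richardson(self):
        # (one step of dt) vs (two steps of dt/2) differ at O(dt²): the gap
        # must shrink ~4x when dt is halved
        s0 = IhState(O=0.2, OL=0.1, P1=0.3)
        v, ca = -70.0, 0.002

        def gap(dt):
            big = ih_regulated_step(s0, v, ca, dt, C)
            half = ih_regulated_step(ih_regulated_step(s0, v, ca, dt / 2, C),
                                     v, ca, dt / 2, C)
            return (abs(big.O - half.O) + abs(big.OL - half.OL)
                    + abs(big.P1 - half.P1))

        g1, g2 = gap(1.0), gap(0.5)
        assert g1 > 0
        assert g1 / g2 == pytest.approx(4.0, rel=0.5)

    def test_fractions_stay_bounded(self):
        rng = np.random.default_rng(0)
        s = IhState(O=0.5, OL=0.2, P1=0.5)
        for _ in range(2000):
            v = rng.uniform(-120, 60)
            ca = rng.uniform(1e-6, 0.02)
            s = ih_regulated_step(s, v, ca, 0.05, C)
            assert 0.0 <= s.O <= 1.0 and 0.0 <= s.OL <= 1.0
            assert s.O + s.OL <= 1.0 + 1e-12
            assert 0.0 <= s.P1 <= 1.0

    def test_rejects_nonpositive_dt(self):
        with pytest.raises(ValueError):
            ih_regulated_step(IhState(), -70.0, 1e-4, 0.0, C)


class TestDendriticCurrents:
    def test_km_rate_limit_at_half_voltage(self):
        a, b = km_rates(C["km.vhalf"], C["km.q"], C["km.rate"], C["km.vhalf"],
                        C["km.vslope"])
        assert a == pytest.approx(C["km.q"] * C["km.rate"] * C["km.vslope"])
        assert b == pytest.approx(C["km.q"] * C["km.rate"] * C["km.vslope"])

    def test_kca_vanishes_without_calcium(self):
        kin = km_kca_nap_hva_kinetics(-60.0, 1e-12, C)
        assert kin["kca"]["m_inf"] == pytest.approx(0.0, abs=1e-6)

    def test_hva_gates_half_open_where_rates_balance(self):
        from scipy.optimize import brentq

        q = C["hva.q"]
        v_m = brentq(lambda v: hva_rates(v, q)[0] - hva_rates(v, q)[1], -60, 20)
        kin = km_kca_nap_hva_kinetics(v_m, C["ca.rest_mM"], C)
        assert kin["hva"]["m_inf"] == pytest.approx(0.5, abs=1e-9)

    def test_vtrap_limit_matches_series(self):
        assert vtrap(1e-9, 4.0) == pytest.approx(4.0, rel=1e-6)
        assert vtrap(0.1, 4.0) == pytest.approx(0.1 / (math.exp(0.025) - 1), rel=1e-12)


class TestCalciumPool:
    def test_rest_is_fixed_point(self):
        pool = CalciumPool()
        out = update_calcium(pool, 0.0, 0.1)
        assert out.ca_mM == pytest.approx(pool.rest_mM)

    def test_monotone_decay_toward_rest(self):
        pool = CalciumPool(ca_mM=0.01)
        prev = pool.ca_mM
        for _ in range(100):
            pool = update_calcium(pool, 0.0, 0.1)
            assert pool.ca_mM <= prev
            prev = pool.ca_mM
        assert pool.ca_mM > pool.rest_mM

    def test_steady_state_under_constant_inward_current(self):
        pool = CalciumPool()
        i_ca = -2.0  # µA/cm², inward
        for _ in range(20_000):
            pool = update_calcium(pool, i_ca, 0.05)
        expected = pool.rest_mM + pool.influx * abs(i_ca) * pool.tau_ms
        assert pool.ca_mM == pytest.approx(expected, rel=1e-3)


class TestNernst:
    def test_symmetry_gives_zero(self):
        assert nernst_eca(1.0, 1.0, 309.0) == pytest.approx(0.0)

    def test_e_squared_ratio_at_rt_over_f_26mv(self):
        t_k = 26e-3 * 96485.332 / 8.31446  # temperature where RT/F = 26 mV
        ca_in = 1e-3
        assert nernst_eca(ca_in, math.e**2 * ca_in, t_k) == pytest.approx(26.0, rel=1e-9)

    def test_physiological_value(self):
        assert nernst_eca(2.4e-4, 2.0, 309.0) == pytest.approx(120.2, abs=0.3)

    def test_rejects_nonpositive_concentration(self):
        with pytest.raises(ValueError):
            nernst_eca(0.0, 2.0)


class TestConstantTable:
    def test_overrides_apply_and_unknown_keys_rejected(self):
        c = channel_constants({"it_tc.m_vhalf": -55.0})
        assert c["it_tc.m_vhalf"] == -55.0
        with pytest.raises(KeyError):
            channel_constants({"no.such_key": 1.0})
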