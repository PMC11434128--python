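"""Integration engine: determinism, numerical stability, checkpointing."""

import numpy as np
import pytest

from somnotc import kernels as K
from somnotc.engine import CheckpointError, Engine, run
from somnotc.fixtures import FixtureSpec, make_fixture

from conftest import SEED, spindle_pair_config


def small_config(duration_ms=2000.0, stage="N2"):
    cfg = spindle_pair_config(stage=stage)
    cfg.schedule.stages[0].duration_ms = duration_ms
    cfg.validate()
    return cfg


class TestRunContract:
    def test_zero_duration_gives_empty_raster_and_initial_sample(self):
        cfg = make_fixture(FixtureSpec("single_tc_rebound", seed=SEED))
        res = run(cfg, duration_ms=0.0)
        assert res.spike_ids.size == 0
        assert res.t_ms.size == 1 and res.t_ms[0] == 0.0
        assert res.voltage_traces["TC:0"][0] == pytest.approx(
            cfg.cells["TC"].v_init)

    def test_same_seed_bit_identical(self):
        a = run(small_config(), seed=5)
        b = run(small_config(), seed=5)
        assert np.array_equal(a.spike_ids, b.spike_ids)
        assert np.array_equal(a.spike_times, b.spike_times)
        assert np.array_equal(a.lfp_summed, b.lfp_summed)
        assert np.array_equal(a.lfp_bio, b.lfp_bio)

    def test_different_seed_changes_mini_driven_run(self):
        a = run(small_config(), seed=1)
        b = run(small_config(), seed=2)
        assert not (np.array_equal(a.spike_times, b.spike_times)
                    and np.array_equal(a.lfp_summed, b.lfp_summed))

    def test_spike_times_within_run_window(self, cycle_result):
        assert cycle_result.spike_times.min() >= 0.0
        assert cycle_result.spike_times.max() <= cycle_result.duration_ms

    def test_traces_share_one_sampling_grid(self, cycle_result):
        n = cycle_result.t_ms.size
        assert cycle_result.lfp_summed.size == n
        assert cycle_result.lfp_bio.size == n
        assert cycle_result.levels.shape == (n, 3)
        dt = np.diff(cycle_result.t_ms)
        assert np.allclose(dt, cycle_result.record_dt_ms)


class TestNumerics:
    def test_gating_variables_stay_in_unit_interval(self):
        eng = Engine(small_config())
        eng.advance(eng.n_steps)
        for pop, rows in (("TC", (K.T_M, K.T_H, K.T_N, K.T_MT, K.T_HT,
                                  K.T_O, K.T_OL, K.T_P1)),
                          ("RE", (K.T_M, K.T_H, K.T_N, K.T_MT, K.T_HT))):
            S = eng.states[pop]
            for row in rows:
                assert S[row].min() >= 0.0 and S[row].max() <= 1.0
        for pop in ("PY", "INH"):
            S = eng.states[pop]
            for row in (K.C_MS, K.C_HS, K.C_NS, K.C_MNAPS, K.C_MD, K.C_HD,
                        K.C_MNAPD, K.C_MKM, K.C_MKCA, K.C_MHVA, K.C_HHVA):
                assert S[row].min() >= 0.0 and S[row].max() <= 1.0

    def test_voltages_stay_in_physiological_range(self, cycle_result):
        assert cycle_result.lfp_summed.min() > -120.0
        assert cycle_result.lfp_summed.max() < 60.0
        for tr in cycle_result.voltage_traces.values():
            assert tr.min() > -120.0 and tr.max() < 60.0

    def test_quiet_cell_trajectory_converges_under_step_halving(self):
        # hyperpolarised (subthreshold) TC cell: halving dt changes the
        # sampled voltage trajectory by well under the convergence tolerance
        cfg = make_fixture(FixtureSpec("single_tc_rebound", seed=SEED))
        va = run(cfg, duration_ms=1500.0).voltage_traces["TC:0"]
        cfg2 = make_fixture(FixtureSpec("single_tc_rebound", seed=SEED))
        cfg2.integration.dt_ms = cfg2.integration.dt_ms / 2
        cfg2.validate()
        vb = run(cfg2, duration_ms=1500.0).voltage_traces["TC:0"]
        # compare after the initial settling transient
        assert np.max(np.abs(va[500:] - vb[500:])) < 0.1


class TestCheckpoint:
    def test_immediate_save_restore_round_trip(self):
        eng = Engine(small_config(duration_ms=1000.0))
        eng.advance(4000)
        blob = eng.checkpoint()
        eng2 = Engine.restore(blob)
        assert eng2.step == eng.step
        for pop in eng.states:
            assert np.array_equal(eng.states[pop], eng2.states[pop])

    def test_resumed_run_bit_identical_to_straight_run(self):
        cfg = small_config(duration_ms=3000.0)
        straight = Engine(cfg).run_to_end()

        eng = Engine(small_config(duration_ms=3000.0))
        eng.advance(int(1500.0 / eng.dt))
        blob = eng.checkpoint()
        resumed_engine = Engine.restore(blob)
        resumed = resumed_engine.run_to_end()

        assert np.array_equal(straight.spike_ids, resumed.spike_ids)
        assert np.array_equal(straight.spike_times, resumed.spike_times)
        assert np.array_equal(straight.lfp_summed, resumed.lfp_summed)
        assert np.array_equal(straight.lfp_bio, resumed.lfp_bio)

    def test_corrupted_blob_raises_not_misloads(self):
        eng = Engine(small_config(duration_ms=500.0))
        blob = eng.checkpoint()
        with pytest.raises(CheckpointError):
            Engine.restore(blob[: len(blob) // 3])
        with pytest.raises(CheckpointError):
            Engine.restore(b"not a checkpoint at all")


class TestDepressionSwitch:
    def test_zero_use_equals_nondepressing_model_exactly(self):
        # with U = 0 the depressing AMPA synapse reduces to plain AMPA:
        # whole-run trace equality to machine precision
        def slab(depressing, u):
            cfg = make_fixture(FixtureSpec("cortical_slab_n3", seed=SEED,
                                           scale=0.025))
            cfg.schedule.stages[0].duration_ms = 1500.0
            for name in ("PY_PY", "PY_INH"):
                cfg.connectivity.projections[name].depressing = depressing
            cfg.synapses.depression_U = u
            cfg.validate()
            return run(cfg)

        a = slab(depressing=True, u=0.0)
        b = slab(depressing=False, u=0.0)
        assert np.array_equal(a.spike_ids, b.spike_ids)
        assert np.array_equal(a.spike_times, b.spike_times)
        assert np.array_equal(a.lfp_summed, b.lfp_summed)


class TestResultContainer:
    def test_hdf5_round_trip(self, tmp_path, rebound_result):
        from somnotc.engine import load_result, save_result

        p = tmp_path / "run.h5"
        save_result(rebound_result, str(p))
        back = load_result(str(p))
        assert np.array_equal(back.spike_ids, rebound_result.spike_ids)
        assert np.array_equal(back.spike_times, rebound_result.spike_times)
        assert np.array_equal(back.lfp_summed, rebound_result.lfp_summed)
        assert back.stage_labels == rebound_result.stage_labels
        assert back.config_yaml == rebound_result.config_yaml

    def test_plain_text_raster_export(self, tmp_path, rebound_result):
        from somnotc.engine import export_raster_text

        p = tmp_path / "raster.tsv"
        export_raster_text(rebound_result, str(p))
        lines = p.read_text().splitlines()
        assert len(lines) == rebound_result.spike_ids.size
        cid, t = lines[0].split("\t")
        assert int(cid) == rebound_result.spike_ids[0]
        assert float(t) == pytest.approx(rebound_result.spike_times[0], abs=1e-3)
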