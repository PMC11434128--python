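"""Shared fixtures: expensive simulation runs are session-scoped so the
dynamical property tests and the acceptance suite reuse the same results."""

from __future__ import annotations

import numpy as np
import pytest

from somnotc.engine import Engine, run
from somnotc.fixtures import FixtureSpec, make_fixture

SEED = 1


@pytest.fixture(scope="session")
def rebound_result():
    cfg = make_fixture(FixtureSpec("single_tc_rebound", seed=SEED))
    return run(cfg)


@pytest.fixture(scope="session")
def spindle_results():
    """(N2 run, wake control run) of the RE–TC pair."""
    out = {}
    for stage in ("N2", "wake"):
        cfg = make_fixture(FixtureSpec("re_tc_spindle_pair", seed=SEED), stage=stage)
        out[stage] = run(cfg)
    return out


@pytest.fixture(scope="session")
def slab_results():
    """(depressing run, U = 0 run) of the N3 cortical slab."""
    cfg = make_fixture(FixtureSpec("cortical_slab_n3", seed=SEED))
    depressing = run(cfg)
    cfg0 = make_fixture(FixtureSpec("cortical_slab_n3", seed=SEED))
    cfg0.synapses.depression_U = 0.0
    no_depression = run(cfg0)
    return {"depressing": depressing, "no_depression": no_depression}


@pytest.fixture(scope="session")
def cycle_result():
    cfg = make_fixture(FixtureSpec("full_reduced_cycle", seed=SEED))
    return run(cfg)


def spindle_pair_config(stage: str = "N2", seed: int = SEED):
    return make_fixture(FixtureSpec("re_tc_spindle_pair", seed=seed), stage=stage)


def thalamic_lfp(result, n_tc: int) -> np.ndarray:
    """Mean TC membrane voltage of a thalamic fixture run (after settling)."""
    v = np.column_stack([result.voltage_traces[f"TC:{i}"] for i in range(n_tc)])
    return v[result.t_ms >= result.settle_ms].mean(axis=1)
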