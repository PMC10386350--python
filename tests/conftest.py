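import numpy as np
import pytest

from phagepool.simulate import (
    SimConfig,
    build_pool,
    emit_reads,
    simulate_trajectories,
    truth_frame,
)


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(seed=7, n_clones=50, depth=2000, error_rate=0.0)


@pytest.fixture(scope="session")
def small_run(small_config):
    """One small error-free stochastic run shared across tests."""
    pool = build_pool(small_config)
    traj = simulate_trajectories(pool, small_config.timepoints)
    sims = emit_reads(pool, traj, small_config)
    return {
        "config": small_config,
        "pool": pool,
        "traj": traj,
        "sims": sims,
        "truth": truth_frame(sims, pool),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20230918)
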