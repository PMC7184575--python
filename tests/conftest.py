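import numpy as np
import pandas as pd
import pytest

from mkgblup import (
    MarkerMatrix,
    RecordDesign,
    SimulationConfig,
    simulate_markers,
    simulate_physiology,
    simulate_trial,
)


@pytest.fixture(scope="session")
def small_config():
    """A small but structurally complete trial configuration."""
    return SimulationConfig(
        n_lines=60,
        n_markers=400,
        n_envs=2,
        n_blocks_per_env=4,
        var_genetic=40.0,
        var_ge=10.0,
        var_error=40.0,
        env_means=[100.0, 120.0],
        block_sd=3.0,
        n_qtl=80,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    markers = simulate_markers(small_config)
    plots, truth = simulate_trial(markers, small_config)
    plots = simulate_physiology(plots, truth, small_config)
    return markers, plots, truth


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture
def tiny_markers():
    """Hand-built 4-line x 3-marker matrix with one missing call."""
    dosage = np.array(
        [
            [0.0, 2.0, 1.0],
            [2.0, 2.0, 0.0],
            [0.0, 0.0, 2.0],
            [2.0, 0.0, 0.0],
        ]
    )
    missing = np.zeros_like(dosage, dtype=bool)
    missing[3, 2] = True
    return MarkerMatrix(
        line_ids=["a", "b", "c", "d"],
        marker_ids=["m1", "m2", "m3"],
        dosage=dosage,
        missing=missing,
    )


@pytest.fixture
def random_psd_kernel(rng):
    def make(n_lines: int, seed: int | None = None):
        r = rng if seed is None else np.random.default_rng(seed)
        A = r.standard_normal((n_lines, max(2 * n_lines, 8)))
        K = A @ A.T / A.shape[1]
        lines = [f"L{i}" for i in range(n_lines)]
        return pd.DataFrame(K, index=lines, columns=lines)

    return make


@pytest.fixture
def grid_design():
    def make(n_lines: int, n_envs: int) -> RecordDesign:
        genos, envs = [], []
        for e in range(n_envs):
            for g in range(n_lines):
                genos.append(f"L{g}")
                envs.append(f"E{e}")
        return RecordDesign(genos, envs)

    return make
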