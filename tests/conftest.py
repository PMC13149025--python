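import numpy as np
import pandas as pd
import pytest

from mfxtools import io
from mfxtools.synthetic import SceneConfig, simulate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_table(trace_ids, ts, xs, ys, zs, efos=None, valid=None):
    n = len(ts)
    return pd.DataFrame(
        {
            "trace_id": np.asarray(trace_ids, dtype=np.int64),
            "t": np.asarray(ts, dtype=float),
            "x": np.asarray(xs, dtype=float),
            "y": np.asarray(ys, dtype=float),
            "z": np.asarray(zs, dtype=float),
            "efo": np.full(n, 75_000.0) if efos is None else np.asarray(efos, dtype=float),
            "valid": np.ones(n, dtype=bool) if valid is None else np.asarray(valid, dtype=bool),
        }
    )


def sparse_scene_config(**overrides) -> SceneConfig:
    """A well-resolved scene: one guaranteed trace of ~12 localizations per
    vertex, so vertex clouds rarely bridge at the default clustering radii."""
    kwargs = dict(
        n_trimers=50,
        side_mean=20.0,
        side_sd=1.5,
        vertex_sigma_xy=3.0,
        vertex_sigma_z=3.0,
        label_efficiency=1.0,
        background_density=0.0,
        field_size=5.0,
        traces_per_vertex_mean=0.0,
        min_traces_per_vertex=1,
        locs_per_vertex_mean=12.0,
        min_locs_per_trace=12,
        efo_shape=0.1,
        rng_seed=0,
    )
    kwargs.update(overrides)
    return SceneConfig(**kwargs)


@pytest.fixture
def small_scene():
    cfg = sparse_scene_config(n_trimers=20, rng_seed=3)
    table, truth = simulate_scene(cfg)
    return cfg, table, truth


@pytest.fixture
def random_table(rng):
    n = 60
    return make_table(
        np.repeat(np.arange(6), 10),
        np.tile(np.arange(10) * 1e-3, 6) + np.repeat(np.arange(6), 10),
        rng.normal(0, 100, n),
        rng.normal(0, 100, n),
        rng.normal(0, 50, n),
        efos=rng.uniform(5e4, 1e5, n),
    )


@pytest.fixture
def empty_table():
    return io.empty_table()
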