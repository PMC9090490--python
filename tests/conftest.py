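import numpy as np
import pandas as pd
import pytest
import trimesh

from morphocell.config import RunConfig
from morphocell.spharm import descriptor_series
from morphocell.synthetic import SynthCellParams, make_cell_sequence


@pytest.fixture(scope="session")
def cfg():
    return RunConfig(seed=0)


@pytest.fixture(scope="session")
def unit_sphere():
    return trimesh.creation.icosphere(subdivisions=4, radius=1.0)


@pytest.fixture(scope="session")
def sphere_r5():
    return trimesh.creation.icosphere(subdivisions=3, radius=5.0)


@pytest.fixture(scope="session")
def ellipsoid211():
    m = trimesh.creation.icosphere(subdivisions=3, radius=1.0)
    m = trimesh.Trimesh(vertices=np.asarray(m.vertices) * np.array([2.0, 1.0, 1.0]),
                        faces=np.asarray(m.faces), process=False)
    return m


@pytest.fixture(scope="session")
def small_cell_seq():
    """Short default synthetic cell (bumpy, noisy, oscillating)."""
    return make_cell_sequence(SynthCellParams(seed=11), n_frames=24, dt=5.0, dataset_id="small")


@pytest.fixture(scope="session")
def run_cells_with_space(cfg):
    """Three run-mode-only cells with descriptor tables and a fitted shape space.

    Shared by shape-space, stats and behavior tests (descriptor computation
    is the expensive step).
    """
    from morphocell.shape_space import fit_pca

    cells = [
        make_cell_sequence(
            SynthCellParams(seed=100 + s, rate_run_to_stop=0.0, rate_stop_to_run=0.0,
                            start_mode="run"),
            220, 5.0, dataset_id=f"run{s}")
        for s in range(2)
    ]
    tables = [descriptor_series(s, cfg) for s in cells]
    space = fit_pca(pd.concat(tables, ignore_index=True))
    return cells, tables, space


def random_rotation(seed):
    rng = np.random.default_rng(seed)
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )
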