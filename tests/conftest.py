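import numpy as np
import pytest

from actfc.preprocess import BoldRun
from actfc.synthdata import SimulationDesign, component_layout, make_toy_atlas


def make_run(data: np.ndarray, tr: float = 2.0, subject_id: str = "s0",
             group_id: str = "A") -> BoldRun:
    """Wrap a (V, T) matrix as a BoldRun on a V x 1 x 1 grid."""
    v = data.shape[0]
    coords = np.column_stack([np.arange(v), np.zeros(v, int), np.zeros(v, int)])
    return BoldRun(data=data, voxel_index=coords, tr_seconds=tr,
                   subject_id=subject_id, group_id=group_id, grid_shape=(v, 1, 1))


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def small_design():
    """Tiny two-group design used across edge-wise testing checks:
    30 shared common voxels (3 shared components of 10), 10 subjects/group."""
    return SimulationDesign(
        grid_shape=(6, 6, 4), n_regions=4, subjects_per_group=10,
        n_volumes=150, n_components=4, activation_fraction=0.3,
        noise_sigma=1.0, seed=101,
    )


@pytest.fixture(scope="session")
def small_layout(small_design):
    return component_layout(small_design)


@pytest.fixture(scope="session")
def small_atlas(small_design):
    return make_toy_atlas(small_design)
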