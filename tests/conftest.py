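import numpy as np
import pytest
import trimesh

from hippofuse.densecnn import ArchConfig
from hippofuse.io import VolumeGrid
from hippofuse.spectrum import TriangleMesh
from hippofuse.synthetic import SyntheticConfig, generate_dataset


def icosphere_mesh(subdivisions: int, radius: float = 1.0) -> TriangleMesh:
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriangleMesh(np.asarray(ico.vertices), np.asarray(ico.faces))


@pytest.fixture(scope="session")
def icosphere4() -> TriangleMesh:
    return icosphere_mesh(4)


@pytest.fixture(scope="session")
def ball_mask() -> VolumeGrid:
    """Voxelized ball of radius 8 mm on a 24-cube grid at 1 mm spacing."""
    from hippofuse.synthetic import make_hippocampus_mask

    mask = make_hippocampus_mask((8.0, 8.0, 8.0), None, (24, 24, 24), (1, 1, 1))
    return VolumeGrid(mask, (1.0, 1.0, 1.0))


def small_synth_config(**overrides) -> SyntheticConfig:
    """A 16-cube configuration small enough for fast CNN tests."""
    kw = dict(n_per_class=10, grid_shape=(16, 16, 16),
              base_semi_axes_mm=(4.5, 3.8, 3.2), atrophy_factor=0.85,
              bump_amplitude_mm=0.4, bump_count_cn=2, bump_count_ad=6,
              jitter_sd=0.1, seed=11)
    kw.update(overrides)
    return SyntheticConfig(**kw)


def small_arch() -> ArchConfig:
    return ArchConfig(input_grid=(16, 16, 16), initial_filters=4,
                      dense_block_filters=(4, 8))


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(small_synth_config())
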