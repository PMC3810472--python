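import numpy as np
import pytest

from restgraph import synthetic as syn
from restgraph.datasets import BoldDataset


@pytest.fixture(scope="session")
def small_config():
    """Small fast cohort: 6^3 grid, 8 regions, 2 sub-blocks per region."""
    return syn.SyntheticConfig(
        grid_shape=(6, 6, 6), n_regions=8, modules_per_region=2,
        n_frames=168, n_subjects_per_group=4, seed=7,
    )


@pytest.fixture(scope="session")
def small_atlas(small_config):
    return syn.generate_toy_atlas(small_config)


@pytest.fixture(scope="session")
def small_cohort(small_config, small_atlas):
    return syn.generate_cohort(small_config, atlas=small_atlas)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_dataset(series: np.ndarray, tr: float = 2.0) -> BoldDataset:
    """Wrap an (n_voxels, n_frames) series matrix as a 1-D-mask dataset."""
    series = np.asarray(series, dtype=float)
    data = series.reshape(series.shape[0], 1, 1, series.shape[1])
    return BoldDataset(data=data, mask=np.ones((series.shape[0], 1, 1), bool),
                       tr_seconds=tr)
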