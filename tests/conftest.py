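import numpy as np
import pytest

from phenoseg import LabeledPointCloud, PlantSpec, generate_plant


@pytest.fixture
def small_cloud():
    """A 40-point labeled cloud with mixed geometry."""
    rng = np.random.default_rng(7)
    coords = rng.uniform(-0.2, 0.2, size=(40, 3))
    labels = (rng.uniform(size=40) < 0.3).astype(int)
    return LabeledPointCloud(coords=coords, labels=labels, name="small")


@pytest.fixture
def seedling():
    """An early-stage synthetic plant (~1k points)."""
    return generate_plant(PlantSpec(stage=2, seed=11, points_per_area=15_000))


@pytest.fixture
def mature_plant():
    """A late-stage synthetic plant with dense canopy structure."""
    return generate_plant(PlantSpec(stage=10, seed=11, points_per_area=15_000))


def subsample(cloud, n, seed=0):
    if cloud.n_points <= n:
        return cloud
    idx = np.random.default_rng(seed).choice(cloud.n_points, n, replace=False)
    return cloud.subset(idx)
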