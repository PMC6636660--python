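import numpy as np
import pytest

from acdpipe import field_inventory as fi
from acdpipe import lidar_processing as lp
from acdpipe.synthetic_forest import (
    LidarSimConfig,
    StandConfig,
    generate_stand,
    simulate_point_cloud,
)


@pytest.fixture(scope="session")
def small_stand():
    """16-plot stand: enough spatial structure to exercise every stage."""
    return generate_stand(StandConfig(n_plots=16, rng_seed=42))


@pytest.fixture(scope="session")
def small_cloud(small_stand):
    return simulate_point_cloud(small_stand, config=LidarSimConfig(rng_seed=43))


@pytest.fixture(scope="session")
def small_npc(small_cloud):
    classified = lp.classify_ground(small_cloud)
    dem = lp.build_dem(classified)
    return lp.normalize_heights(classified, dem)


@pytest.fixture(scope="session")
def small_chm(small_npc, small_stand):
    return lp.rasterize_chm(small_npc, pixel_size=1.0, bounds=small_stand.extent)


@pytest.fixture(scope="session")
def small_summaries(small_stand):
    areas = {p: poly.area for p, poly in small_stand.plots.items()}
    return fi.plot_summaries(small_stand.trees, plot_areas=areas)


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
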