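import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def library():
    from bvtvkit.materials import default_library

    return default_library()


@pytest.fixture(scope="session")
def small_sample():
    """A coarse trabecular block used by several estimator tests."""
    from bvtvkit.phantom import generate_trabecular

    return generate_trabecular(0.285, (9.0, 13.0, 13.0), 0.1, seed=11)


@pytest.fixture(scope="session")
def clinical_fat_sample(small_sample):
    from bvtvkit.phantom import downsample_to_grid, fill_pores

    filled = fill_pores(small_sample, "fat", residual_air_fraction=0.0)
    return downsample_to_grid(filled, 0.43, 0.6)
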