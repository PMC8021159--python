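import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_bank():
    """A short bank (identity + a few smoothing/derivative filters) for
    pipeline tests where the full 80-layer bank would only add runtime."""
    from dropseg.filters import FilterBank, FilterSpec

    return FilterBank(
        specs=(
            FilterSpec("identity", "identity"),
            FilterSpec("gaussian_s1.0", "gaussian", (("sigma", 1.0),)),
            FilterSpec("gaussian_s2.5", "gaussian", (("sigma", 2.5),)),
            FilterSpec("log_s1.6", "laplacian_of_gaussian", (("sigma", 1.6),)),
            FilterSpec("gradmag_s1.0", "gradient_magnitude", (("sigma", 1.0),)),
            FilterSpec("median_w3", "median", (("window", 3.0),)),
        )
    )


@pytest.fixture(scope="session")
def easy_scenes_small():
    """A dozen easy-preset scenes at 32x32 for fast end-to-end tests."""
    from dropseg.synthetic import SceneSpec, generate_dataset

    spec = SceneSpec(canvas=32, cell_axes=(9.0, 13.0), droplet_radius=(2.0, 4.0),
                     droplet_count=(1, 3))
    return generate_dataset(spec, 12, seed=7)
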