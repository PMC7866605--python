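import numpy as np
import pytest

from nirfusion import SpectraSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_set(n=6, m=32, n_classes=2, seed=0, sensor="outer_skin"):
    """Small random SpectraSet with a descending grid."""
    r = np.random.default_rng(seed)
    grid = np.linspace(12000, 3500, m)
    labels = tuple(int(5 * (1 + i % n_classes)) for i in range(n))
    return SpectraSet(
        grid=grid,
        intensities=r.normal(1.0, 0.3, size=(n, m)),
        labels=labels,
        sensor=sensor,
    )


@pytest.fixture
def small_set():
    return make_set()


@pytest.fixture(scope="session")
def default_data():
    """Default synthetic two-sensor dataset, seed 1."""
    from nirfusion import GeneratorConfig, generate
    return generate(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def default_partition(default_data):
    from nirfusion import kennard_stone, default_cal_size
    outer, inner = default_data
    x = np.hstack([outer.intensities, inner.intensities])
    return kennard_stone(x, default_cal_size(outer.n))
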