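import numpy as np
import pytest

from nspnet import AtlasMap, RegionalTimeSeries, SimulationSpec, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def block_fc():
    """Two uncoupled 2-node blocks: the hand-worked partition example."""
    return np.array(
        [
            [1.0, 0.8, 0.0, 0.0],
            [0.8, 1.0, 0.0, 0.0],
            [0.0, 0.0, 1.0, 0.6],
            [0.0, 0.0, 0.6, 1.0],
        ]
    )


@pytest.fixture
def small_atlas():
    return AtlasMap.evenly_split(14)  # 7 systems x 2 regions


def random_fc(rng: np.random.Generator, n: int) -> np.ndarray:
    """Generic nonnegative symmetric unit-diagonal matrix (clipped corrcoef)."""
    x = rng.standard_normal((3 * n, n)) + 0.3 * rng.standard_normal((3 * n, 1))
    C = np.corrcoef(x, rowvar=False)
    C = np.where(C < 0, 0.0, C)
    np.fill_diagonal(C, 1.0)
    return C


@pytest.fixture
def tiny_cohort():
    """Small two-group cohort with a strong planted dwell difference."""
    spec = SimulationSpec(
        n_regions=21,
        n_systems=7,
        n_subjects_per_group=6,
        n_frames=60,
        seed=7,
    )
    return simulate_cohort(spec)


@pytest.fixture
def white_noise_series(rng):
    return RegionalTimeSeries(
        rng.standard_normal((120, 6)), subject_id="sub-wn"
    )
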