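import numpy as np
import pytest

from farka import EpochSet, PopulationSpec, make_population


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_spd(rng, n: int, jitter: float = 0.5) -> np.ndarray:
    A = rng.standard_normal((n, n))
    return A @ A.T + jitter * np.eye(n)


def random_spd_set(rng, n: int, count: int, jitter: float = 0.5) -> np.ndarray:
    return np.stack([random_spd(rng, n, jitter) for _ in range(count)])


@pytest.fixture
def small_population() -> list[EpochSet]:
    """Three subjects, modest size — fast enough for per-test use."""
    spec = PopulationSpec(
        n_subjects=3, n_epochs_per_class=15, ch=4, T=256,
        erd_channels=((0,), (1,)), seed=7,
    )
    return make_population(spec)
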