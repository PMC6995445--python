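import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


def make_spd(rng: np.random.Generator, n: int, n_samples: int | None = None) -> np.ndarray:
    """Well-conditioned random SPD matrix (Wishart-style)."""
    m = n_samples or 3 * n
    a = rng.standard_normal((n, m))
    return a @ a.T / m


def make_correlation(rng: np.random.Generator, n: int, n_samples: int | None = None) -> np.ndarray:
    """Random full-rank sample correlation matrix."""
    q = make_spd(rng, n, n_samples)
    d = np.sqrt(np.diag(q))
    q = q / np.outer(d, d)
    q = (q + q.T) / 2
    np.fill_diagonal(q, 1.0)
    return q


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_study():
    """A compact two-condition study with a clear participant signal."""
    import fcgeo as fg

    cfg = fg.GeneratorConfig(
        n_participants=12,
        n_rois=8,
        n_frames=150,
        n_conditions=2,
        subject_effect=1.0,
        condition_effect=0.0,
        noise_floor=0.5,
        seed=77,
    )
    return fg.generate_study(cfg)
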