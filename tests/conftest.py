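import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mosslif import ImageMeta, RgbImage, SyntheticConfig

# Derandomized hypothesis profile: numba's first-call compilation would trip
# per-example deadlines, and the suite must be reproducible run-to-run.
settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


META = ImageMeta(trial_id="unit", day=1, session="am", position=1, side="front")


def make_image(pixels: np.ndarray, **meta_kwargs) -> RgbImage:
    meta = ImageMeta(**{**META.__dict__, **meta_kwargs}) if meta_kwargs else META
    return RgbImage(pixels=np.asarray(pixels, dtype=np.uint8), meta=meta)


def random_density(rng: np.random.Generator, n_bins: int = 256) -> np.ndarray:
    """A random normalized density curve (Dirichlet-like via exponentials)."""
    raw = rng.exponential(size=n_bins)
    return raw / raw.sum()


def gaussian_density(mu: float, sigma: float, n_bins: int = 256) -> np.ndarray:
    """A discretized, renormalized Gaussian bump — a stylized channel curve."""
    codes = np.arange(n_bins)
    raw = np.exp(-0.5 * ((codes - mu) / sigma) ** 2)
    return raw / raw.sum()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230830)


@pytest.fixture
def tiny_config() -> SyntheticConfig:
    """A miniature study: 2 days x 2 sessions x 4 images of 24x24 frames."""
    return SyntheticConfig(
        width=24,
        height=24,
        days=2,
        sessions_per_day=2,
        images_per_session=4,
        treatment_days=(2,),
        seed=7,
    )
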