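import numpy as np
import pytest

from wallmotion.phantom import PhantomConfig, generate_series


def small_params(**overrides) -> dict:
    """Geometry/timing overrides for a fast 32x32 single-slice phantom."""
    params = dict(
        rows=32,
        cols=32,
        n_slices=1,
        n_frames=128,
        dt=0.05,
        mean_hr=72,
        lv_ed_radius=7,
        lv_es_radius=4,
        rv_ed_radius=7,
        rv_es_radius=5,
        wall_thickness=2,
        seed=1,
    )
    params.update(overrides)
    return params


def small_config(**overrides) -> PhantomConfig:
    """A fast 32x32 single-slice phantom used throughout the suite."""
    return PhantomConfig(**small_params(**overrides))


@pytest.fixture
def make_phantom():
    """Factory fixture: build (series, masks, truth) for a small phantom."""

    def _make(**overrides):
        return generate_series(small_config(**overrides))

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20260904)
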