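import numpy as np
import pytest

from stalkmetric.nn import NetworkConfig, SALevelSpec
from stalkmetric.nn import autograd
from stalkmetric.synthetic import CheckerboardSpec, SyntheticStemConfig, generate_stem_scene


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def float64_engine(monkeypatch):
    """Run the autodiff engine at float64 for finite-difference checks."""
    monkeypatch.setattr(autograd, "DTYPE", np.float64)


@pytest.fixture
def small_net_cfg():
    """A miniature network for fast structural tests (same topology)."""
    return NetworkConfig(
        sa_levels=(
            SALevelSpec(64, 0.1, 16, (16, 16, 32)),
            SALevelSpec(16, 0.2, 16, (32, 32, 64)),
            SALevelSpec(8, 0.3, 8, (64, 64, 64)),
            SALevelSpec(4, 0.4, 8, (64, 64, 64)),
        ),
        fp_mlps=((32, 32), (32, 32), (32, 32), (32, 32, 32)),
        seed=0,
    )


def tiny_scene(seed: int, stem_points: int = 100, ground_points: int = 1858):
    """A 2048-point scene with the realistic ~1:20 stem:background ratio."""
    cfg = SyntheticStemConfig(
        stem_points=stem_points,
        ground_points=ground_points,
        checkerboard=CheckerboardSpec(points_per_square=10),
        seed=seed,
    )
    return generate_stem_scene(cfg)


@pytest.fixture
def clean_scene():
    """A noiseless, dense scene where measurement should be near-exact."""
    cfg = SyntheticStemConfig(stem_points=6000, ground_points=2000, noise_sd=0.0,
                              checkerboard=CheckerboardSpec(points_per_square=30),
                              seed=11)
    return generate_stem_scene(cfg)
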