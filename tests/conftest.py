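import numpy as np
import pytest

from seapen import ColonyRecord, GeneratorConfig
from seapen.synthetic import RelativeNoise


@pytest.fixture
def default_gen() -> GeneratorConfig:
    return GeneratorConfig()


@pytest.fixture
def noise_free_gen() -> GeneratorConfig:
    """Generator with every stochastic distortion switched off."""
    return GeneratorConfig(
        relative_noise=RelativeNoise(rachis=0.0, total=0.0, fresh=0.0, dry=0.0),
        asymmetry_prob=0.0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


@pytest.fixture
def sample_colonies() -> list:
    """A tiny hand-written measured sample."""
    return [
        ColonyRecord("a", 20, 18, 135.7, 79.6, 2.50, 0.80),
        ColonyRecord("b", 22, 22, 140.0, 80.0, 2.60, None),
        ColonyRecord("c", 16, 16, 100.0, 55.0, 1.10, 0.35),
        ColonyRecord("d", 25, 24, 150.0, 82.0, 3.10, 1.05),
        ColonyRecord("e", 18, 18, 120.0, 70.0, 1.90, 0.60),
    ]


@pytest.fixture
def colony_csv(tmp_path):
    """Write a small well-formed colony table and return its path."""
    path = tmp_path / "colonies.csv"
    path.write_text(
        "colony_id,leaves_left,leaves_right,total_length_mm,"
        "peduncle_length_mm,fresh_weight_g,dry_weight_g\n"
        "c1,20,18,135.7,79.6,2.50,0.80\n"
        "c2,22,22,140.0,80.0,2.60,\n"
    )
    return path


@pytest.fixture
def rov_csv(tmp_path):
    path = tmp_path / "rov.csv"
    path.write_text("colony_id,leaf_count\nr1,18\nr2,21\nr3,25\n")
    return path
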