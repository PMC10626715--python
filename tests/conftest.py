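import numpy as np
import pytest

from transitqmp.reactor import ReactorConfig
from transitqmp.simulate import SpeciesParams, SpeciesSet, default_panel


@pytest.fixture(scope="session")
def panel() -> SpeciesSet:
    return default_panel()


@pytest.fixture(scope="session")
def short_config() -> ReactorConfig:
    return ReactorConfig.for_arm("short")


@pytest.fixture
def saturated_species() -> SpeciesSet:
    """Single species with K=0 everywhere it feeds: always saturated."""
    return SpeciesSet(
        [
            SpeciesParams(
                "sat", 0.3, {"simple_carb": (0.0, 1.0)}, 1e11, {"acetate": 5.0}
            )
        ]
    )


@pytest.fixture
def two_pool_species() -> SpeciesSet:
    """Two species on disjoint pools, for conservation accounting."""
    return SpeciesSet(
        [
            SpeciesParams("a", 0.4, {"simple_carb": (0.5, 1.0)}, 2e11,
                          {"acetate": 4.0}),
            SpeciesParams("b", 0.2, {"complex_fibre": (0.8, 1.0)}, 3e11,
                          {"propionate": 3.0}),
        ]
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
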