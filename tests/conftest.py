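import numpy as np
import pytest

from enca import Palette, SceneConfig, generate_scene
from enca.nomenclature import AGRI, FOREST, LandCoverClass, WETLAND
from enca.scene import Climate


@pytest.fixture(scope="session")
def toy_palette():
    """Three-class palette: forest / crops / water."""
    return Palette(
        (
            LandCoverClass(1, "Forest", FOREST, 90, True, True, False, 100, 0.1, 0.4, 40, 8),
            LandCoverClass(2, "Crops", AGRI, 50, False, False, False, 5, 0.1, 0.3, 30, 6),
            LandCoverClass(3, "Water", WETLAND, 0, False, False, True, 0.5, 0.0, 0.1, 5, 1),
        )
    )


@pytest.fixture(scope="session")
def small_config():
    return SceneConfig(grid_shape=(32, 32), n_watersheds=4, seed=11,
                       patches_per_class=1)


def available(scene, cls: int, want: int) -> int:
    """At most ``want`` pixels of ``cls``, capped by what the scene holds."""
    return min(want, int((scene.opening.data == cls).sum()))


@pytest.fixture(scope="session")
def scene(small_config):
    return generate_scene(small_config)


@pytest.fixture(scope="session")
def flat_climate():
    """Identical precipitation at both dates (for no-change invariants)."""
    return Climate(p_series={"2013": 1554.0, "2018": 1554.0})


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
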