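import numpy as np
import pytest

from hemirad import ModelConfig, SceneSpec, make_scene


@pytest.fixture(scope="session")
def config():
    return ModelConfig()


@pytest.fixture(scope="session")
def flat_scene():
    return make_scene(SceneSpec(terrain_kind="flat", extent=200.0))


@pytest.fixture(scope="session")
def crater_scene():
    return make_scene(SceneSpec(terrain_kind="crater", extent=300.0,
                                rim_angle_deg=30.0, crater_radius=80.0))


@pytest.fixture(scope="session")
def inclined_scene():
    return make_scene(SceneSpec(terrain_kind="inclined_plane", extent=300.0,
                                slope_deg=10.0))


@pytest.fixture(scope="session")
def slab_scene():
    return make_scene(SceneSpec(terrain_kind="flat", forest_kind="uniform_slab",
                                extent=100.0, slab_height=20.0))


@pytest.fixture(scope="session")
def gapped_scene():
    return make_scene(SceneSpec(terrain_kind="flat", forest_kind="gapped",
                                extent=100.0, crown_height=15.0,
                                crown_width=4.0, crown_density=0.03,
                                evergreen_fraction=0.3, seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
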