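"""Shared fixtures: small synthetic scenes generated at test time."""

import numpy as np
import pytest

from moorberry.synthetic import SceneConfig, generate_scene


@pytest.fixture(scope="session")
def small_cfg() -> SceneConfig:
    # small frame, bush radii scaled down with it
    return SceneConfig(
        width_px=500,
        height_px=500,
        bush_radius_range_px=(12, 30),
        seed=7,
        site_id="T1",
    )


@pytest.fixture(scope="session")
def small_scene(small_cfg):
    return generate_scene(small_cfg)


@pytest.fixture()
def rng():
    # fresh deterministic stream per test: results don't depend on test order
    return np.random.default_rng(12345)
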