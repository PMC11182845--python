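import numpy as np
import pytest

from perivasc import (
    PipelineConfig,
    SceneSpec,
    generate_scene,
    scene_to_result,
)


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def default_scene():
    """One default synthetic donor scene (seeded)."""
    return generate_scene(SceneSpec(seed=42))


@pytest.fixture(scope="session")
def default_result(default_scene, config):
    """The full single-donor pipeline run on the default scene."""
    return scene_to_result(default_scene, config, donor="d42")


def cylinder_mask(shape, spacing, axis_xy, radius, z_range):
    """Flat-capped cylinder along z, built analytically (test oracle input)."""
    shape = tuple(shape)
    idx = np.indices(shape)
    x = idx[0] * spacing[0]
    y = idx[1] * spacing[1]
    z = idx[2] * spacing[2]
    lateral = (x - axis_xy[0]) ** 2 + (y - axis_xy[1]) ** 2
    return (lateral <= radius**2 + 1e-9) & (z >= z_range[0]) & (z <= z_range[1])


@pytest.fixture(scope="session")
def cylinder():
    """Radius 5 um, length 100 um cylinder at 1 um isotropic spacing."""
    spacing = (1.0, 1.0, 1.0)
    mask = cylinder_mask((24, 24, 106), spacing, (12.0, 12.0), 5.0, (2.0, 102.0))
    return mask, spacing
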