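import numpy as np
import pytest

import lipmorph as lm


@pytest.fixture(scope="session")
def plane15():
    mesh, fn = lm.analytic_surface("plane", size=1.0, resolution=15)
    return mesh, fn


@pytest.fixture(scope="session")
def sphere_lvl4():
    mesh, fn = lm.analytic_surface("sphere", size=1.0, resolution=4)
    return mesh, fn


@pytest.fixture(scope="session")
def sphere10_lvl4():
    mesh, fn = lm.analytic_surface("sphere", size=10.0, resolution=4)
    return mesh, fn


@pytest.fixture(scope="session")
def cylinder_r2():
    mesh, fn = lm.analytic_surface("cylinder", size=2.0, resolution=30)
    return mesh, fn


@pytest.fixture(scope="session")
def saddle70():
    mesh, fn = lm.analytic_surface("saddle", size=4.0, resolution=70)
    return mesh, fn


@pytest.fixture(scope="session")
def patch_config():
    return lm.SyntheticConfig(
        trait="philtrum", n_categories=3, n_per_category=2, seed=11
    )


@pytest.fixture(scope="session")
def patch_with_landmarks(patch_config):
    mesh, lms, label = lm.lip_patch(patch_config, 0)
    return mesh, lms


@pytest.fixture(scope="session")
def aligned_patch(patch_with_landmarks):
    mesh, lms = patch_with_landmarks
    return lm.align_pose(mesh, lms)


@pytest.fixture(scope="session")
def patch_field(aligned_patch):
    mesh, _ = aligned_patch
    return lm.curvature_tensor_field(mesh, neighborhood_radius=2.5)


def antipodal_pair(mesh):
    v0 = mesh.vertices[0]
    anti = int(np.argmin(np.linalg.norm(mesh.vertices + v0, axis=1)))
    return 0, anti
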