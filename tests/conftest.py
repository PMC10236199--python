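"""Shared fixtures: phantoms and the one expensive end-to-end run.

The belly-bulge personalization (baseline phantom vs analytically bulged
subject) is session-scoped because several accuracy, quality and contact
checks all interrogate the same run.
"""

from __future__ import annotations

import numpy as np
import pytest

from morphforge import (
    Deformation,
    PipelineConfig,
    deform_phantom,
    make_phantom,
    run_pipeline,
)
from morphforge.phantom import PhantomSpec


BULGE_CENTER = (0.0, 25.0, -15.0)   # on the belly skin of the default phantom
BULGE_AMPLITUDE = 20.0              # mm; 10 voxels at the 2 mm default grid
BULGE_RADIUS = 40.0


@pytest.fixture(scope="session")
def phantom():
    return make_phantom()


@pytest.fixture(scope="session")
def bulge():
    return Deformation(
        "belly_bulge", (BULGE_AMPLITUDE, BULGE_RADIUS), center=BULGE_CENTER
    )


@pytest.fixture(scope="session")
def bulged_phantom(phantom, bulge):
    return deform_phantom(phantom, bulge)


@pytest.fixture(scope="session")
def bulge_pipeline(phantom, bulged_phantom):
    """Type I personalization of the baseline phantom to its bulged twin."""
    cfg = PipelineConfig(
        baseline_skin=phantom.skin_surfaces,
        baseline_skeleton=phantom.skeleton_surfaces,
        baseline_mesh=phantom.mesh,
        subject_skin=bulged_phantom.skin_surfaces,
        subject_skeleton=bulged_phantom.skeleton_surfaces,
        rigid_mode="none",
    )
    return run_pipeline(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
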