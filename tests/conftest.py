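"""Shared fixtures: synthetic phantoms and hand-built toy head models.

Phantoms are generated programmatically at test time; the "tiny"
configuration keeps grids small enough that distance transforms and
candidate sweeps stay fast while preserving all the geometric
structure the planner relies on.
"""

import numpy as np
import pytest

from seegplan.metrics import TrajectoryEvaluator
from seegplan.phantom import HeadModel, PhantomConfig, make_phantom

TINY_KW = dict(
    grid_shape=(64, 64, 64),
    scalp_radius_mm=28.0,
    brain_radius_mm=24.0,
    n_target_rois=2,
    roi_radius_mm=4.0,
    n_sulci=3,
    sulcus_depth_mm=6.0,
    n_vessel_trees=1,
    vessel_radius_mm=1.0,
)

SMALL_KW = dict(
    grid_shape=(96, 96, 96),
    scalp_radius_mm=44.0,
    brain_radius_mm=38.0,
    n_target_rois=3,
    roi_radius_mm=5.0,
    n_sulci=4,
    sulcus_depth_mm=8.0,
)


def tiny_config(seed=3, **overrides) -> PhantomConfig:
    return PhantomConfig(seed=seed, **{**TINY_KW, **overrides})


@pytest.fixture(scope="session")
def tiny_phantom():
    return make_phantom(tiny_config())


@pytest.fixture(scope="session")
def small_phantom():
    return make_phantom(PhantomConfig(seed=1, **SMALL_KW))


@pytest.fixture(scope="session")
def small_evaluator(small_phantom):
    model, _ = small_phantom
    return TrajectoryEvaluator(model)


def centered_affine(shape, spacing=(1.0, 1.0, 1.0)) -> np.ndarray:
    shape = np.asarray(shape)
    spacing = np.asarray(spacing, float)
    affine = np.eye(4)
    affine[:3, :3] = np.diag(spacing)
    affine[:3, 3] = -(shape - 1) * spacing / 2.0
    return affine


def ball_model(
    shape=(80, 80, 80),
    scalp_r=36.0,
    brain_r=30.0,
    gm_t=3.0,
    vessel_voxels=(),
    sulci_voxels=(),
) -> HeadModel:
    """Concentric-sphere head model with hand-placed vessels/sulci voxels.

    The vessel mask gets one far-corner voxel by default so distance
    fields are well-defined without sentinel warnings.
    """
    affine = centered_affine(shape)
    shape = tuple(shape)
    idx = np.indices(shape).reshape(3, -1).T
    world = idx + affine[:3, 3]
    r = np.linalg.norm(world, axis=1).reshape(shape)
    scalp = r <= scalp_r
    brain = r <= brain_r
    gm = brain & (r > brain_r - gm_t)
    vessels = np.zeros(shape, bool)
    if vessel_voxels is not None:
        if len(vessel_voxels) == 0:
            # default: one deep vessel voxel on the -x side, far from the
            # +x/+z test trajectories, so fields are non-sentinel
            vessel_voxels = [(shape[0] // 2 - int(brain_r) + 5, shape[1] // 2, shape[2] // 2)]
        for v in vessel_voxels:
            vessels[tuple(v)] = True
    sulci = np.zeros(shape, bool)
    for v in sulci_voxels:
        sulci[tuple(v)] = True
    sulci &= brain
    return HeadModel(
        scalp_mask=scalp, brain_mask=brain, gm_mask=gm, sulci_mask=sulci,
        vessel_mask=vessels & scalp,
        roi_labels=np.zeros(shape, np.int16), affine=affine,
    )
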