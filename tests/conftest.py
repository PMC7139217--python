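import numpy as np
import pytest

from densedock import (
    LigandPose,
    SimulationParams,
    make_engine_outputs,
    make_scene,
)


@pytest.fixture(scope="session")
def clean_scene():
    """Noise-free paired-map scene (shared; treat as read-only)."""
    return make_scene(resolution=4.0, voxel=1.0, noise_sigma=0.0, seed=7)


@pytest.fixture(scope="session")
def noisy_scene():
    return make_scene(resolution=4.0, voxel=1.0, noise_sigma=0.1, seed=3)


@pytest.fixture(scope="session")
def engine_emulation(noisy_scene):
    return make_engine_outputs(
        noisy_scene, n_engines=3, n_poses=20, decoy_range=(5.0, 20.0), seed=3
    )


@pytest.fixture(scope="session")
def sim_params():
    return SimulationParams(resolution=4.0, voxel_size=1.0)


def make_fragment_pose(pose_id="p", engine="", score=None, lower=True):
    """A small rigid 5-atom fragment with distinct atom names."""
    coords = np.array(
        [
            [0.0, 0.0, 0.0],
            [1.5, 0.0, 0.0],
            [1.5, 1.4, 0.0],
            [0.0, 1.4, 0.6],
            [-1.2, 0.7, 0.0],
        ]
    )
    return LigandPose(
        names=["C1", "C2", "N1", "O1", "C3"],
        elements=["C", "C", "N", "O", "C"],
        coords=coords,
        engine=engine,
        engine_score=score,
        lower_is_better=lower if score is not None else None,
        pose_id=pose_id,
    )


def random_rigid_copy(pose, rng, max_shift=15.0):
    """Random rotation + translation of a pose (uniform shift in a box)."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(random_state=rng).as_matrix()
    shift = rng.uniform(-max_shift, max_shift, 3)
    return pose.transformed(rot, shift)
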