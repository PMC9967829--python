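import numpy as np
import pytest

from stairwatch import CameraIntrinsics, Session, SkeletonFrame
from stairwatch.scene import SceneSpec


@pytest.fixture(scope="session")
def intr():
    return CameraIntrinsics(fx=500.0, fy=500.0, cx=320.0, cy=240.0, width=640, height=480)


@pytest.fixture(scope="session")
def scene():
    return SceneSpec()


@pytest.fixture(scope="session")
def true_frame(scene):
    return scene.stair_frame()


def make_stair_session(times, pelvis, intr, direction="unknown", participant="t"):
    """Build a stair-space session with only a pelvis trajectory."""
    frames = [
        SkeletonFrame(timestamp=float(t), joints={"PELVIS": np.asarray(p, dtype=float)})
        for t, p in zip(times, pelvis)
    ]
    return Session(
        frames=frames, intrinsics=intr, participant=participant,
        direction=direction, space="stair",
    )


@pytest.fixture(scope="session")
def stair_session_factory(intr):
    def factory(times, pelvis, **kw):
        return make_stair_session(times, pelvis, intr, **kw)

    return factory
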