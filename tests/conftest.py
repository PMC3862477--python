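import numpy as np
import pytest

from stiflemech.kinematics import BoneLandmarks, Point3


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def axis_aligned_femur(frame: str = "lab") -> BoneLandmarks:
    """Femur with condyle centers on the x axis and the head straight above:
    its anatomic frame is the identity."""
    return BoneLandmarks(
        role="femur",
        points={
            "medial_condyle_center": Point3(12.5, 0.0, 0.0, frame),
            "lateral_condyle_center": Point3(-12.5, 0.0, 0.0, frame),
            "femoral_head_center": Point3(0.0, 0.0, 200.0, frame),
            "ccl_origin": Point3(-3.0, -6.0, 1.0, frame),
        },
    )


def axis_aligned_tibia(frame: str = "lab") -> BoneLandmarks:
    return BoneLandmarks(
        role="tibia",
        points={
            "medial_condyle_edge": Point3(15.0, 0.0, 0.0, frame),
            "lateral_condyle_edge": Point3(-15.0, 0.0, 0.0, frame),
            "distal_tibia_center": Point3(0.0, 0.0, -210.0, frame),
            "ccl_insertion": Point3(1.0, 7.0, -4.0, frame),
        },
    )


@pytest.fixture
def femur_landmarks():
    return axis_aligned_femur()


@pytest.fixture
def tibia_landmarks():
    return axis_aligned_tibia()
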