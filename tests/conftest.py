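import math

import numpy as np
import pytest

from rootangle import FDISchema, default_dentition, generate_phantom
from rootangle.angulation import ToothInstance


@pytest.fixture(scope="session")
def schema():
    return FDISchema.default()


@pytest.fixture(scope="session")
def straight_phantom():
    """One full-dentition phantom with straight roots and its ground truth."""
    spec = default_dentition(seed=11, hook_prob=0.0)
    return generate_phantom(spec)


def rotated_rect_instance(height, width, angle_deg, class_index=1, offset=(300, 500)):
    """Exact rasterization of a height x width rectangle rotated by angle_deg.

    The rectangle's long side lies along the image rows before rotation, so
    the expected from-vertical orientation of the rotated shape is angle_deg.
    """
    a = math.radians(angle_deg)
    half_h, half_w = height / 2.0, width / 2.0
    pad = int(math.ceil(math.hypot(half_h, half_w))) + 2
    rr, cc = np.mgrid[-pad:pad + 1, -pad:pad + 1]
    # rotate pixel coords back by -angle and test against the axis-aligned box
    r_back = rr * math.cos(a) + cc * math.sin(a)
    c_back = -rr * math.sin(a) + cc * math.cos(a)
    inside = (np.abs(r_back) <= half_h) & (np.abs(c_back) <= half_w)
    return ToothInstance(class_index, rr[inside] + offset[0], cc[inside] + offset[1])
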