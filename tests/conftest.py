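import numpy as np
import pytest

from lapseg.mask_io import ClassTable
from lapseg.scene_fixtures import ClassSpec, SceneConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def table3():
    """Tiny 3-class table for conversion tests."""
    return ClassTable(
        (
            (0, "background", (0, 0, 0)),
            (1, "tissue", (200, 60, 60)),
            (2, "tool", (120, 120, 140)),
        )
    )


@pytest.fixture
def tiny_scene():
    """Cheap 4-class scene config for pipeline tests (32x32)."""
    return SceneConfig(
        class_specs=(
            ClassSpec("background", 1.0, 0.4, "background", (10, 10, 10)),
            ClassSpec("tissue", 1.0, 0.4, "large_blob", (200, 80, 80)),
            ClassSpec("organ", 0.8, 0.12, "medium_blob", (90, 160, 60)),
            ClassSpec("tool", 0.7, 0.05, "elongated_tool", (170, 170, 190)),
        ),
        image_size=(32, 32),
        seed=11,
    )


def random_mask_pair(rng, max_side=8, n_classes=4):
    h = int(rng.integers(1, max_side + 1))
    w = int(rng.integers(1, max_side + 1))
    return (
        rng.integers(0, n_classes, (h, w)),
        rng.integers(0, n_classes, (h, w)),
    )
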