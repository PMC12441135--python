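import numpy as np
import pytest

from clonemap.core_model import CellRecord, ImageStack
from clonemap.ephys import StepProtocol


def make_stack(positions, colors, image_id="img0", mouse_id="m0",
               condition="stroke", timepoint="2w",
               bounds=(400.0, 400.0, 30.0), ki67=None):
    """Build an ImageStack from explicit coordinates and colors."""
    cells = []
    for i, (p, c) in enumerate(zip(positions, colors)):
        flag = None if ki67 is None else bool(ki67[i])
        cells.append(CellRecord(cell_id=f"{image_id}:{i}", image_id=image_id,
                                x=float(p[0]), y=float(p[1]),
                                z=float(p[2]) if len(p) > 2 else 0.0,
                                color=c, ki67=flag))
    return ImageStack(image_id=image_id, mouse_id=mouse_id,
                      condition=condition, timepoint=timepoint,
                      x_extent=bounds[0], y_extent=bounds[1],
                      z_height=bounds[2], cells=cells)


@pytest.fixture
def two_cell_stack():
    return make_stack([(100, 100, 10), (150, 100, 20)], ["YFP", "YFP"])


@pytest.fixture
def random_stack():
    rng = np.random.default_rng(42)
    n = 120
    pos = rng.uniform(0, 1, size=(n, 3)) * np.array([400.0, 400.0, 30.0])
    colors = rng.choice(["mCFP", "nGFP", "YFP", "RFP"], size=n)
    return make_stack(pos, colors)


@pytest.fixture
def proto70():
    return StepProtocol(holding=-70.0)


@pytest.fixture
def proto20():
    return StepProtocol(holding=-20.0)
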