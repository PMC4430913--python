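import numpy as np
import pytest

from stenoreg import phantom


@pytest.fixture()
def tube_spec2d():
    """Single straight tube, width 6 px, noise-free."""
    return phantom.PhantomSpec2D(
        image_size=(96, 96),
        tree=[phantom.Branch2D("main", [(10.0, 12.0), (80.0, 84.0)], width=6.0)],
        noise_sd=0.0,
        seed=3,
    )


@pytest.fixture()
def tree_spec2d():
    """Three branches meeting at one junction, widths 4-8 px."""
    j = (48.0, 48.0)
    return phantom.PhantomSpec2D(
        image_size=(96, 96),
        tree=[
            phantom.Branch2D("prox", [(6.0, 10.0), j], width=8.0),
            phantom.Branch2D("dist", [j, (88.0, 80.0)], width=6.0),
            phantom.Branch2D("side", [j, (20.0, 86.0)], width=4.0),
        ],
        noise_sd=0.0,
        seed=0,
    )


@pytest.fixture()
def cross_mask():
    """1-px '+' cross with arms of length 5 (center at (10, 10))."""
    m = np.zeros((21, 21), dtype=bool)
    m[10, 5:16] = True
    m[5:16, 10] = True
    return m


def straight_curve(z0, z1, y0, x0, dy=0.0, dx=0.0, n=12):
    t = np.linspace(0.0, 1.0, n)
    return np.column_stack([z0 + (z1 - z0) * t, y0 + dy * t, x0 + dx * t])


@pytest.fixture()
def vertical_tube_spec3d():
    """One vertical tube of radius 3 spanning slices 10-40."""
    return phantom.PhantomSpec3D(
        volume_size=(56, 64, 64),
        artery_curves=(
            phantom.Branch3D("LAD", straight_curve(10, 40, 32, 32), radius=3.0),
        ),
        noise_sd=0.0,
        seed=0,
    )
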