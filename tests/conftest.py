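import numpy as np
import pytest

from woundtrack.edge_extraction import Front
from woundtrack.synthetic import SyntheticWoundSpec


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_spec():
    """Small synthetic wound spec used across segmentation tests."""
    return SyntheticWoundSpec(
        height=300, width=400, n_frames=6, drift_vd=2.0, lag_tau1=2, seed=7
    )


@pytest.fixture
def straight_front():
    return Front(side="L", points=np.array([[0.0, 0.0], [0.0, 100.0]]))


def make_stripe_mask(height, width, x_left, x_right):
    """Cell mask with a vertical background stripe x in [x_left, x_right)."""
    mask = np.ones((height, width), dtype=bool)
    mask[:, x_left:x_right] = False
    return mask


def make_sinusoid_mask(height, width, x_left_fn, x_right_fn):
    """Cell mask whose gap edges follow x_left_fn(y), x_right_fn(y)."""
    cols = np.arange(width)[None, :]
    y = np.arange(height)
    xl = np.asarray(x_left_fn(y))[:, None]
    xr = np.asarray(x_right_fn(y))[:, None]
    return (cols < xl) | (cols > xr)
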