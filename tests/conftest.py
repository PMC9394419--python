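import numpy as np
import pytest

from trusfit import PhantomSpec, SliceGrid, SuperellipseParams, generate_phantom


def random_valid_params(rng, with_pose=True):
    """Draw one parameter vector inside every model invariant."""
    ax = rng.uniform(8.0, 25.0)
    ay = rng.uniform(8.0, 25.0)
    eps = rng.uniform(1.0, 3.5)
    t = rng.uniform(-0.4, 0.4)
    b = rng.uniform(-0.4, 0.4) / ay
    r = rng.uniform(-np.pi / 2 + 1e-3, np.pi / 2)
    lx, ly = (rng.uniform(28.0, 36.0, size=2) if with_pose else (0.0, 0.0))
    return SuperellipseParams(ax=ax, ay=ay, lx=lx, ly=ly, r=r, eps=eps, t=t, b=b)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def grid128():
    return SliceGrid(rows=128, cols=128, spacing_x=0.5, spacing_y=0.5, origin=(0.0, 0.0))


@pytest.fixture(scope="session")
def default_phantom():
    spec = PhantomSpec(seed=7)
    mask, model = generate_phantom(spec)
    return spec, mask, model


def small_phantom_spec(seed=0):
    """Reduced-scale phantom for registration tests (keeps volumes small)."""
    cx, cy = 24.0, 24.0
    rows = [
        (0.0, 9.0, 7.5, 2.0, 0.05, 0.0),
        (8.0, 13.0, 11.0, 2.2, 0.12, 0.008),
        (16.0, 15.0, 12.5, 2.4, 0.18, 0.012),
        (24.0, 13.0, 11.0, 2.2, 0.12, 0.008),
        (32.0, 9.5, 8.0, 2.0, 0.05, 0.0),
    ]
    stack = [
        (z, SuperellipseParams(ax=ax, ay=ay, lx=cx, ly=cy, r=0.1, eps=eps, t=t, b=b))
        for z, ax, ay, eps, t, b in rows
    ]
    grid = SliceGrid(rows=96, cols=96, spacing_x=0.5, spacing_y=0.5)
    return PhantomSpec(stack=stack, grid=grid, z_spacing=2.0, seed=seed)


@pytest.fixture(scope="session")
def small_phantom():
    spec = small_phantom_spec()
    mask, model = generate_phantom(spec)
    return spec, mask, model
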