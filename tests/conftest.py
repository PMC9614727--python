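import numpy as np
import pytest

from poreflux import ChannelGeometry, Selection, SyntheticSpec, Trajectory


@pytest.fixture
def geom():
    """A 0.4 nm channel through a 2.5 nm slab, axis at the box center."""
    return ChannelGeometry(
        origin=np.array([5.0, 5.0, 6.0]), radius=0.4, z_lo=-1.25, z_hi=1.25
    )


@pytest.fixture
def spec():
    return SyntheticSpec(seed=42)


def make_traj(z_paths, box=(10.0, 10.0, 12.0), xy=(5.0, 5.0), dt=0.01):
    """Trajectory from explicit per-particle z paths at fixed xy (on-axis)."""
    z = np.atleast_2d(np.asarray(z_paths, dtype=float))  # (P, T)
    T = z.shape[1]
    pos = np.empty((T, z.shape[0], 3))
    pos[:, :, 0] = xy[0]
    pos[:, :, 1] = xy[1]
    pos[:, :, 2] = z.T
    return Trajectory(np.arange(T) * dt, pos, np.asarray(box, dtype=float))


def water_sel(n):
    return Selection("waters", np.arange(n), "water-oxygen")
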