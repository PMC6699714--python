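import numpy as np
import pytest

from cilialoss.trajectory_io import LengthTrajectory


def make_traj(
    lengths,
    interval_s=90.0,
    cilium_id="c0",
    condition="serum",
    role="experimental",
    times=None,
):
    """Build a trajectory from a plain list of lengths on a regular grid."""
    lengths = np.asarray(lengths, dtype=float)
    if times is None:
        times = np.arange(len(lengths)) * interval_s
    return LengthTrajectory(
        cilium_id=cilium_id,
        condition=condition,
        role=role,
        times=np.asarray(times, dtype=float),
        lengths=lengths,
        frame_interval=interval_s,
    )


@pytest.fixture
def traj_factory():
    return make_traj
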