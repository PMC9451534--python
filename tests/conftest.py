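import zlib

import numpy as np
import pytest

from sptstates.data import AcquisitionParams, Trajectory, TrajectoryDataset


@pytest.fixture
def rng(request):
    """Deterministic per-test generator, independent of execution order."""
    return np.random.default_rng(zlib.crc32(request.node.name.encode()))


def make_rbme_trajectory(rng, L, D, loc_error_var, dt, traj_id=0, start_frame=0):
    """Exact RBME trajectory: Brownian path plus iid positional noise."""
    path = np.sqrt(2.0 * D * dt) * rng.standard_normal((L + 1, 2)).cumsum(axis=0)
    pos = path + np.sqrt(loc_error_var) * rng.standard_normal((L + 1, 2))
    return Trajectory(traj_id, np.arange(start_frame, start_frame + L + 1), pos)


def make_rbme_dataset(rng, n, D, loc_error_var, dt=0.00748, mean_jumps=4.0,
                      max_jumps=40, occupations=None):
    """Dataset of iid RBME trajectories; D may be scalar or per-state with
    ``occupations`` giving mixture weights. Returns (dataset, labels)."""
    D = np.atleast_1d(np.asarray(D, dtype=float))
    s2 = np.broadcast_to(np.atleast_1d(np.asarray(loc_error_var, dtype=float)), D.shape)
    if occupations is None:
        occupations = np.full(D.size, 1.0 / D.size)
    labels = rng.choice(D.size, size=n, p=occupations)
    trajs = []
    for i, k in enumerate(labels):
        L = min(int(rng.geometric(1.0 / mean_jumps)), max_jumps)
        trajs.append(make_rbme_trajectory(rng, L, D[k], s2[k], dt, traj_id=i))
    ds = TrajectoryDataset(trajs, AcquisitionParams(frame_interval=dt))
    return ds, labels


@pytest.fixture
def small_rbme_dataset(rng):
    ds, _ = make_rbme_dataset(rng, 200, 1.0, 0.001)
    return ds
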