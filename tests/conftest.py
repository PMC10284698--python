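import numpy as np
import pytest

from sterolfilm import rotor
from sterolfilm.trajectory import LayerTrajectory


@pytest.fixture(scope="session")
def chol_run():
    """One moderate cholesterol-preset rotor run shared across tests."""
    cfg = rotor.RotorConfig.preset("cholesterol", seed=7, sweeps=8000,
                                   burn_in=1000, sample_stride=25)
    start = rotor.build_multilayer(cfg)
    traj, stats = rotor.rotor_mc_simulate(start, cfg, log_proposals=2000)
    return cfg, start, traj, stats


def make_trajectory(axes, xy=None, head_z=None, box=(10.0, 10.0, 50.0),
                    times=None, layer=None):
    """Hand-rolled LayerTrajectory from an (F, M, 3) axis array."""
    axes = np.asarray(axes, dtype=float)
    F, M, _ = axes.shape
    axes = axes / np.linalg.norm(axes, axis=-1, keepdims=True)
    if xy is None:
        rng = np.random.default_rng(0)
        xy = np.broadcast_to(rng.uniform(0, box[0], (M, 2)), (F, M, 2)).copy()
    if head_z is None:
        head_z = np.full((F, M), 5.0)
    if times is None:
        times = np.arange(F, dtype=float)
    if layer is None:
        layer = np.zeros(M, dtype=int)
    labels = np.asarray(["test"] * M, dtype=object)
    return LayerTrajectory(box, times, xy, head_z, axes, layer, labels)
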