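import numpy as np
import pytest

from skypad import AnalysisParams, MotionStage, Trajectory
from skypad.synthetic import make_oscillator, make_random_walk, make_staged_track


def make_traj(positions, tf=1.0, particle_id="t"):
    positions = np.asarray(positions, dtype=float)
    return Trajectory(
        particle_id=particle_id,
        frames=np.arange(1, len(positions) + 1),
        positions=positions,
        time_per_frame=tf,
    )


def random_mixed_trajectory(rng, max_frames=200, tf=1.0):
    """A random staged / Brownian / oscillating trajectory for oracle checks."""
    kind = rng.integers(3)
    if kind == 0:
        nf = int(rng.integers(2, max_frames + 1))
        return make_random_walk(
            float(rng.uniform(0.01, 2.0)), nf, tf, seed=int(rng.integers(2**31))
        )
    if kind == 1:
        nf = int(rng.integers(4, max_frames + 1))
        return make_oscillator(
            float(rng.uniform(0.5, 8.0)),
            int(rng.integers(2, 20)),
            nf,
            tf,
            seed=int(rng.integers(2**31)),
            jitter_sd=float(rng.uniform(0.0, 0.5)),
        )
    stages = []
    total = 0
    for _ in range(int(rng.integers(1, 5))):
        dur = int(rng.integers(1, max_frames // 4 + 1))
        total += dur
        mode = ("pause", "processive", "brownian")[rng.integers(3)]
        theta = rng.uniform(0, 2 * np.pi)
        stages.append(
            MotionStage(
                dur,
                mode,
                speed=float(rng.uniform(0.0, 3.0)),
                heading=(float(np.cos(theta)), float(np.sin(theta))),
                step_noise_sd=float(rng.uniform(0.0, 0.6)),
                diffusion=float(rng.uniform(0.0, 1.0)),
            )
        )
    if total < 2:
        stages.append(MotionStage(2, "pause"))
    traj, _ = make_staged_track(stages, tf, seed=int(rng.integers(2**31)))
    return traj


def random_params(rng, tf=1.0, dim=2):
    return AnalysisParams(
        distance_threshold=float(rng.uniform(0.2, 15.0)),
        speed_threshold=float(rng.uniform(0.0, 2.0)),
        time_per_frame=tf,
        dim=dim,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20140219)
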