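"""Synthetic trajectories with known ground truth.

Three motion primitives cover the behaviors the analysis must tell apart:

* *pause* — the particle's true position stays put; only localization jitter
  moves the observed position;
* *processive* — the true position advances at constant speed along a
  heading (the kymograph "sloped line");
* *brownian* — the true position performs a random walk with per-frame
  increment variance ``2 * D * TF`` per axis.

Jitter models localization error: an isotropic Gaussian added to each
observed frame independently (non-cumulative), distinct from Brownian motion
whose displacements accumulate. Staged tracks return per-frame ground-truth
labels so that segmentation recovery can be scored. All generators are pure
functions of their arguments, including the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .io_tracks import Trajectory, ValidationError

__all__ = [
    "MotionStage",
    "make_staged_track",
    "make_random_walk",
    "make_oscillator",
    "make_demo_cohort",
]

PAUSE = "pause"
PROCESSIVE = "processive"
BROWNIAN = "brownian"


@dataclass(frozen=True)
class MotionStage:
    """One phase of a staged track.

    ``speed`` (length/time) and ``heading`` (unit vector) apply to processive
    stages; ``diffusion`` (length^2/time) to brownian stages;
    ``step_noise_sd`` (length) is the per-frame localization jitter of any
    stage.
    """

    duration_frames: int
    mode: str
    speed: float = 0.0
    heading: Optional[Tuple[float, ...]] = None
    step_noise_sd: float = 0.0
    diffusion: float = 0.0

    def __post_init__(self) -> None:
        if self.duration_frames < 1:
            raise ValidationError("duration_frames must be >= 1")
        if self.mode not in (PAUSE, PROCESSIVE, BROWNIAN):
            raise ValidationError(f"unknown stage mode {self.mode!r}")
        if self.speed < 0 or self.step_noise_sd < 0 or self.diffusion < 0:
            raise ValidationError("speed, step_noise_sd and diffusion must be >= 0")
        if self.mode == PROCESSIVE and self.heading is not None:
            norm = math.sqrt(sum(c * c for c in self.heading))
            if not math.isclose(norm, 1.0, rel_tol=1e-9):
                raise ValidationError(f"processive heading must have unit norm, got |h|={norm}")


def _heading_vector(stage: MotionStage, dim: int) -> np.ndarray:
    if stage.heading is None:
        h = np.zeros(dim)
        h[0] = 1.0
        return h
    h = np.asarray(stage.heading, dtype=float)
    if len(h) != dim:
        raise ValidationError(f"heading has {len(h)} components for a {dim}D track")
    return h


def make_staged_track(
    stages: Sequence[MotionStage],
    time_per_frame: float = 1.0,
    dim: int = 2,
    seed: int = 0,
    particle_id: object = "staged",
    length_unit: str = "um",
    time_unit: str = "min",
) -> Tuple[Trajectory, List[str]]:
    """Concatenate motion stages into one trajectory plus per-frame true labels.

    Frame 0 sits at the origin; the step into frame ``t`` follows the stage
    that frame ``t`` belongs to, so ``labels[t]`` is the mode that produced
    the displacement ending at frame ``t`` (``labels[0]`` repeats the first
    stage). Observed positions are the true positions plus the stage's
    localization jitter.
    """
    if not stages:
        raise ValidationError("need at least one stage")
    nf = sum(s.duration_frames for s in stages)
    if nf < 2:
        raise ValidationError("staged track needs at least 2 frames in total")

    stage_of_frame: List[MotionStage] = []
    for stage in stages:
        stage_of_frame.extend([stage] * stage.duration_frames)

    rng = np.random.default_rng(seed)
    base = np.zeros((nf, dim))
    for t in range(1, nf):
        stage = stage_of_frame[t]
        if stage.mode == PROCESSIVE:
            step = stage.speed * time_per_frame * _heading_vector(stage, dim)
        elif stage.mode == BROWNIAN:
            step = rng.normal(0.0, math.sqrt(2.0 * stage.diffusion * time_per_frame), dim)
        else:
            step = np.zeros(dim)
        base[t] = base[t - 1] + step

    noise = np.vstack(
        [rng.normal(0.0, s.step_noise_sd, dim) if s.step_noise_sd > 0 else np.zeros(dim)
         for s in stage_of_frame]
    )
    labels = [stage_of_frame[0].mode] + [s.mode for s in stage_of_frame[1:]]
    traj = Trajectory(
        particle_id=particle_id,
        frames=np.arange(1, nf + 1),
        positions=base + noise,
        time_per_frame=time_per_frame,
        length_unit=length_unit,
        time_unit=time_unit,
    )
    return traj, labels


def make_random_walk(
    diffusion: float,
    n_frames: int,
    time_per_frame: float = 1.0,
    dim: int = 2,
    seed: int = 0,
    particle_id: object = "random_walk",
    length_unit: str = "um",
    time_unit: str = "min",
) -> Trajectory:
    """Brownian track: independent Gaussian increments of variance 2*D*TF per axis."""
    if diffusion < 0:
        raise ValidationError("diffusion must be >= 0")
    if n_frames < 2:
        raise ValidationError("n_frames must be >= 2")
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, math.sqrt(2.0 * diffusion * time_per_frame), (n_frames - 1, dim))
    positions = np.vstack([np.zeros(dim), np.cumsum(steps, axis=0)])
    return Trajectory(
        particle_id=particle_id,
        frames=np.arange(1, n_frames + 1),
        positions=positions,
        time_per_frame=time_per_frame,
        length_unit=length_unit,
        time_unit=time_unit,
    )


def make_oscillator(
    amplitude: float,
    period_frames: int,
    n_frames: int,
    time_per_frame: float = 1.0,
    seed: int = 0,
    jitter_sd: float = 0.0,
    particle_id: object = "oscillator",
    length_unit: str = "um",
    time_unit: str = "min",
) -> Trajectory:
    """Confined sinusoidal oscillation along X, embedded in 2D.

    The particle covers path length every frame yet never strays farther than
    ``amplitude`` from its start — the motion pattern that fools
    instantaneous-speed averaging and that threshold segmentation (with
    DT > 2*amplitude) correctly scores as zero time in motion.
    """
    if not amplitude > 0:
        raise ValidationError("amplitude must be > 0")
    if period_frames < 2:
        raise ValidationError("period_frames must be >= 2")
    if n_frames < 2:
        raise ValidationError("n_frames must be >= 2")
    t = np.arange(n_frames)
    positions = np.column_stack(
        [amplitude * np.sin(2.0 * np.pi * t / period_frames), np.zeros(n_frames)]
    )
    if jitter_sd > 0:
        rng = np.random.default_rng(seed)
        positions = positions + rng.normal(0.0, jitter_sd, positions.shape)
    return Trajectory(
        particle_id=particle_id,
        frames=np.arange(1, n_frames + 1),
        positions=positions,
        time_per_frame=time_per_frame,
        length_unit=length_unit,
        time_unit=time_unit,
    )


def _unit(rng: np.random.Generator, dim: int = 2) -> Tuple[float, ...]:
    v = rng.normal(size=dim)
    return tuple(v / np.linalg.norm(v))


def make_demo_cohort(
    seed: int = 0, time_per_frame: float = 20.0
) -> dict:
    """Three 50-frame particles spanning the canonical behavior classes.

    With TF = 20 min, DT = 10 um and ST = 0.20 um/min these emulate nuclei
    moving in myotubes:

    * ``steady_mover`` — processive throughout at 0.31 um/min;
    * ``fast_pauser`` — two long pauses, moving ~1/3 of the time at 0.71 um/min;
    * ``slow_pauser`` — two long pauses, moving ~1/4 of the time at 0.36 um/min.

    Returns ``{particle_id: (Trajectory, labels)}``. Pause phases carry
    stronger localization jitter (sub-DT oscillation), move phases a small
    one; headings differ between move phases, making the tracks genuinely 2D.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s) & 0x7FFFFFFF for s in ss.generate_state(4)]
    rng = np.random.default_rng(seeds[3])
    pause_jitter, move_jitter = 0.8, 0.3

    def pause(n):
        return MotionStage(n, PAUSE, step_noise_sd=pause_jitter)

    def move(n, v):
        return MotionStage(n, PROCESSIVE, speed=v, heading=_unit(rng), step_noise_sd=move_jitter)

    cohort = {}
    cohort["steady_mover"] = make_staged_track(
        [move(50, 0.31)], time_per_frame, seed=seeds[0], particle_id="steady_mover"
    )
    cohort["fast_pauser"] = make_staged_track(
        [pause(16), move(9, 0.71), pause(16), move(9, 0.71)],
        time_per_frame,
        seed=seeds[1],
        particle_id="fast_pauser",
    )
    cohort["slow_pauser"] = make_staged_track(
        [pause(17), move(8, 0.36), pause(17), move(8, 0.36)],
        time_per_frame,
        seed=seeds[2],
        particle_id="slow_pauser",
    )
    return cohort
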