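"""Threshold-driven trajectory segmentation (the kymograph-equivalent scan).

The scan mimics what a kymograph user does by hand: starting from an anchor
frame ``n``, the net (straight-line) displacement ``d(n, n+i)`` is accumulated
over increasing ``i`` until it exceeds a distance threshold DT — a
displacement the user considers significant, typically the particle size.
The stretch ``[n, n+i]`` becomes one segment, its speed is
``d / (i * TF)``, and the segment is called *moving* if that speed exceeds a
speed threshold ST and *paused* otherwise. The scan then restarts from the
closing frame. A trailing stretch whose displacement never exceeds DT before
the recording ends is emitted as a *residual* segment and counted as
non-moving time: a displacement never confirmed as significant cannot be
called motion.

Because segment speed uses net displacement over elapsed time, an oscillating
particle — which racks up instantaneous speed while going nowhere — yields no
moving segments at all, which is the failure mode of instantaneous-speed
averaging this scan exists to fix.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .io_tracks import ConsistencyError, Trajectory, ValidationError

__all__ = [
    "MOVING",
    "PAUSED",
    "RESIDUAL",
    "AnalysisParams",
    "Segment",
    "ParticleReport",
    "displacement",
    "skypad_scan",
    "classify_segment",
    "motion_summary",
]

MOVING = "moving"
PAUSED = "paused"
RESIDUAL = "residual"


@dataclass(frozen=True)
class AnalysisParams:
    """User-facing thresholds of the scan.

    distance_threshold (DT): minimum net displacement, in the trajectory's
    length unit, for a stretch to close a segment. speed_threshold (ST):
    speed, in length per time, above which a completed segment is classified
    moving. Comparisons are strict ("higher than" DT, "above" ST); ties stay
    on the not-yet-crossed / paused side. ``dim`` is 2 or 3 and must match
    the trajectories analyzed.
    """

    distance_threshold: float
    speed_threshold: float
    time_per_frame: float
    dim: int = 2

    def __post_init__(self) -> None:
        if not self.distance_threshold > 0:
            raise ValidationError("distance_threshold must be > 0")
        if self.speed_threshold < 0:
            raise ValidationError("speed_threshold must be >= 0")
        if not self.time_per_frame > 0:
            raise ValidationError("time_per_frame must be > 0")
        if self.dim not in (2, 3):
            raise ValidationError("dim must be 2 or 3")


@dataclass(frozen=True)
class Segment:
    """One DT-crossing stretch of a trajectory (or the residual tail).

    ``speed == net_displacement / elapsed_time`` by construction; for
    completed (non-residual) segments ``net_displacement`` exceeds the DT of
    the generating scan.
    """

    start_frame: int
    end_frame: int
    net_displacement: float
    elapsed_time: float
    speed: float
    state: str

    def __post_init__(self) -> None:
        if self.end_frame <= self.start_frame:
            raise ValidationError("segment must span at least one frame interval")

    @property
    def span_frames(self) -> int:
        return self.end_frame - self.start_frame


@dataclass
class ParticleReport:
    """Per-particle motion statistics derived from the segmentation.

    ``mean_moving_speed`` is the unweighted mean over moving segments and is
    ``None`` (absent) for a particle with no moving segment — not 0, which
    would bias cohort averages. A *pause* is a maximal run of consecutive
    non-moving segments (paused and residual merged); its duration is the
    summed elapsed time, matching how a kymograph reader counts one pause
    per flat stretch. ``persistence``, ``diffusion_coefficient`` and ``msd``
    are filled by the metrics layer.
    """

    particle_id: object
    mean_moving_speed: Optional[float]
    percent_time_in_motion: float
    n_pauses: int
    pause_durations: List[float]
    total_time: float
    segments: List[Segment] = field(default_factory=list)
    persistence: Optional[float] = None
    diffusion_coefficient: Optional[float] = None
    msd: Optional[object] = None


def _check_params(traj: Trajectory, params: AnalysisParams) -> None:
    if params.dim != traj.dim:
        raise ValidationError(
            f"params.dim={params.dim} but trajectory {traj.particle_id!r} is {traj.dim}D"
        )
    if not math.isclose(params.time_per_frame, traj.time_per_frame, rel_tol=1e-9):
        raise ValidationError(
            f"params.time_per_frame={params.time_per_frame} differs from "
            f"trajectory time_per_frame={traj.time_per_frame}"
        )


def displacement(traj: Trajectory, n: int, i: int) -> float:
    """Euclidean distance between the positions at frames ``n`` and ``n + i``.

    ``n`` is 1-based (the first frame is 1) and ``i >= 1`` the frame
    increment; works for 2D and 3D trajectories alike.
    """
    nf = traj.n_frames
    if i < 1 or n < 1 or n + i > nf:
        raise IndexError(f"frame pair ({n}, {n + i}) out of range for NF={nf}")
    return float(np.linalg.norm(traj.positions[n + i - 1] - traj.positions[n - 1]))


def skypad_scan(traj: Trajectory, params: AnalysisParams) -> List[Segment]:
    """Greedy left-to-right partition of a trajectory into DT-crossing segments.

    Anchored at frame ``n`` (initially 1), the smallest ``i >= 1`` with
    ``displacement(traj, n, i) > DT`` closes a segment ``[n, n+i]``; the scan
    restarts at ``n + i``. If the track ends before DT is crossed, one final
    residual segment covers ``[n, NF]``. The returned segments tile
    ``[1, NF]`` with no gaps or overlaps; completed segments are classified
    moving/paused by :func:`classify_segment`.
    """
    _check_params(traj, params)
    nf = traj.n_frames
    pos = traj.positions
    dt, tf = params.distance_threshold, params.time_per_frame

    segments: List[Segment] = []
    n = 1
    while n < nf:
        dists = np.linalg.norm(pos[n:] - pos[n - 1], axis=1)
        crossed = np.flatnonzero(dists > dt)
        if crossed.size:
            i = int(crossed[0]) + 1
            d = float(dists[crossed[0]])
            seg = Segment(
                start_frame=n,
                end_frame=n + i,
                net_displacement=d,
                elapsed_time=i * tf,
                speed=d / (i * tf),
                state=PAUSED,
            )
            segments.append(classify_segment(seg, params))
            n += i
        else:
            i = nf - n
            d = float(dists[-1])
            segments.append(
                Segment(
                    start_frame=n,
                    end_frame=nf,
                    net_displacement=d,
                    elapsed_time=i * tf,
                    speed=d / (i * tf),
                    state=RESIDUAL,
                )
            )
            n = nf
    return segments


def classify_segment(seg: Segment, params: AnalysisParams) -> Segment:
    """Label a completed segment moving/paused by its speed against ST.

    Moving iff ``speed > ST`` (strict); a speed exactly at ST is paused.
    Residual segments are never classified — they stay residual and count
    as non-moving time.
    """
    if seg.state == RESIDUAL:
        raise ValidationError("residual segments are not classified against ST")
    state = MOVING if seg.speed > params.speed_threshold else PAUSED
    return dataclasses.replace(seg, state=state)


def motion_summary(
    traj: Trajectory, segments: List[Segment], params: AnalysisParams
) -> ParticleReport:
    """Summarize a segmented trajectory into per-particle motion statistics."""
    _check_params(traj, params)
    if not segments:
        raise ConsistencyError("empty segment list cannot tile a trajectory")
    first, last = int(traj.frames[0]), int(traj.frames[-1])
    if segments[0].start_frame != 1 or segments[-1].end_frame != traj.n_frames:
        raise ConsistencyError(
            f"segments cover [{segments[0].start_frame}, {segments[-1].end_frame}] "
            f"but the trajectory spans [1, {traj.n_frames}] (frames {first}..{last})"
        )
    for a, b in zip(segments, segments[1:]):
        if b.start_frame != a.end_frame:
            raise ConsistencyError(
                f"gap or overlap between segments at frames {a.end_frame} vs {b.start_frame}"
            )

    moving = [s for s in segments if s.state == MOVING]
    total_time = traj.total_time
    moving_time = sum(s.elapsed_time for s in moving)
    percent = 100.0 * moving_time / total_time

    pause_durations: List[float] = []
    run = 0.0
    for seg in segments:
        if seg.state == MOVING:
            if run > 0:
                pause_durations.append(run)
            run = 0.0
        else:
            run += seg.elapsed_time
    if run > 0:
        pause_durations.append(run)

    return ParticleReport(
        particle_id=traj.particle_id,
        mean_moving_speed=float(np.mean([s.speed for s in moving])) if moving else None,
        percent_time_in_motion=percent,
        n_pauses=len(pause_durations),
        pause_durations=pause_durations,
        total_time=total_time,
        segments=list(segments),
    )
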