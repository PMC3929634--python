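"""Persistence, MSD, diffusion coefficient and cohort aggregation.

Persistence (the D/T directionality ratio used for polarized cell migration)
is net first-to-last displacement over total path length: 1 for perfectly
directional movement, 0 for a track returning to its start.

The MSD uses the overlapping time-averaged convention: at lag ``n`` frames
all ``NF - n`` start frames contribute one squared displacement, so

    MSD(n*TF) = (1 / (NF - n)) * sum_{j=1..NF-n} |r(j + n) - r(j)|^2 .

A simple diffusion coefficient is obtained by normalizing each lag by
``2 * dim * lag`` and averaging the per-lag coefficients over the first
quarter of the available lags by default — large lags of a time-averaged MSD
are noisy (few independent increments) and would dominate the mean.

Cohort aggregation averages each statistic over the particles for which it is
present (an immobile particle has no moving speed; skipping it beats silently
imputing 0) and reports dispersion as the sample SD for cohorts below 15
particles and the SEM from 15 particles on.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .io_tracks import Trajectory, ValidationError
from .segmentation import AnalysisParams, ParticleReport, motion_summary, skypad_scan

__all__ = [
    "MSDCurve",
    "StatSummary",
    "CohortSummary",
    "persistence",
    "msd_curve",
    "diffusion_coefficient",
    "mean_instantaneous_speed",
    "cohort_summary",
    "analyze_trajectory",
    "analyze_cohort",
]

logger = logging.getLogger(__name__)

#: cohort size at which dispersion switches from SD to SEM
SEM_THRESHOLD = 15

#: statistics aggregated across a cohort, in report-column order
COHORT_STATISTICS = (
    "mean_moving_speed",
    "percent_time_in_motion",
    "n_pauses",
    "mean_pause_duration",
    "persistence",
    "diffusion_coefficient",
)


@dataclass
class MSDCurve:
    """Time-averaged MSD: ``values[k]`` is the MSD at lag ``lags[k] = (k+1)*TF``,
    averaged over ``n_increments[k] = NF - (k+1)`` overlapping displacement pairs."""

    lags: np.ndarray
    values: np.ndarray
    n_increments: np.ndarray

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.n_increments = np.asarray(self.n_increments, dtype=int)
        if not (len(self.lags) == len(self.values) == len(self.n_increments)):
            raise ValidationError("lags, values and n_increments must have equal length")

    def __len__(self) -> int:
        return len(self.lags)


@dataclass(frozen=True)
class StatSummary:
    """Mean, dispersion (SD or SEM per the cohort rule) and effective n of one statistic."""

    mean: float
    dispersion: float
    n: int


@dataclass
class CohortSummary:
    n_particles: int
    stats: dict
    dispersion_kind: str  # "SD" or "SEM"
    mean_msd: Optional[MSDCurve]


def persistence(traj: Trajectory) -> Optional[float]:
    """Net first-to-last displacement over total path length, in [0, 1].

    Returns ``None`` for a fully stationary track (zero path length), where
    the ratio is undefined.
    """
    steps = np.linalg.norm(np.diff(traj.positions, axis=0), axis=1)
    path = float(steps.sum())
    if path == 0.0:
        logger.warning(
            "particle %r is fully stationary; persistence is undefined", traj.particle_id
        )
        return None
    net = float(np.linalg.norm(traj.positions[-1] - traj.positions[0]))
    return net / path


def msd_curve(traj: Trajectory, max_lag: Optional[int] = None) -> MSDCurve:
    """Overlapping time-averaged MSD for lags ``1..max_lag`` frames.

    ``max_lag`` defaults to ``NF - 1`` (every available lag).
    """
    nf = traj.n_frames
    if max_lag is None:
        max_lag = nf - 1
    if not 1 <= max_lag <= nf - 1:
        raise ValidationError(f"max_lag must be in [1, {nf - 1}], got {max_lag}")
    pos = traj.positions
    values = np.empty(max_lag)
    for n in range(1, max_lag + 1):
        disp = pos[n:] - pos[:-n]
        values[n - 1] = np.mean(np.einsum("ij,ij->i", disp, disp))
    lags = np.arange(1, max_lag + 1) * traj.time_per_frame
    n_increments = nf - np.arange(1, max_lag + 1)
    return MSDCurve(lags=lags, values=values, n_increments=n_increments)


def diffusion_coefficient(
    curve: MSDCurve, dim: int, n_lags_used: Optional[int] = None
) -> float:
    """Simple diffusion coefficient from an MSD curve.

    Each lag gives ``D_n = MSD(n*TF) / (2 * dim * n * TF)``; the estimate is
    the unweighted mean of ``D_n`` over the first ``n_lags_used`` lags
    (default: the first quarter of the curve, at least one lag). For purely
    diffusive motion every ``D_n`` estimates the same D; for directed motion
    ``D_n`` grows with the lag, a useful diagnostic that the simple model
    does not apply.
    """
    if len(curve) == 0:
        raise ValidationError("empty MSD curve")
    if dim not in (2, 3):
        raise ValidationError("dim must be 2 or 3")
    if n_lags_used is None:
        n_lags_used = max(1, len(curve) // 4)
    if not 1 <= n_lags_used <= len(curve):
        raise ValidationError(
            f"n_lags_used must be in [1, {len(curve)}], got {n_lags_used}"
        )
    d_n = curve.values[:n_lags_used] / (2.0 * dim * curve.lags[:n_lags_used])
    return float(np.mean(d_n))


def mean_instantaneous_speed(traj: Trajectory) -> float:
    """Average frame-to-frame displacement over TF — the conventional estimate
    the segmentation is compared against (it conflates oscillation with movement)."""
    steps = np.linalg.norm(np.diff(traj.positions, axis=0), axis=1)
    return float(np.mean(steps)) / traj.time_per_frame


# ---------------------------------------------------------------------------
# cohort level


def _particle_stat(report: ParticleReport, name: str) -> Optional[float]:
    if name == "mean_pause_duration":
        return float(np.mean(report.pause_durations)) if report.pause_durations else None
    value = getattr(report, name)
    return None if value is None else float(value)


def cohort_summary(reports: Sequence[ParticleReport]) -> CohortSummary:
    """Aggregate particle reports: per-statistic mean/dispersion and mean MSD.

    Dispersion is the sample SD (n-1 denominator; defined as 0 for a single
    value) when the cohort has fewer than 15 particles, and the SEM
    (SD / sqrt(n), with n the particles contributing to that statistic)
    otherwise. Statistics absent for a particle are skipped, and the
    effective n is reported per statistic.
    """
    if not reports:
        raise ValidationError("cohort_summary needs at least one report")
    n_particles = len(reports)
    kind = "SD" if n_particles < SEM_THRESHOLD else "SEM"

    stats = {}
    for name in COHORT_STATISTICS:
        values = [v for r in reports if (v := _particle_stat(r, name)) is not None]
        if not values:
            continue
        arr = np.asarray(values, dtype=float)
        sd = float(np.std(arr, ddof=1)) if len(arr) > 1 else 0.0
        dispersion = sd if kind == "SD" else sd / math.sqrt(len(arr))
        stats[name] = StatSummary(mean=float(arr.mean()), dispersion=dispersion, n=len(arr))

    curves = [r.msd for r in reports if r.msd is not None]
    mean_msd = None
    if curves:
        n_lags = min(len(c) for c in curves)
        stacked = np.vstack([c.values[:n_lags] for c in curves])
        mean_msd = MSDCurve(
            lags=curves[0].lags[:n_lags],
            values=stacked.mean(axis=0),
            n_increments=np.full(n_lags, len(curves)),
        )

    return CohortSummary(
        n_particles=n_particles, stats=stats, dispersion_kind=kind, mean_msd=mean_msd
    )


# ---------------------------------------------------------------------------
# pipeline convenience


def analyze_trajectory(
    traj: Trajectory,
    params: AnalysisParams,
    compute_persistence: bool = True,
    max_lag: Optional[int] = None,
    n_lags_used: Optional[int] = None,
) -> ParticleReport:
    """Run scan → summary → persistence/MSD/D for one trajectory."""
    segments = skypad_scan(traj, params)
    report = motion_summary(traj, segments, params)
    if compute_persistence:
        report.persistence = persistence(traj)
    report.msd = msd_curve(traj, max_lag)
    report.diffusion_coefficient = diffusion_coefficient(report.msd, traj.dim, n_lags_used)
    return report


def analyze_cohort(
    trajectories: Sequence[Trajectory],
    params: AnalysisParams,
    compute_persistence: bool = True,
    max_lag: Optional[int] = None,
    n_lags_used: Optional[int] = None,
) -> tuple[List[ParticleReport], CohortSummary]:
    """Analyze every trajectory and aggregate the cohort."""
    reports = [
        analyze_trajectory(t, params, compute_persistence, max_lag, n_lags_used)
        for t in trajectories
    ]
    return reports, cohort_summary(reports)
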