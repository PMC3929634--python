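"""Reading and writing particle-track tables.

Input is the stacked-column layout produced by most tracking workflows: a
header row, then one row per frame with the frame number and X, Y (optionally
Z) coordinates; several particles are concatenated vertically in the same
columns, each contributing exactly ``frames_per_particle`` rows. Columns may
be addressed either by header name or by spreadsheet letter (``A`` is the
first column), and pixel coordinates are converted to physical units through
a user-supplied distance-per-pixel ratio.

Output writers emit plain CSV tables plus a machine-readable JSON report;
presentation concerns (cell colouring, in-sheet charts) are deliberately out
of scope.
"""

from __future__ import annotations

import dataclasses
import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Optional, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .metrics import CohortSummary
    from .segmentation import ParticleReport, Segment

__all__ = [
    "SkyPadError",
    "FormatError",
    "ParseError",
    "ValidationError",
    "TruncationError",
    "ConsistencyError",
    "TrackTableSpec",
    "Trajectory",
    "read_tracks",
    "write_stacked_tracks",
    "write_segments",
    "write_particle_reports",
]


class SkyPadError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(SkyPadError):
    """The file layout does not match the declared table spec (e.g. missing column)."""


class ParseError(SkyPadError):
    """A cell that should be numeric could not be parsed."""


class ValidationError(SkyPadError):
    """Values parsed fine but violate an invariant (frame numbering, parameter range...)."""


class TruncationError(ValidationError):
    """Fewer data rows than frames_per_particle x n_particles."""


class ConsistencyError(SkyPadError):
    """Derived objects disagree with each other (e.g. segments do not tile a track)."""


_LETTER_RE = re.compile(r"^[A-Za-z]{1,3}$")


def column_letter_to_index(letter: str) -> int:
    """Convert a spreadsheet column letter (``A``, ``B``, ... ``AA``) to a 0-based index."""
    if not _LETTER_RE.match(letter):
        raise FormatError(f"not a spreadsheet column letter: {letter!r}")
    idx = 0
    for ch in letter.upper():
        idx = idx * 26 + (ord(ch) - ord("A") + 1)
    return idx - 1


@dataclass(frozen=True)
class TrackTableSpec:
    """Declares how a stacked track table is laid out and scaled.

    Parameters
    ----------
    frames_per_particle:
        Number of frames (rows) per particle, NF. Every particle in the file
        must have exactly this many rows, numbered 1..NF.
    n_particles:
        Number of particles stacked in the file.
    frame_column, x_column, y_column, z_column:
        Column identifiers, either spreadsheet letters (``"A"``) or header
        names. ``z_column`` enables 3D trajectories.
    pixel_ratio:
        Physical length per pixel; coordinates are multiplied by this on read.
        Use 1.0 when coordinates are already in physical units.
    time_per_frame:
        Duration between consecutive frames (TF), in ``time_unit``.
    sheet_name:
        Worksheet to read from an ``.xlsx`` file; the first sheet if omitted.
    """

    frames_per_particle: int
    n_particles: int
    frame_column: str = "A"
    x_column: str = "B"
    y_column: str = "C"
    z_column: Optional[str] = None
    pixel_ratio: float = 1.0
    length_unit: str = "um"
    time_unit: str = "min"
    time_per_frame: float = 1.0
    sheet_name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.frames_per_particle < 2:
            raise ValidationError("frames_per_particle must be >= 2")
        if self.n_particles < 1:
            raise ValidationError("n_particles must be >= 1")
        if not self.pixel_ratio > 0:
            raise ValidationError("pixel_ratio must be > 0")
        if not self.time_per_frame > 0:
            raise ValidationError("time_per_frame must be > 0")
        cols = [self.frame_column, self.x_column, self.y_column]
        if self.z_column is not None:
            cols.append(self.z_column)
        if len(set(cols)) != len(cols):
            raise ValidationError(f"column identifiers must be pairwise distinct, got {cols}")

    @property
    def dim(self) -> int:
        return 3 if self.z_column is not None else 2


@dataclass
class Trajectory:
    """One particle's ordered positions.

    ``frames`` are consecutive integers (conventionally 1..NF); ``positions``
    is an (NF, dim) array in ``length_unit``. ``time_per_frame`` (TF) is the
    duration between consecutive frames in ``time_unit``.
    """

    particle_id: object
    frames: np.ndarray
    positions: np.ndarray
    time_per_frame: float
    length_unit: str = "um"
    time_unit: str = "min"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] not in (2, 3):
            raise ValidationError(
                f"positions must be an (NF, 2) or (NF, 3) array, got shape {self.positions.shape}"
            )
        if len(self.frames) != len(self.positions):
            raise ValidationError("frames and positions must have the same length")
        if len(self.frames) < 2:
            raise ValidationError("a trajectory needs at least 2 frames")
        if not np.all(np.diff(self.frames) == 1):
            raise ValidationError(
                f"frames of particle {self.particle_id!r} must be consecutive integers"
            )
        if not np.all(np.isfinite(self.positions)):
            raise ValidationError(f"particle {self.particle_id!r} has non-finite coordinates")
        if not self.time_per_frame > 0:
            raise ValidationError("time_per_frame must be > 0")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def dim(self) -> int:
        return self.positions.shape[1]

    @property
    def total_time(self) -> float:
        """Track duration, (NF - 1) * TF."""
        return (self.n_frames - 1) * self.time_per_frame


# ---------------------------------------------------------------------------
# reading


def _load_table(path: Path, sheet_name: Optional[str]) -> pd.DataFrame:
    suffix = path.suffix.lower()
    if suffix in (".xlsx", ".xlsm", ".xls"):
        return pd.read_excel(path, sheet_name=sheet_name if sheet_name else 0, header=0)
    sep = "\t" if suffix in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep, header=0, skip_blank_lines=False)


def _resolve_column(df: pd.DataFrame, ident: str, role: str) -> pd.Series:
    """Resolve a column identifier: header names take precedence over letters."""
    if ident in df.columns:
        return df[ident]
    if _LETTER_RE.match(str(ident)):
        idx = column_letter_to_index(str(ident))
        if idx < df.shape[1]:
            return df.iloc[:, idx]
    raise FormatError(
        f"{role} column {ident!r} not found: no such header and no column at that letter "
        f"(file has {df.shape[1]} columns: {list(df.columns)})"
    )


def _numeric(series: pd.Series, role: str) -> np.ndarray:
    values = pd.to_numeric(series, errors="coerce")
    bad = values.isna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(
            f"non-numeric {role} value {series.iloc[row]!r} at data row {row + 1} "
            f"(sheet line {row + 2})"
        )
    return values.to_numpy(dtype=float)


def read_tracks(path, spec: TrackTableSpec) -> list[Trajectory]:
    """Read stacked particle tracks from a CSV/TSV/XLSX file.

    The header row is skipped (the data region starts at sheet line 2);
    particle ``k`` (1-based) is built from data rows
    ``(k-1)*NF + 1 .. k*NF``. Coordinates are multiplied by
    ``spec.pixel_ratio``. Frame numbers within each particle must be exactly
    1..NF.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = _load_table(path, spec.sheet_name)

    frame_s = _resolve_column(df, spec.frame_column, "frame")
    coord_series = [
        _resolve_column(df, spec.x_column, "X"),
        _resolve_column(df, spec.y_column, "Y"),
    ]
    if spec.z_column is not None:
        coord_series.append(_resolve_column(df, spec.z_column, "Z"))

    nf, npart = spec.frames_per_particle, spec.n_particles
    needed = nf * npart
    # trailing all-empty rows (common in hand-edited sheets) are not data
    empty = (frame_s.isna() & pd.concat(coord_series, axis=1).isna().all(axis=1)).to_numpy()
    n_rows = 0 if empty.all() else int(np.flatnonzero(~empty)[-1]) + 1
    if n_rows < needed:
        raise TruncationError(
            f"need {needed} data rows ({npart} particles x {nf} frames), found {n_rows}"
        )

    frames_all = _numeric(frame_s.iloc[:needed], "frame")
    coords_all = np.column_stack(
        [_numeric(s.iloc[:needed], role) for s, role in zip(coord_series, "XYZ")]
    )
    coords_all = coords_all * spec.pixel_ratio

    expected = np.arange(1, nf + 1)
    trajectories = []
    for k in range(npart):
        sl = slice(k * nf, (k + 1) * nf)
        frames = frames_all[sl]
        if not np.array_equal(frames, expected):
            raise ValidationError(
                f"particle {k + 1}: frame numbers must run 1..{nf} consecutively "
                f"(data rows {k * nf + 1}..{(k + 1) * nf})"
            )
        trajectories.append(
            Trajectory(
                particle_id=k + 1,
                frames=expected.copy(),
                positions=coords_all[sl],
                time_per_frame=spec.time_per_frame,
                length_unit=spec.length_unit,
                time_unit=spec.time_unit,
            )
        )
    return trajectories


# ---------------------------------------------------------------------------
# writing


def write_stacked_tracks(trajectories: Sequence[Trajectory], path, pixel_ratio: float = 1.0) -> None:
    """Write trajectories back to the stacked layout (inverse of :func:`read_tracks`).

    Coordinates are divided by ``pixel_ratio`` so that reading the file with
    the same ratio reproduces the input positions.
    """
    path = Path(path)
    frames = []
    for traj in trajectories:
        cols = {"frame": traj.frames}
        for axis, name in zip(range(traj.dim), ("x", "y", "z")):
            cols[name] = traj.positions[:, axis] / pixel_ratio
        cols["particle"] = np.repeat(traj.particle_id, traj.n_frames)
        frames.append(pd.DataFrame(cols))
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    pd.concat(frames, ignore_index=True).to_csv(path, sep=sep, index=False)


def write_segments(segments_by_particle: dict, path) -> None:
    """Write one row per segment: id, frames, displacement, time, speed, state."""
    rows = []
    for pid, segments in segments_by_particle.items():
        for seg in segments:
            rows.append(
                {
                    "particle_id": pid,
                    "start_frame": seg.start_frame,
                    "end_frame": seg.end_frame,
                    "net_displacement": seg.net_displacement,
                    "elapsed_time": seg.elapsed_time,
                    "speed": seg.speed,
                    "state": seg.state,
                }
            )
    columns = [
        "particle_id",
        "start_frame",
        "end_frame",
        "net_displacement",
        "elapsed_time",
        "speed",
        "state",
    ]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


_PARTICLE_COLUMNS = [
    "particle_id",
    "mean_moving_speed",
    "percent_time_in_motion",
    "n_pauses",
    "mean_pause_duration",
    "persistence",
    "diffusion_coefficient",
]


def _report_row(report: "ParticleReport") -> dict:
    pauses = report.pause_durations
    return {
        "particle_id": report.particle_id,
        "mean_moving_speed": report.mean_moving_speed,
        "percent_time_in_motion": report.percent_time_in_motion,
        "n_pauses": report.n_pauses,
        "mean_pause_duration": float(np.mean(pauses)) if pauses else None,
        "persistence": report.persistence,
        "diffusion_coefficient": report.diffusion_coefficient,
    }


def write_particle_reports(
    reports: Sequence["ParticleReport"],
    cohort: "CohortSummary",
    stem,
    params: Optional[dict] = None,
) -> list[Path]:
    """Write per-particle statistics, the MSD tables and a JSON report.

    Produces ``<stem>_particles.csv`` (one row per particle followed by a
    cohort block with mean, dispersion per the SD/SEM rule and effective n),
    ``<stem>_msd.csv`` (long-format per-particle and cohort-average MSD) and
    ``<stem>_report.json`` (everything, machine-readable, with the analysis
    parameters echoed for re-use). Absent statistics (e.g. moving speed of an
    immobile particle) are written as empty cells / ``null``, never as 0.

    Returns the list of paths written.
    """
    if not reports:
        raise ValidationError("need at least one particle report")
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)

    rows = [_report_row(r) for r in reports]
    block = []
    for label, attr in (("cohort_mean", "mean"), (f"cohort_{cohort.dispersion_kind}", "dispersion"), ("cohort_n", "n")):
        row = {"particle_id": label}
        for col in _PARTICLE_COLUMNS[1:]:
            stat = cohort.stats.get(col)
            row[col] = getattr(stat, attr) if stat is not None else None
        block.append(row)
    particles_df = pd.DataFrame(rows + block, columns=_PARTICLE_COLUMNS)
    particles_path = Path(f"{stem}_particles.csv")
    particles_df.to_csv(particles_path, index=False)

    msd_rows = []
    for r in reports:
        if r.msd is None:
            continue
        for lag, val, n_inc in zip(r.msd.lags, r.msd.values, r.msd.n_increments):
            msd_rows.append(
                {"particle_id": r.particle_id, "lag": lag, "msd": val, "n_increments": n_inc}
            )
    if cohort.mean_msd is not None:
        for lag, val, n_inc in zip(
            cohort.mean_msd.lags, cohort.mean_msd.values, cohort.mean_msd.n_increments
        ):
            msd_rows.append(
                {"particle_id": "cohort_mean", "lag": lag, "msd": val, "n_increments": n_inc}
            )
    msd_path = Path(f"{stem}_msd.csv")
    pd.DataFrame(msd_rows, columns=["particle_id", "lag", "msd", "n_increments"]).to_csv(
        msd_path, index=False
    )

    payload = {
        "parameters": params or {},
        "n_particles": cohort.n_particles,
        "dispersion_kind": cohort.dispersion_kind,
        "particles": [
            {
                **_report_row(r),
                "total_time": r.total_time,
                "pause_durations": list(r.pause_durations),
                "segments": [dataclasses.asdict(s) for s in r.segments],
            }
            for r in reports
        ],
        "cohort": {
            name: {"mean": stat.mean, "dispersion": stat.dispersion, "n": stat.n}
            for name, stat in cohort.stats.items()
        },
        "mean_msd": None
        if cohort.mean_msd is None
        else {
            "lags": cohort.mean_msd.lags.tolist(),
            "values": cohort.mean_msd.values.tolist(),
            "n_increments": cohort.mean_msd.n_increments.tolist(),
        },
    }
    json_path = Path(f"{stem}_report.json")
    json_path.write_text(json.dumps(payload, indent=2, allow_nan=True))
    return [particles_path, msd_path, json_path]
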