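import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from skypad import (
    MOVING,
    PAUSED,
    RESIDUAL,
    AnalysisParams,
    ConsistencyError,
    Segment,
    ValidationError,
    classify_segment,
    displacement,
    motion_summary,
    skypad_scan,
)
from skypad.synthetic import MotionStage, make_staged_track

from conftest import make_traj, random_mixed_trajectory, random_params
from reference_impl import brute_scan, brute_summary


def params(dt=1.0, st=0.5, tf=1.0, dim=2):
    return AnalysisParams(dt, st, tf, dim)


# ---------------------------------------------------------------------------
# displacement


def test_displacement_pythagorean():
    traj = make_traj([[0, 0], [3, 4]])
    assert displacement(traj, 1, 1) == pytest.approx(5.0)


def test_displacement_identical_positions_is_zero():
    traj = make_traj([[2, 7], [2, 7]])
    assert displacement(traj, 1, 1) == 0.0


def test_displacement_3d():
    traj = make_traj([[0, 0, 0], [1, 2, 2]])
    assert displacement(traj, 1, 1) == pytest.approx(3.0)


@pytest.mark.parametrize("n,i", [(0, 1), (1, 0), (2, 1), (1, 2)])
def test_displacement_out_of_range(n, i):
    traj = make_traj([[0, 0], [1, 1]])
    with pytest.raises(IndexError):
        displacement(traj, n, i)


# ---------------------------------------------------------------------------
# scan


def test_stationary_track_is_one_residual_segment():
    traj = make_traj(np.zeros((30, 2)))
    segs = skypad_scan(traj, params(dt=0.5))
    assert len(segs) == 1
    (seg,) = segs
    assert seg.state == RESIDUAL
    assert (seg.start_frame, seg.end_frame) == (1, 30)


def test_constant_velocity_closed_form():
    """1 unit/frame with DT=9.5: crossings every 10 frames, then a residual tail."""
    traj = make_traj(np.column_stack([np.arange(50.0), np.zeros(50)]))
    segs = skypad_scan(traj, params(dt=9.5, st=0.5))
    bounds = [(s.start_frame, s.end_frame) for s in segs]
    assert bounds == [(1, 11), (11, 21), (21, 31), (31, 41), (41, 50)]
    for seg in segs[:-1]:
        assert seg.net_displacement == pytest.approx(10.0)
        assert seg.speed == pytest.approx(1.0)
        assert seg.state == MOVING
    assert segs[-1].state == RESIDUAL
    assert segs[-1].net_displacement == pytest.approx(9.0)


def test_scan_requires_two_frames():
    with pytest.raises(ValidationError):
        make_traj([[0.0, 0.0]])


def test_scan_rejects_dim_mismatch():
    traj = make_traj([[0, 0, 0], [5, 0, 0]])
    with pytest.raises(ValidationError, match="3D"):
        skypad_scan(traj, params(dim=2))


# ---------------------------------------------------------------------------
# classification


@pytest.mark.parametrize(
    "speed,st,expected",
    [
        (0.51, 0.20, MOVING),  # the worked nucleus: 0.51 um/min against ST 0.20
        (0.20, 0.20, PAUSED),  # tie goes to paused
        (0.1999, 0.20, PAUSED),
        (1e-9, 0.0, MOVING),  # ST=0: any positive speed moves
    ],
)
def test_classify_against_speed_threshold(speed, st, expected):
    seg = Segment(1, 2, speed * 1.0, 1.0, speed, PAUSED)
    assert classify_segment(seg, params(st=st)).state == expected


def test_residual_segments_are_not_classified():
    seg = Segment(1, 5, 0.1, 4.0, 0.025, RESIDUAL)
    with pytest.raises(ValidationError):
        classify_segment(seg, params())


# ---------------------------------------------------------------------------
# summary


def test_stationary_summary():
    traj = make_traj(np.zeros((30, 2)), tf=2.0)
    p = params(dt=0.5, tf=2.0)
    report = motion_summary(traj, skypad_scan(traj, p), p)
    assert report.percent_time_in_motion == 0.0
    assert report.mean_moving_speed is None
    assert report.n_pauses == 1
    assert report.pause_durations == [pytest.approx(58.0)]
    assert report.total_time == pytest.approx(58.0)


def test_staged_track_matches_brute_force_reference():
    """Pause 20 / move 20 / pause 10 track agrees with the naive reference scan."""
    stages = [
        MotionStage(20, "pause", step_noise_sd=0.2),
        MotionStage(20, "processive", speed=1.5, heading=(0.6, 0.8), step_noise_sd=0.2),
        MotionStage(10, "pause", step_noise_sd=0.2),
    ]
    traj, _ = make_staged_track(stages, time_per_frame=1.0, seed=42)
    p = params(dt=3.0, st=0.5)
    segs = skypad_scan(traj, p)
    ref = brute_scan(traj.positions.tolist(), p.distance_threshold, p.speed_threshold,
                     p.time_per_frame)
    assert [(s.start_frame, s.end_frame, s.state) for s in segs] == [
        (r[0], r[1], r[5]) for r in ref
    ]
    report = motion_summary(traj, segs, p)
    ref_speed, ref_pct, ref_npause, ref_pauses = brute_summary(ref, traj.n_frames, 1.0)
    assert report.mean_moving_speed == pytest.approx(ref_speed)
    assert report.percent_time_in_motion == pytest.approx(ref_pct)
    assert report.n_pauses == ref_npause
    assert report.pause_durations == pytest.approx(ref_pauses)


def test_summary_rejects_non_tiling_segments():
    traj = make_traj(np.column_stack([np.arange(10.0), np.zeros(10)]))
    p = params(dt=2.5)
    segs = skypad_scan(traj, p)
    assert len(segs) >= 3
    with pytest.raises(ConsistencyError):
        motion_summary(traj, segs[1:], p)
    with pytest.raises(ConsistencyError):  # interior gap
        motion_summary(traj, [segs[0]] + segs[2:], p)
    with pytest.raises(ConsistencyError):
        motion_summary(traj, [], p)


def test_time_accounting_is_exhaustive():
    """Moving + paused + residual time always equals (NF-1)*TF."""
    rng = np.random.default_rng(7)
    for _ in range(20):
        traj = random_mixed_trajectory(rng, max_frames=80)
        p = random_params(rng)
        segs = skypad_scan(traj, p)
        report = motion_summary(traj, segs, p)
        assert sum(s.elapsed_time for s in segs) == pytest.approx(report.total_time)
        moving_t = sum(s.elapsed_time for s in segs if s.state == MOVING)
        assert report.percent_time_in_motion == pytest.approx(100 * moving_t / report.total_time)


# ---------------------------------------------------------------------------
# properties


@settings(max_examples=100, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**31 - 1))
def test_scan_properties_random_tracks(seed):
    """Tiling, oracle equivalence and completed-displacement bound on random tracks."""
    rng = np.random.default_rng(seed)
    traj = random_mixed_trajectory(rng, max_frames=60)
    p = random_params(rng)
    segs = skypad_scan(traj, p)
    # tiling: spans sum to NF-1, contiguous
    assert segs[0].start_frame == 1 and segs[-1].end_frame == traj.n_frames
    assert all(a.end_frame == b.start_frame for a, b in zip(segs, segs[1:]))
    assert sum(s.span_frames for s in segs) == traj.n_frames - 1
    # completed segments crossed DT; only a trailing residual may not
    for s in segs[:-1]:
        assert s.state in (MOVING, PAUSED) and s.net_displacement > p.distance_threshold
        assert s.speed == pytest.approx(s.net_displacement / s.elapsed_time)
    if segs[-1].state == RESIDUAL:
        assert segs[-1].net_displacement <= p.distance_threshold
    # oracle equivalence
    ref = brute_scan(traj.positions.tolist(), p.distance_threshold, p.speed_threshold,
                     p.time_per_frame)
    assert [(s.start_frame, s.end_frame, s.state) for s in segs] == [
        (r[0], r[1], r[5]) for r in ref
    ]


@settings(max_examples=60, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**31 - 1))
def test_distance_threshold_monotonicity(seed):
    """Raising DT never increases the number of completed segments."""
    rng = np.random.default_rng(seed)
    traj = random_mixed_trajectory(rng, max_frames=60)
    dts = sorted(rng.uniform(0.2, 15.0, size=3))
    counts = []
    for dt in dts:
        segs = skypad_scan(traj, params(dt=dt))
        counts.append(sum(1 for s in segs if s.state != RESIDUAL))
    assert counts == sorted(counts, reverse=True)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**31 - 1))
def test_speed_threshold_monotonicity(seed):
    """Raising ST never increases percent time in motion."""
    rng = np.random.default_rng(seed)
    traj = random_mixed_trajectory(rng, max_frames=60)
    dt = float(rng.uniform(0.2, 10.0))
    pcts = []
    for stv in sorted(rng.uniform(0.0, 2.0, size=3)):
        p = params(dt=dt, st=stv)
        pcts.append(motion_summary(traj, skypad_scan(traj, p), p).percent_time_in_motion)
    assert pcts == sorted(pcts, reverse=True)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**31 - 1), angle=st.floats(0, 2 * np.pi))
def test_rigid_motion_invariance(seed, angle):
    """Rotation + translation leave displacements, speeds and states unchanged."""
    rng = np.random.default_rng(seed)
    traj = random_mixed_trajectory(rng, max_frames=60)
    p = random_params(rng)
    rot = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
    shift = rng.uniform(-50, 50, size=2)
    moved = make_traj(traj.positions @ rot.T + shift, tf=traj.time_per_frame)
    a, b = skypad_scan(traj, p), skypad_scan(moved, p)
    assert len(a) == len(b)
    for sa, sb in zip(a, b):
        assert (sa.start_frame, sa.end_frame, sa.state) == (sb.start_frame, sb.end_frame, sb.state)
        assert sb.net_displacement == pytest.approx(sa.net_displacement, rel=1e-9)
        assert sb.speed == pytest.approx(sa.speed, rel=1e-9)


def test_staged_recovery_within_quantization_bound():
    """Percent time in motion lands within the DT boundary-quantization bound."""
    v, dt, tf = 2.0, 4.0, 1.0
    stages = [
        MotionStage(20, "pause", step_noise_sd=0.05),
        MotionStage(20, "processive", speed=v, heading=(1.0, 0.0), step_noise_sd=0.05),
        MotionStage(10, "pause", step_noise_sd=0.05),
    ]
    traj, labels = make_staged_track(stages, tf, seed=5)
    p = params(dt=dt, st=v / 2, tf=tf)
    report = motion_summary(traj, skypad_scan(traj, p), p)
    truth_pct = 100.0 * labels.count("processive") / (traj.n_frames - 1)
    bound = 100.0 * (2 * dt / (v * report.total_time))
    assert abs(report.percent_time_in_motion - truth_pct) <= bound + 1e-9
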