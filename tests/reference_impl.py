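"""Independent brute-force reference implementations.

Written directly from the prose description of the method as plain Python
loops, deliberately sharing no code with the package: the scan increments i
until the straight-line distance from the anchor exceeds DT, computes the
speed over that stretch, classifies it against ST, and restarts from the
closing frame; summaries, persistence and MSD are computed the same naive
way. Used as oracles.
"""

import math


def brute_distance(positions, a, b):
    """Euclidean distance between 0-based rows a and b, any dimension."""
    return math.sqrt(sum((positions[b][k] - positions[a][k]) ** 2 for k in range(len(positions[a]))))


def brute_scan(positions, dt, st, tf):
    """Return a list of (start, end, net, time, speed, state), frames 1-based."""
    nf = len(positions)
    segments = []
    n = 1
    while n < nf:
        hit = None
        for i in range(1, nf - n + 1):
            d = brute_distance(positions, n - 1, n + i - 1)
            if d > dt:
                hit = (i, d)
                break
        if hit is None:
            i = nf - n
            d = brute_distance(positions, n - 1, nf - 1)
            speed = d / (i * tf)
            segments.append((n, nf, d, i * tf, speed, "residual"))
            n = nf
        else:
            i, d = hit
            speed = d / (i * tf)
            state = "moving" if speed > st else "paused"
            segments.append((n, n + i, d, i * tf, speed, state))
            n = n + i
    return segments


def brute_summary(segments, nf, tf):
    """(mean moving speed or None, % time in motion, n_pauses, pause durations)."""
    total = (nf - 1) * tf
    moving = [s for s in segments if s[5] == "moving"]
    mean_speed = sum(s[4] for s in moving) / len(moving) if moving else None
    percent = 100.0 * sum(s[3] for s in moving) / total
    pauses = []
    run = 0.0
    for s in segments:
        if s[5] == "moving":
            if run > 0:
                pauses.append(run)
            run = 0.0
        else:
            run += s[3]
    if run > 0:
        pauses.append(run)
    return mean_speed, percent, len(pauses), pauses


def brute_persistence(positions):
    path = sum(
        brute_distance(positions, j, j + 1) for j in range(len(positions) - 1)
    )
    if path == 0:
        return None
    return brute_distance(positions, 0, len(positions) - 1) / path


def brute_msd(positions, tf, max_lag):
    """[(lag_time, msd, n_increments)] with every available overlapping pair."""
    nf = len(positions)
    out = []
    for n in range(1, max_lag + 1):
        total = 0.0
        count = 0
        for j in range(nf - n):
            total += brute_distance(positions, j, j + n) ** 2
            count += 1
        out.append((n * tf, total / count, count))
    return out
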