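# Methods

## The scan

A trajectory is an ordered list of positions `r(1..NF)` sampled every TF
time units. The scan greedily partitions `[1, NF]`: anchored at frame `n`
(initially 1), it takes the smallest `i ≥ 1` with `|r(n+i) − r(n)| > DT`
(strictly greater; a displacement exactly at DT has not crossed), closes the
segment `[n, n+i]`, and restarts at `n+i`. Segment speed is net
displacement over elapsed time, `d/(i·TF)` — net, not summed path length,
because the same straight-line distance defines the crossing itself, and
because that is the quantity a kymograph line slope measures. A segment is
*moving* iff its speed is strictly above ST; a tie is paused. If the track
ends before DT is crossed, the remainder `[n, NF]` is a *residual* segment:
its displacement was never confirmed significant, so it counts as
non-moving time (this is why a particle that moves steadily for the whole
recording scores ~98%, not 100%, time in motion — the tail quantization).
Segments always tile `[1, NF]` with no gaps or overlaps; this is asserted
before any summary is computed.

Assumptions: frames are complete and evenly spaced (tracking gaps are
rejected at read time rather than interpolated — interpolation would
fabricate displacement exactly where the method is most sensitive), and DT
exceeds the oscillation/localization amplitude of a genuinely stationary
particle. DT should be chosen like the kymograph user's judgement of a
significant displacement, typically the particle diameter; ST as the
largest speed observed during known pauses.

Derived statistics:

- **mean moving speed** — unweighted mean of moving-segment speeds. This
  mirrors averaging kymograph line slopes; a time-weighted mean coincides
  with it when segment durations are equal and differs little otherwise.
  With no moving segment the value is *absent* (`None`/empty cell), never
  0: zero-imputation would drag cohort averages of motile populations down
  by their immobile members.
- **percent time in motion** — summed moving-segment time over `(NF−1)·TF`.
- **pauses** — a pause is a maximal run of consecutive non-moving segments
  (paused and residual merged), its duration their summed time; a
  kymograph reader counts one pause per flat stretch regardless of how
  many sub-threshold crossings compose it.

## Persistence, MSD, diffusion coefficient

Persistence is net first-to-last displacement divided by total path length
(the D/T directionality ratio): 1 for straight-line movement, 0 for a
closed loop, undefined (absent) for a fully stationary track.

The MSD uses the overlapping time-averaged convention: at lag `n` frames,
all `NF − n` start frames contribute, `MSD(n·TF) = mean_j |r(j+n) − r(j)|²`.
Overlapping increments are the field standard and use every measured pair;
the increment count is reported per lag.

The simple diffusion coefficient normalizes each lag by the free-diffusion
law, `D_n = MSD(n·TF) / (2·dim·n·TF)`, and averages `D_n` over the first
quarter of the available lags by default (`n_lags_used` exposes the
choice). Large lags of a time-averaged MSD rest on few independent
increments and are disproportionately noisy; a short-lag average keeps the
estimator's variance small while remaining unbiased for Brownian motion.
For directed motion `D_n` grows linearly with lag — a diagnostic that the
diffusive model does not apply, not a usable D. For the parameter-recovery
checks we use lags 1–10 of `NF = 10⁴` tracks, where the estimator's
relative error is a few percent per replicate.

Cohort aggregation averages each statistic over the particles for which it
is present and reports the effective n per statistic. Dispersion follows
the spreadsheet rule the field uses: sample SD (n−1 denominator, 0 for a
singleton) below 15 particles, SEM (`SD/√n`, n the contributing particles)
from 15 on. The cohort MSD is the lag-wise mean of the per-particle curves.

## Synthetic tracks and what they do (not) show

The generators compose three primitives: *pause* (true position fixed),
*processive* (constant speed along a heading), and *brownian* (increment
variance `2·D·TF` per axis). Localization error is modelled as isotropic
Gaussian jitter added independently to each observed frame —
non-cumulative, which is what distinguishes detection noise from Brownian
motion. A confined sinusoidal oscillator reproduces the failure mode the
scan exists to fix. Staged tracks return per-frame ground-truth labels so
recovery can be scored; all generators are pure functions of their
arguments including the seed.

The demo cohort (NF = 50, TF = 20 min, analyzed at DT = 10 um,
ST = 0.20 um/min — the working conditions for nuclei in myotubes, DT being
roughly a nuclear diameter) contains a steady mover at 0.31 um/min, a fast
pauser (0.71 um/min, moving ~1/3 of the time) and a slow pauser
(0.36 um/min, ~1/4 of the time), with pause-phase jitter of 0.8 um and
move-phase jitter of 0.3 um — sub-micron localization error plus visible
in-place wobble, both far below DT.

What passing these tests does *not* show: real tracks have gaps, uneven
exposure times, drift, and noise that is neither Gaussian nor isotropic;
real pauses are not perfectly stationary and real runs not perfectly
straight. The synthetic results validate the algorithmic machinery and its
statistical behavior, not tracker quality or threshold choice on any
particular dataset.

## Numerical choices and edge cases

- Threshold comparisons are strict (`> DT`, `> ST`); ties deterministically
  fall to the not-yet-crossed / paused side.
- The scan is vectorized per anchor (one distance evaluation against all
  later frames), so a track of any practical length analyzes in
  milliseconds; an independent pure-loop reference implementation is kept
  in the test suite and the two are compared exactly on thousands of random
  tracks.
- Trajectories must have ≥ 2 frames, finite coordinates and consecutive
  frame numbers (1..NF within each particle of a stacked file); violations
  raise typed errors naming the particle and row.
- `time_per_frame` appears in both the table spec and the analysis
  parameters; they are cross-checked and a mismatch is an error rather than
  a silent preference.
- Speeds are stored as `net_displacement / elapsed_time` computed once at
  segment construction, so the identity holds exactly in every output.
- Output CSVs use full float repr, so write→read round-trips are exact to
  well beyond 10 significant digits.

## Problem sizes

The test suite checks oracle equivalence on 1000 random mixed trajectories
(NF ≤ 200), property suites at 200 random cases each (NF ≤ 60), diffusion
recovery on 20 replicates of NF = 10⁴, and an increment-variance check at
NF = 10⁵; the whole suite runs in a few seconds. These sizes give the
Monte-Carlo assertions comfortable statistical margins (the D-recovery
tolerance of 15% per replicate sits more than five standard errors from the
estimator's spread at these sizes).

## Known limitations

- Missing frames are rejected, not interpolated; pre-clean tracks with gaps.
- The simple diffusion coefficient assumes free diffusion; no anomalous
  exponent, confinement or velocity-autocorrelation fitting is attempted.
- Mean moving speed is unweighted across segments; cohorts of particles
  with very heterogeneous segment durations may prefer a time-weighted
  variant, which can be computed from the emitted segment table.
- The scan's greedy left-to-right partition is order-dependent by design
  (it mimics the kymograph reading direction); reversing a track can yield
  different segment boundaries within the DT quantization.
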