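# Methods

This note documents the models, conventions and numerical choices behind
`skategears`, in the order the pipeline runs, and what the synthetic data
do and do not establish.

## Synthetic trajectory generator

No public motion-capture or dGNSS recordings of ski skating exist, so all
testing rests on a generator with exact ground truth. Each technique is a
`TechniqueTemplate`: one or two sinusoidal harmonics per local axis riding
on a straight or turning mean path,

- sideways: `s(t) = ± A_m sin(2π f t − π/2)`,
- vertical: `v(t) = A_v [sin(2π f t − π/2 + φ_v) + r sin(4π f t − π + 2 φ_v)]`,
- fore-aft: `u(t) = A_u sin(2π f t − π/2 + φ_u)`,

with cycle frequency `f`, mirror sign `±` (left/right variants), and a
second vertical harmonic `r > 0` only for G3, which has two pole pushes per
movement cycle. Sinusoids reproduce exactly the property the classifier
exploits — the phase relations between the three components — while keeping
every derived quantity analytic: true cycle events are the sideways-velocity
maxima `t = (k + ¼)/f` (or `(k + ¾)/f` mirrored), so event counts, spacings
and heading changes can be asserted in closed form. The fixed −π/2 sideways
phase keeps events strictly inside the sampled interval.

**Amplitudes are calibration constants, not measurements.** The analysis
thresholds (40 m/s sideways and 100 m/s vertical band sums under the STFT
convention below; both config values) imply a scale for realistic head
oscillation: the defaults (sideways 0.20–0.22 m for all skating gears,
vertical 0.12–0.18 m for G2–G4, ≤ 0.01 m for G5 and Tuck, with G5 retaining
a large sideways swing) were chosen once so that the main gears sit clearly
above both gates across 0.6–0.9 Hz while Tuck and G5 sit clearly below,
mirroring the bimodal band-sum distributions seen in real skiing. They are
config entries and can be re-calibrated against real data.

Measurement noise is white Gaussian, σ = 30 mm per axis at 50 Hz — the
accepted proxy for fixed-ambiguity kinematic dGNSS. No colored-noise or
multipath model is attempted. Pole-plant criterion events are the true
cycle events plus a constant 0.15 s offset and 20 ms Gaussian jitter.
Courses concatenate segments (duration, technique, speed, heading rate,
incline) with C0-continuous position, analytically integrated turning, and
float-flagged outage windows. Inter-event intervals that straddle a segment
join are labelled `transition` and excluded from truth tables.

What passing tests on these data do **not** show: robustness to
biomechanical variability between skiers, to non-sinusoidal waveforms, to
GNSS error correlation, or to gradual technique transitions. The treadmill
validation logic (identical conditions, clean periodicity) is emulated; the
field results are emulated only in structure.

## Smoothing spline

Per axis and per contiguous fixed block, a cubic smoothing spline is fitted
with the discrepancy criterion: residual RMS equal to the expected noise SD
(default 0.030 m, configurable). This is implemented with a FITPACK
smoothing spline (`s = n σ²`), which also places knots adaptively; if
FITPACK fails, a penalized smoothing spline is used with the penalty found
by bisection on log₁₀ λ against the same residual target (capped at λ = 100,
above which the banded solve loses accuracy without further smoothing).
Velocity is the spline's analytic derivative — finite differences of the
raw positions would amplify noise by ~2 fs σ ≈ 3 m/s. Blocks shorter than
10 samples are dropped with a warning. Irregularly sampled blocks are
re-evaluated on an exact uniform 50 Hz grid.

On a 0.7 Hz, 0.2 m sinusoid with 30 mm noise the smoother recovers the
signal to ~9 mm RMS, comparable to an ideal-band zero-phase low-pass.

## Local coordinate system

The origin is the smoothed trajectory low-passed at 0.3 Hz (5th-order
Butterworth, forward-backward so zero phase). Two numerical details
matter at so low a cutoff:

- the per-block linear trend (the progression) is removed before filtering
  and added back — it passes a DC-gain-1 filter anyway, and filtering only
  the residual suppresses the multi-second edge transients;
- `filtfilt` padding is extended to three cutoff periods (the library
  default of ~18 samples is far too short).

Blocks shorter than three settling lengths (3 · fs/cutoff = 10 s) are
dropped: the bidirectional filter is unreliable on them.

Axes: ê_s = normalized origin velocity (central differences of the origin),
ê_v = global up, ê_m = ê_s × ê_v renormalized — pointing to the skier's
right; the convention is irrelevant downstream because the left/right merge
makes the pipeline mirror-symmetric. Samples with origin speed < 0.1 m/s
have an undefined frame and are flagged invalid. Head position is projected
onto the axes first and the projections are then differentiated
(`np.gradient`); for a frame rotating at turn rates of ~20°/s the
commutation error against differentiate-then-project is ≲ 0.07 m/s, well
under the 0.7 m/s prominence threshold.

Cycles that reach within one cutoff period (3.3 s) of a block edge are
discarded (`edge_guard_periods`): inside that guard the origin is still
settling and cycle features are distorted enough to flip NNC labels. This
trades a few cycles per block edge for clean classification.

## Cycle detection and averaging

Boundaries are sideways-velocity maxima with topographic prominence
≥ 0.7 m/s (block endpoints act as infinite-depth valleys — the standard
convention) and mutual separation ≥ 0.8 s; among closer peaks the higher
wins, ties to the earlier. Both rules are exact: a pure sine of amplitude
0.35 m/s (prominence 0.70) passes, 0.3 m/s does not.

Cycle length uses the smoothed position (chord, not path length). Heading
rate is |net azimuth change| / duration — per-cycle net change rather than
instantaneous maxima, because it is robust to noise and matches how turning
is judged per cycle.

Averaging duration over N successive cycles telescopes: the block mean is
(last − first boundary)/N, so interior boundary errors cancel and the RMS
deviation falls ~1/N, faster than the 1/√N of independent samples. This is
asserted exactly (`average_over_n`) and measured on noisy synthetic trials:
single-cycle RMS relative deviation ~2%, five-cycle ~0.3–0.8% (the
acceptance script recomputes this).

## Features

Each cycle is linearly resampled at 12 equispaced instants on
[t_start, t_end) — half-open so the wrap point is not duplicated — and
mean-centred per component. Circular cross-correlation (period 12) of
fore-aft × sideways and vertical × sideways at lags −6…+6, each normalized
by the product of component norms, yields two 13-point waveforms
concatenated into the 26-vector. Circularity is justified because a cycle
is one full period; normalization gives the amplitude (speed,
anthropometry) invariance, puts every entry in [−1, 1], and makes mirroring
an exact sign flip. Raw and linear-boundary modes are available as ablation
switches; un-normalized correlation would track absolute oscillation
magnitude and lose the invariance, which is why normalized is the default.
Cycles with fewer than 12 samples are dropped with a warning.

## Spectral gates and decision tree

The STFT convention is fixed because threshold units are meaningless
without it: one-sided magnitude spectrum of the Hanning-windowed (periodic,
256 samples) LCS velocity, 512-point FFT, hop 1, **no** window-gain or
length normalization; a band value is the sum of |X| over bins whose centre
frequency lies in the closed band (sideways 0.5–1.0 Hz → 5 bins, vertical
0.5–1.5 Hz → 10 bins). Band sums are computed as one complex correlation
per band bin rather than a full spectrogram (identical to machine
precision, verified against a direct frame-wise FFT in tests; cheap at
hop 1 on long recordings). Frames are stamped at the window centre, so
gating decisions smear by at most half a window (2.56 s) at transitions.

Precedence is fixed: Tuck ≻ Turn ≻ G5 ≻ NNC. Tuck gating runs on time
intervals *before* cycle detection (a static crouch has no cycles to
detect); cycles overlapping a Tuck interval by more than half their
duration are suppressed. The G5 rule uses the **mean** of the vertical band
over the frames whose centres fall inside the cycle — the mean (rather than
max or a single frame) is the least noisy per-cycle summary and the choice
is flagged as open. Comparisons are strict (`<`): a band sum exactly at
threshold is not Tuck/G5.

## Network and training

26-15-K feed-forward network, tanh hidden layer, softmax output (a single
logistic unit when only two classes are present). Training: scikit-learn's
MLP with full-batch L-BFGS and L2 weight decay (α = 10⁻⁴), deterministic
under a fixed seed. The L2 penalty stands in for Bayesian-regularization
backpropagation — the substantive claim is that the five classes are
linearly-separably encoded by the features, not that a particular trainer
is needed — and a stratified 20% of the cycles is held out and reported as
validation accuracy rather than used as a stopping rule (full-batch
quasi-Newton converges on its own tolerance). On the default 510-cycle
synthetic corpus (45 G2R / 120 G2L / 165 G3 / 120 G4R / 60 G4L, frequencies
0.6–0.9 Hz, speeds 3–5 m/s, ±15% amplitude jitter, 30 mm noise) both the
408 training and 102 validation cycles classify perfectly. Weights
serialize to plain JSON; prediction uses an explicit forward pass on the
stored weights, so a saved model has no pickle or library-version
dependency.

## Evaluation

Automated cycles match annotation intervals greedily by maximal temporal
overlap, requiring the overlap to cover at least half of the shorter
interval (the 0.5 and the denominator convention are documented choices;
an exhaustive-assignment oracle in the tests confirms greedy optimality on
small instances). Unmatched truth cycles count as predicted `none`,
unmatched detections as true `none`; confusion matrices carry both, and
per-class sensitivity is diagonal/row-sum (NaN for empty rows). The
threshold sweep re-labels a *fixed* set of detected cycles over a
(T_G5, T_turn) grid — the prominence threshold is excluded because changing
it would change the detected-cycle set and invalidate the matching.

## Degenerate inputs and determinism

All-float input yields an empty cycle table with the full span marked
excluded. Empty files, unknown fix flags and unknown labels raise explicit
errors. Every stochastic step (noise, pole-plant jitter, corpus
composition, train/validation split, weight init) takes an explicit seed;
identical inputs and seeds give bit-identical outputs, and CSV writers use
round-trip float formatting.

## Problem sizes

Defaults throughout target desk-scale runs: trials of 30–60 s (20–45
cycles), a 510-cycle training corpus, and a 12-trial acceptance run; all
complete in seconds on one core. Larger corpora and longer courses only
change runtime, not any convention above.

## Known limitations

- The hard-rule thresholds are calibrated to the fixed STFT convention and
  to head-mounted sensing; other mount points need re-calibration.
- G5 vs main-gear separation rests entirely on the vertical band sum; real
  G5 with vigorous torso motion will leak past the gate (the generator's
  G5 template is idealized).
- Turning is detected from net per-cycle heading change; short corrections
  within a cycle are invisible.
- The 5.12 s analysis window delays every gate decision near technique
  transitions by up to half a window.
- The synthetic corpus makes class separation easier than field data;
  perfect validation accuracy here does not predict field sensitivity.
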