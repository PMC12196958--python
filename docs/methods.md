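# Methods

This note documents the models and algorithms in `tpear`, the parameters
that matter, the synthetic-data generator the tests rest on, and the design
choices made where the published descriptions of these methods leave the
design open.

## Signals and conventions

All analysis happens in a body-referenced frame: SI (superior–inferior,
positive up), ML (mediolateral, positive toward the participant's left), AP
(anterior–posterior, positive forward).  Accelerations are specific force in
m/s² (a stationary sensor reads +9.81 on SI), angular rates are deg/s, and
the nominal sampling rate is fs = 100 Hz.  Raw device axes are remapped at
read time through an `AxisMap` (signed axis per target channel).  The
north–east–down navigation convention appears only inside the attitude
filter, where the body frame is x = AP, y = −ML, z = −SI.

## Data quality screen and gap repair

Lost transmission packets surface as skipped sample indices or NaN rows;
both count as missing.  A trial is excluded when a single run of more than
10 consecutive samples is missing, or — in evaluation workflows, where
reference ICs exist — when any missing sample lies within 0.3 s of a
reference IC, since such a gap would directly corrupt that event's
detection.  The IC-proximity rule needs labelled events, so detection-only
workflows apply the long-gap rule alone.  Surviving interior gaps are filled
per channel with a not-a-knot cubic spline (which reproduces cubic
polynomials exactly); leading/trailing gaps are held at the nearest observed
value, because cubic extrapolation beyond the record is unstable and badly
truncated trials are removed by the screen anyway.  Observed samples are
never altered and the missing mask records exactly the filled positions.

## Attitude and yaw

A quaternion error-state Kalman filter propagates orientation with the
gyroscope and corrects tilt with the accelerometer's gravity direction.
The error state is the 3-component attitude error; the measurement Jacobian
is the skew matrix of the predicted body-frame gravity direction, whose null
space is the gravity axis — so roll and pitch are observable and yaw is pure
gyro integration, as appropriate without a magnetometer.  Heading is
therefore relative: yaw starts at 0, which is exactly what the turn
thresholds require.  Defaults: gyro noise 0.5 deg/s (attitude random walk),
gravity-direction observation std 0.05, initial tilt std 5°, and a ±3 m/s²
gate on ‖a‖ − g that lets the filter coast through impacts and free-fall-like
samples.  Any attitude filter meeting the package's accuracy tests (final
yaw of a 60° rotation within 1°, stationary yaw within 0.1°) can be swapped
in behind `estimate_orientation`.

Yaw is unwrapped (period 360°) before differentiation; ψ̇ uses central
differences with one-sided stencils at the ends, which halves the phase
error of forward differences at the 30 deg/s threshold.  An optional
zero-phase low-pass on ψ̇ exists but is off by default; the thresholds are
applied to the raw derivative.

## Turn segmentation

Each timed-up-and-go-style trial contains one turn.  Start: the earliest
sample with |ψ| > 15° **and** |ψ̇| > 30 deg/s (both at the same sample —
the head leads the body into the turn, so the angle threshold alone would
fire on casual head movements).  End: the earliest subsequent sample with
|ψ| ≥ |ψ|max − 5°, the maximum taken over the whole trial (the turn is over
when the head has reached its maximal rotation).  All three thresholds are
configuration-exposed with these values as defaults.  If no sample meets the
start criteria, or the yaw never exceeds 15°, a no-turn result (`None`) is
returned — distinct from an error.  When several disjoint threshold
excursions exist the earliest start is used and a warning logged.

## Singular spectrum analysis

A signal of length N is embedded in the L × K Hankel trajectory matrix
(K = N − L + 1), decomposed by SVD, and each eigentriple is mapped back to a
length-N elementary series by anti-diagonal averaging (implemented as a
convolution of the scaled singular vectors divided by the diagonal counts;
a dense brute-force implementation is kept in the test suite as the oracle).
L = round(window_seconds · fs) with a 2 s default; trials shorter than 4 s
fall back to a 1 s window.  For speed, at most 30 eigentriples are
reconstructed explicitly (configurable); the remainder is carried as a
single residual series so the reconstruction identity — components plus
residual equal the input exactly — holds regardless of the cap.  Gait
signals concentrate their energy in a handful of components, so the cap is
far from binding in practice.

Grouping (the published method names the groups but not the rule):

* **trend** — the maximal leading run of components with more than 95 % of
  spectral energy below 0.5 Hz (drift, gravity leakage);
* **dominant** — the adjacent non-trend pair whose FFT peak frequencies
  agree within 20 % and whose combined squared singular values are largest
  (a harmonic manifests as such a pair); a lone oscillatory component is
  accepted when no pair matches;
* **residual** — everything else.

A constant signal yields one rank-1 trend component and no dominant group;
asking for its dominant oscillation raises `FlatSignalError`, which the
detectors propagate for gait-free input.

Diagonal averaging is least reliable within one window of the record ends;
with a drift several times stronger than the oscillation, the dominant
pair carries visible boundary transients (interior correlation with the
generating sinusoid stays above 0.9999 while the full-support value can
drop to ~0.996).  The acceptance check of dominant recovery therefore uses
drifts of variance comparable to the oscillation, where full-support
correlation exceeds 0.999; stronger drifts are a documented limitation.

## Event detection

**SSA baseline.**  The SI channel is band-passed 0.5–5 Hz (zero-phase
Butterworth, order 4) and decomposed; ICs are the maxima of its dominant
oscillation, found as zero crossings of the derivative.  Maxima below 20 %
of the largest dominant peak are discarded — SSA leaves low-amplitude ripple
outside the walking bout which would otherwise spawn spurious cycles.  The
step side is left if the signed difference of consecutive dominant-ML
samples at the IC is positive, right otherwise (an IC at sample 0 uses the
forward difference).  The TC is the first local extremum of the trend-removed
ML signal strictly between the IC and the next IC — a maximum after a left
IC, a minimum after a right IC by default.  The polarity mapping is
configuration-invertible because it depends on the chosen ML sign
convention; the default matches the ML-positive-left convention above.  The
ML channel is decomposed without prior band-passing so that trend removal
remains meaningful.

**TP-EAR.**  The SI channel is band-passed 0.5–12 Hz — the wider band keeps
the separate IC and TC bursts visible — and SSA runs on it as above.  For
each dominant-SI peak a trusted window opens at the last sample before the
peak where the dominant signal is at or below 80 % of the peak value, and
closes at the first dominant minimum after the peak; windows clipped by the
record edge are flagged truncated.  Peaks of the windowed band-passed signal
are counted with a prominence floor of 5 % of the window's peak-to-peak
range (no minimum-distance constraint: the window already localizes one
cycle):

* exactly two → first is the IC, second the TC;
* more than two → IC = the peak closest to the dominant peak (ties broken
  toward the earlier peak, configurable), TC = the latest peak with positive
  value; the positivity test runs on the band-passed (zero-mean) signal, and
  if no positive peak follows the IC the minimum-gradient fallback below is
  used;
* one → the segment is sharpened and re-counted; if at least two peaks
  emerge they are processed by the rules above; otherwise IC = the dominant
  peak and TC = the sample of minimum (central-difference) gradient between
  the IC and the window close — the steepest descent after the unresolved
  IC/TC complex;
* zero (pathological noise) → same fallback as the unresolved one-peak case,
  keeping one IC per dominant peak.

Laterality is determined exactly as in the baseline.  Overlapping windows
never emit out-of-order cycles, and a final pass drops any TC that does not
lie strictly between its IC and the next IC.

**Peak sharpening.**  The published pipeline calls for a peak-sharpening
step without naming an algorithm; the one here is the package's own design.
It subtracts the 3-sample-smoothed second difference at a 3-sample lag
(≈30 ms, the width of a foot-contact burst), scaled by the locally
normalized signal amplitude:

    y = x − w · d2(x) · (x − min x) / ptp(x),   w = 8 by default.

The amplitude weighting confines the correction to elevated parts of the
segment: shoulder inflections on a peak's flank gain enough curvature
contrast to become countable maxima, while the near-zero valley between
well-separated peaks is untouched, so clear peaks neither move (±1 sample)
nor acquire artifact neighbours.  It is deterministic and sits behind an
interface so alternatives can be swapped in.

## Temporal parameters

For consecutive same-side ICs, stride = (IC_end − IC_start)/fs,
stance = (TC − IC_start)/fs, swing = (IC_end − TC)/fs, so
stride = stance + swing holds exactly by construction.  When the stream
carries both feet's TCs — as ground truth and both detectors produce — two
TCs fall inside each cycle span: the contralateral toe-off a double-support
time (~10 % of the stride) after IC_start, and the ipsilateral foot-off near
60 %.  Stance time is defined by the cycle foot's own foot-off, so the cycle
takes the **last** TC strictly inside its span, equivalently the first TC
after the opposite foot's IC.  A cycle without any in-span TC is skipped and
logged (costing sensitivity, never raising); shifting all events by a
constant leaves every duration unchanged.

## Evaluation protocol

Detected events are matched to ground truth per kind (ICs with ICs, TCs with
TCs), ignoring side, by a one-to-one assignment (Hungarian algorithm on the
|offset| matrix with infeasible pairs masked) that maximizes the number of
pairs within the 300 ms tolerance and, among those, minimizes the total
absolute offset — preventing one detected event from absorbing two truth
events; a recursive exhaustive enumeration serves as the oracle in the
tests.  Unmatched truth events are false negatives and unmatched detected
events false positives; sensitivity = 100·TP/(TP+FN) (the alternative
reading of unmatched truth events as "true negatives" would make
sensitivity uncomputable, and the report metadata records this choice).
Laterality accuracy is the percentage of matched IC pairs with equal sides.
Temporal errors are computed over cycles whose bounding ICs were both
matched: signed error = detected − truth per parameter, reported as
mean ± SD of the signed and absolute error in ms.  Parameter errors beyond
300 ms can arise when one bounding event is early and the other late; they
are retained by default, with an optional `outlier_ms` threshold to exclude
them.  When ground truth comes from a separately clocked system,
`align_start` estimates the integer lag maximizing the cross-correlation of
a shared signal.

## The synthetic trial generator

The generator emulates the four study-style tasks — straight walking,
walking with vertical or horizontal head turns at the instructed ~2 Hz, and
a timed-up-and-go-style trial with a single turn — with an exactly known
event timeline.  The left foot strikes first after a 1 s lead-in; ICs
alternate every half stride (default stride 1.1 s); each foot's TC follows
its own IC by stance_fraction · stride (default 0.6, constrained to ≥0.5 so
double support is non-negative).  Within a bout of n strides per foot this
places one contralateral toe-off a double-support time after *every* IC —
the first right toe-off is the gait-initiation foot-off from standing — so
each foot contributes exactly n ICs and n TCs and no foot-off dangles beyond
the final step.

* SI: gravity plus one Gaussian burst (σ = 30 ms) per event — 2 m/s² at ICs,
  half that at TCs — so every peak location is analytically known and
  detector correctness is decidable.  Vertical head turns add a sinusoid
  here.
* ML: one lateral sway per stride (1 m/s²), phased so its slope at each IC
  is positive-left/negative-right (the laterality convention) and its
  extrema fall on the TCs (the baseline's TC rule); a sway per stride is the
  only phasing under which the slope sign can alternate between successive
  alternating-side ICs.  The extremum placement is a modelling convenience
  that makes the baseline's TC rule exactly satisfiable; the laterality
  encoding is by construction, so laterality tests validate the convention's
  self-consistency, not its physiological truth.  Horizontal head turns add
  a 2 Hz sinusoid (default 1 m/s², comparable to the sway) on this channel —
  reproducing the failure mode that motivates TP-EAR while leaving SI
  untouched.
* AP: a low-amplitude (0.3 m/s²) oscillation at step frequency.
* Gyro: the body turn is a raised-cosine yaw ramp whose analytic rate feeds
  the SI-axis gyro (yaw is about the down axis, hence the sign flip);
  accelerometer and gyro white noise default to 0.1 m/s² and 0.2 deg/s.

Everything is deterministic given the seed.  `inject_gaps` marks chosen
runs as missing (NaN plus mask) to exercise the quality screen and spline
repair.

What the generator does **not** emulate: recorded waveform morphology,
soft-tissue and mounting resonances, stride-to-stride timing and amplitude
variability, asymmetric or pathological gait, turning-induced changes in
foot placement, and head-turn coupling into the gyro.  Passing the synthetic
suite therefore establishes algorithmic correctness — threshold logic, branch
rules, identities, robustness mechanisms — not clinical performance on
recorded data.

On clean trials the baseline detector shows a systematic ~30 ms stance/swing
bias here: its IC estimate is the dominant-oscillation peak, which the TC
burst pulls a few samples late, while its ML-extremum TCs are exact.  TP-EAR
reads both events from the underlying signal peaks and is exact on the same
trials — the synthetic analogue of the bias removal its design targets.

## Problem sizes used

The acceptance script and end-to-end tests use 25 noiseless 20-stride trials
(1000 truth events per detector) for event recovery, 10 trials per condition
for the head-turn robustness comparison, 100 random signals (length
300–1000) for the SSA identity, 50 noisy logistic yaw profiles for turn
segmentation, and 100 random instances (≤12 events per side) for the
matching oracle; these sizes give stable percentages while keeping a full
run around ten seconds.

## Known limitations

* Yaw is relative and drifts with gyro bias over long records; trials are
  assumed to start at rest near the pre-turn heading.
* The SSA window (2 s / 1 s fallback) is manually chosen; no automatic
  window-length optimization is attempted.
* Whether the baseline's ICs should come from the filtered or unfiltered SI
  dominant oscillation is not fully specified in the literature; the
  filtered variant is the default here.
* The matching tolerance (300 ms), turn thresholds (15°, 30 deg/s, 5°) and
  band edges are taken as given; no sensitivity analysis over them is
  performed.
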