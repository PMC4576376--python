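# Methods

This note documents the models, conventions and numerical choices behind
`ddkit`, and what the synthetic fixtures do and do not establish about real
deployments.

## Data model

A deployment is a delimited table, one row per sample, with the wall clock
split over `day/h/min/s/ms` columns. Timestamps are combined as
`day·86 400 000 + h·3 600 000 + min·60 000 + s·1000 + ms` milliseconds and
re-based to the first sample; the absolute value of the first sample is
retained so that fix files sharing the clock can be aligned. Fixes are
merged by **exact** timestamp match — no interpolation — with null
elsewhere; a nearest-sample tolerance exists but is off by default, since
resampling positional data is an analysis decision the user should make
explicitly. Malformed numeric cells become nulls and are counted; nulls are
skipped inside windowed means and carry through every derived channel.
Exports write floats with `%.17g`, and imports parse with round-trip float
precision, so an export → import cycle is bit-exact.

## Magnetometer calibration

Error model: hard-iron effects displace the measurement sphere by a
constant offset `b`; soft-iron effects stretch it into an ellipsoid
(modelled as a symmetric positive-definite linear map). We fit the general
quadric `x'Mx + 2g'x = 1` by linear least squares and extract
`b = −M⁻¹g` and the shape matrix `Q = M / (1 + g'M⁻¹g)`; the correction is
`W = sqrtm(Q)`, i.e. `corrected = W(x − b)` maps the cloud back onto a
sphere. When the ellipsoid does not enclose the origin the RHS=1
normalisation flips the sign of `M`; dividing by `1 + g'M⁻¹g` restores a
positive-definite `Q` either way, so only a mixed-signature quadric is
rejected ("insufficient orientation coverage", as is any cloud whose third
singular value is < 1e-6 of its first — points near a plane cannot
constrain all three axes).

The algebraic fit is validated by parameter recovery (offset and shape
recovered to 1e-6 on noise-free clouds; offset error well under 0.005 raw
units at noise σ = 0.01 on a unit field with 500 points) rather than by
matching any particular published estimator. `W` is rescaled so the mean
corrected norm is one; heading is invariant to positive rescaling of the
field vector, so this global scale is cosmetic. Fit quality is reported as
the coefficient of variation of the corrected norms. The model (13 numbers)
serialises to labelled plain text so it can be inspected, hand-adjusted and
re-applied to other data sets from the same deployment.

Declination is a single user-supplied constant per deployment (obtainable
from the NGDC reference service); it is not re-estimated per fix.

## Attitude and heading

Conventions (angles in degrees at every interface, radians internally):

* a level device reads `(0, 0, +1) g`;
* `pitch = atan2(−sx, √(sy²+sz²))` ∈ [−90, 90], nose-up positive;
* `roll = atan2(sy, sz)` ∈ (−180, 180];
* heading `H = atan2(m_y, −m_x)` mapped to `[0, 360)`, i.e. a level device
  pointing magnetic north reads `(m_x, m_y) ∝ (−1, 0)`; declination is
  added modulo 360 for geographic heading.

The heading ratio `m_y / −m_x` only defines `H` up to a half-turn; the
two-argument arctangent resolves all four quadrants while agreeing with the
ratio wherever it is defined — the quadrant convention is fixed by the
north/east examples above. These sign conventions are internally consistent
and verified by rotation-oracle recovery (forward-simulate a known attitude
and field, recover pitch/roll to 1e-9° and heading to 1e-6°); other tools
may differ by axis signs, which the `AxisMap` (signed axis permutations for
magnetometer-to-accelerometer alignment and mounting orientation) absorbs.

Static acceleration is a centred moving average with an odd window;
edges use the truncated window. The window is a required user parameter
(published guidance ties it to stride/flap period; a value near 2 s of
samples is a common starting point — the synthetic scenarios use 5 samples
to match their 8 Hz gait, see below). Gimbal lock: as |pitch| → 90° the
roll is set to 0 by convention, and heading is nulled when the horizontal
field component falls below 1e-9 of the total field.

## Energetics and speed

`DA_i = |raw_i − running mean_i|` per axis; `VeDBA` is the Euclidean norm
and `ODBA` the L1 norm of `(DA_x, DA_y, DA_z)`, so
`ODBA/√3 ≤ VeDBA ≤ ODBA` always. The phrase "absolute values of running
means … from the corresponding raw acceleration values" admits two
readings; we compute the absolute residual per sample (not a running mean
of absolute residuals), which keeps `static + dynamic = raw` exact. The
speed rule `s = VeDBA·m + c if VeDBA > t else 0` is evaluated exactly as
printed — the threshold is strict, so `VeDBA = t` yields zero — with no
hysteresis or smoothing. Calibrating `m`, `c` against measured VO₂ or
treadmill speed is out of scope; constant-speed mode covers species (e.g.
volant ones) where VeDBA does not track speed, with fix correction
repairing the scale afterwards.

## Dead-reckoning and fix correction

The destination update (README) advances one sample per step with
`q = s·Δt/R`; the speed-to-angle conversion `q = s/R` is dimensionally a
rate, so the per-sample interval Δt (from the timestamps) completes it.
`R = 6.371×10⁶ m`; the earth is spherical throughout (no ellipsoid — fix
correction absorbs the sub-0.5 % error this introduces over inter-fix
distances). Null heading or speed samples leave the position unchanged.
A start at a pole with nonzero motion is rejected (longitude undefined).

`fix_heading` is the standard initial great-circle bearing
`atan2(sin Δλ·cos φ₁, cos φ₀·sin φ₁ − sin φ₀·cos φ₁·cos Δλ)`; published
presentations of the trajectory-heading formula sometimes transpose the
numerator and denominator of the underlying ratio, so we pin the
implementation by the round-trip property instead: one dead-reckoned step
of length `fix_distance(p0, p1)` along `fix_heading(p0, p1)` must land on
`p1` (verified to 1e-9°). `fix_distance` is the haversine form with the
same `R`.

Correction proceeds segment by segment between consecutive fixes, each
segment re-anchored at its opening fix (resetting accumulated error):
compute `hC = gpsHeading − drHeading` (bearings between the segment's
endpoint pairs, not per-sample quantities) and `sC = gpsDistance/drDistance`,
apply `hC` to every sample heading and `sC` to every sample speed in the
segment (`sC` scales `q` uniformly — that is what makes the segment length
equal the fix-to-fix distance), re-integrate, and repeat. Iteration stops
when the incremental adjustments drop below 0.1° and 0.1 %, when the
endpoint residual is below `tol` (default 1 m), after `max_iter` (default
10) accepted iterations, or when a candidate step would worsen the residual
(the step is rejected, which keeps the residual log non-increasing by
construction). `hC` is wrapped to (−180, 180] before application. If a
segment dead-reckons to zero length while its fixes are apart the speed
coefficient is undefined; the segment is flagged and a uniform speed
profile covering the fix-to-fix distance substituted. Samples before the
first fix are left as supplied; samples after the last fix continue from it
with the last segment's corrections (the best local estimate of the
systematic biases). GPS error itself is not modelled: fixes are treated as
truth.

## Behaviour matching

Similarity is per-channel normalized cross-correlation: template and window
zero-meaned and unit-normed, so the score is invariant to gain and offset
of either side. Channels are normalized first and averaged second
(unweighted), so each channel contributes equally regardless of units. The
correlation `r ∈ [−1, 1]` maps to percent as `(r+1)/2·100`: 100 % is an
exact shape match, 0 % maximal anti-correlation, uncorrelated noise ~50 %.
Windows with relative variance below 1e-12 are flat — correlation with them
is undefined — and score 0; a flat template channel is an error. Sliding
dot products are computed by FFT convolution with cumulative-sum window
statistics (the fast NCC construction), agreeing with the direct sliding
correlation to better than 1e-10; the unnormalized mode returns the raw
sliding correlation in signal units (amplitude-aware thresholds).

Match extraction keeps positions scoring **at or above** the threshold
(inclusive, so a 100 % threshold returns exact matches) and reduces them by
non-maximum suppression — highest similarity wins, ties to the earliest
start — so accepted windows do not overlap; suppression can be disabled.
The default threshold is 85 %: on the package's reference benchmark
(61-sample motif at 6 dB SNR) true instances score ≈ 95 % and the noise
floor peaks in the high 70s, so 85 splits the two with margin on both
sides. Boosting pools the above-threshold candidates of several example
templates and suppresses jointly. Resampling uses polyphase low-pass
interpolation/decimation with the output trimmed to `round(L·p/q)`.
Labels are half-open sample intervals; overlapping labels of the same
class union, overlapping labels of different classes are an error; class
codes are assigned 1, 2, … in creation order, 0 meaning unlabelled in
exports. Rejected matches are remembered so re-running a search cannot
resurrect them, but a manual label overrides a rejection (the analyst's
direct call wins). The template store is a directory of plain-text
template files under a JSON index keyed animal → behaviour.

## The synthetic deployment generator

The generator is the package's test bed and defines its study conditions:
10 minutes at 40 Hz by default; start 51.6° N 4.0° W; field inclination
66°, declination −2°, unit field magnitude; hard iron (0.2, −0.1, 0.3);
soft iron an SPD matrix with axis gains 1.15/1.25/1.4 rotated 30° (sensor
gain errors above unity, the common instrumental case); mean speed 1.2 m/s
with a smooth random-walk heading (4°/√s RMS drift); constant pitch 4° and
roll −3°; fixes every 60 s; 12 planted 61-sample motifs on the pressure
channel; a 500-point pre-deployment calibration cloud. Speed model
m = 3 m·s⁻¹/g, c = 0.1 m·s⁻¹, t = 0.05 g, in the range reported for
terrestrial VeDBA-speed calibrations.

Two constructions make truth exactly recoverable:

* the **gait** is a quadrature pair `A(cos ωt, sin ωt)` on the x/y axes
  with the gait period (5 samples, 8 Hz) dividing the smoothing window, so
  the windowed mean of the gait vanishes identically away from the record
  edges and per-sample VeDBA equals `A = (s − c)/m` exactly — the
  VeDBA-speed proxy is true by construction, making `m`, `c` recoverable by
  regression and injected speed-scale errors exactly visible to the fix
  correction;
* systematic errors are injected **physically**: a heading bias is a yaw
  mounting misalignment of the magnetometer frame, a speed scale is a
  mis-scaled gait amplitude, so the derived channels carry exactly the
  biases the correction must estimate.

The noise-free self-consistency scenario uses constant attitude and the
constant-speed option with motifs planted on the pressure channel: any
time-varying attitude or gait passes through the truncated moving-average
window at the record edges and would break sub-1e-6° exactness, which is a
property of the estimator, not of the simulation. What passing these tests
shows is that the chain of transforms is implemented exactly and that
systematic biases are recovered; what it does not show is robustness to
the things the generator leaves out — irregular gaits whose VeDBA-speed
relation is only approximate, time-varying attitude during locomotion,
magnetic anomalies, GPS error (fixes are noiseless by default) and sensor
drift. Accuracy on real deployments is bounded by those effects, not by
the numerics tested here.

## Scales and problem sizes

The test suite and acceptance script use deployments of 2–5 minutes at
40 Hz (4 800–12 000 samples), 10⁴-step oracle walks, 10³ bearing round
trips, 500-point calibration clouds and an 8 000-sample matching benchmark
— sizes chosen so the full suite runs in well under a minute while every
statistic is stable to the asserted tolerances; all structures stream
linearly, and multi-hour deployments (millions of samples) differ only in
runtime.

## Known limitations

Vertical (pressure-derived) movement is not integrated into the track;
there is no gyroscope/Kalman attitude fusion, no magnetic dip estimation,
no ellipsoidal earth, no GPS error model, and no track segmentation. The
behaviour matcher is query-by-example only — supervised classifiers are
deliberately out of scope.
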