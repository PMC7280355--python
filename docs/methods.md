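# Methods

## What is being modeled

Mental-chronometry paradigms delivered through web browsers inherit two
timing distortions from commodity hardware. First, stimulus durations are
quantized to the display refresh cycle (a *frame*, 1000/60 ≈ 16.67 ms on
the common 60 Hz panels) and browsers occasionally realize more or fewer
frames than requested; the error is summarized as the *frame difference*
(realized − requested frames). Second, internally measured response times
(RTs) overestimate the physically realized RT (stimulus onset to actuator
contact) by a device-specific amount: a roughly constant offset plus
variable noise that on some device/browser pairs is clearly bimodal, and
on some devices is itself quantized to the refresh lattice.

`chronobench` contains (a) an emulator that renders experiment schedules
into the raw data an external-chronometry rig would record under a
parametric device model, (b) pipelines that recover duration and RT
accuracy statistics from such data, and (c) a Monte-Carlo study of how the
RT noise model degrades the reliability of individual-difference measures.

## Emulator

A `DeviceProfile` holds: a refresh rate (default 60 Hz), the optical
sensor's sampling rate (default 3000 Hz), a map from (timing method,
presentation method, requested frames) to a distribution over integer
frame differences (most-specific key wins, default is a point mass at 0),
flags for two systematic behaviors seen in practice (CSS-animation timing
realizing exactly one extra frame; 3- and 6-frame requests collapsing to a
single frame with configurable probability, default .7), an omission
probability, and the RT offset model (constant + equal-weight two-Gaussian
mixture + optional refresh-lattice quantization of the measured RT).

The presentation schedule is the full crossing used in the duration
experiment: 120 sequences, each one of the 120 distinct orderings of the
requested durations {1, 3, 6, 15, 30} frames, times five method blocks
(CSS/background, CSS/opacity, rAF/background, rAF/canvas, rAF/opacity),
25 trials per sequence, 3,000 trials in all. The same interval order is
used within each method block of a sequence, and orderings are shuffled by
a seeded uniform shuffle. Every trial is rendered as 400 ms background,
a 400 ms intertrial marker, 400 ms background, then the stimulus.
Luminance is binary 0/1 with no rise/fall ramp — the downstream 50%
threshold rule only needs crossings — and every realized duration is an
integer number of frames by construction. An omitted stimulus contributes
no screen time, producing the diagnostic signature of ~800 ms darkness
followed by the next ~400 ms marker. The RT schedule presents, per method,
every whole-millisecond interval from 150 to 449 exactly once in seeded
pseudorandom order, with 1200 ms between intervals and 5000 ms between
sequences; the actuator trigger is issued 11 ms early so that the 11 ms
solenoid travel lands the touch exactly at the scheduled interval.

Presets (`perfect`, `css_plus_one`, `ios_like`, `windows_chrome_like`,
`macos_chrome_like`, `macos_firefox_like`) encode the qualitative device
classes: the quoted RT offsets (e.g. 68.5 ms constant with 1.7 ms spread
for the Windows/Chrome-like preset; 60.0/12.4 and 89.1/2.4 ms mixture
components for the MacOS/Firefox-like preset) are emulation targets taken
as parameters, not reproductions of any physical measurement. For 1-frame
requests, negative frame differences are folded onto +1 so a stimulus
flagged as presented is never rendered with zero frames.

What the emulator does *not* capture: luminance rise/fall ramps and
backlight flicker, device load, browser-engine scheduling, correlated
frame drops (differences are sampled independently per trial, since only
marginal distributions are modeled), and any systematic structure in
stimulus omissions. Passing round-trip tests therefore show that the
pipelines are correct under the stated noise model, not that any physical
device behaves like a preset.

## Duration pipeline

Events are maximal runs of luminance above 50% of maximum; onset/offset
are the first samples beyond the threshold in each direction, so measured
durations are accurate to one sample period (1/3 ms at 3000 Hz). A
minimum-event-duration filter of 2 sample periods suppresses single-sample
glitches; no hysteresis is applied. Trial matching walks the event stream
consuming one marker per logged trial and classifies the following gap:
~400 ms means the critical stimulus follows, ~800 ms means it was omitted.
Plausibility windows are nominal ±25% (configurable); a sequence containing
an implausible marker is flagged wholesale, and durations that are not
within 2 ms of a frame multiple are flagged individually. Every logged
trial yields exactly one output row, valid or flagged, so accounting is
conservative by construction. Durations stay in milliseconds until
`to_frames` quantizes them (nearest integer, ties half up). Percent-exact,
internal-agreement (internal estimate quantized into frames equals the
sensor's frame count) and frame-difference histograms (range −4..4 with
open-ended pooled edge bins) are simple grouped aggregations over the
matched table.

## RT pipeline

Overestimation is measured RT minus realized RT (touch minus onset).
Summaries report min/max/mean/sample SD (n−1). Quantization detection
computes the circular resultant length of the phases 2π·RT/resolution; the
score is 1.0 on-lattice and ~Rayleigh-distributed (≈√(π/4n)) for
unstructured values, and the flag threshold is 0.9 — the numeric stand-in
for what was originally a visual scatterplot judgment, chosen far above
the null distribution for any n ≥ 30. The two-component Gaussian mixture
is fitted by EM with deterministic initialization (split the sorted sample
at the median, moment-match each half), relative log-likelihood tolerance
1e-8, at most 500 iterations, and up to 5 seeded random-responsibility
restarts if a component's weight or SD collapses; the log-likelihood is
asserted non-decreasing at every step and components are reported in
ascending-mean order.

## Reliability simulation

Each simulated participant p has ex-Gaussian RTs: Normal(trait_p, σ_p) +
Exponential(mean τ_p), with σ_p ~ U(25, 75) ms and τ_p ~ U(50, 100) ms.
Device noise, when enabled, adds a per-participant constant ~ U(60, 130) ms
plus a per-trial draw from an equal-probability mixture of N(0, sd1_p) and
N(mean2_p, sd2_p), sd·_p ~ U(2, 12) ms and mean2_p ~ U(0, 30) ms. In the
*absolute* design the trait (Gaussian mean component) is drawn with SD 15,
25 or 50 ms and the score is the mean measured RT over n trials; in the
*relative* design two traits correlated .5 (equal SDs, so the difference
has the same SD) drive the two conditions with n/2 trials each, and the
score is the difference of condition means. Noise parameters are drawn
once per participant and shared across conditions — one participant, one
device — which is exactly why the constant cancels from relative scores
(an algebraic identity asserted in the tests). Reliability is the squared
Pearson correlation between trait (or trait difference) and score across
the 100 participants of one simulated experiment; replicates with
degenerate variance would be excluded from cell means and counted (with
continuous traits this does not occur in practice). The grid crosses
2 designs × 2 noise conditions × 3 trait SDs × trial counts 10..300 step
10, with 1,000 replicates per cell (per-cell means and SDs are reported).

Random streams: replicate `rep` of grid combination `ci` uses
`SeedSequence(root_seed, spawn_key=(ci, rep))`, and the noise-on and
noise-off runs of a replicate share that stream. Because noise draws are
consumed only after the traits, ex-Gaussian parameters and trial-level RT
draws, the two conditions see identical RTs (common random numbers) and
the noise-induced reliability decrease is a paired, low-variance contrast.
"Average" noise effects are unweighted means of these paired differences
across the 30 trial counts; the crossover is the smallest grid trial count
from which the relative design's mean reliability is at least the absolute
design's at every larger grid point, per trait SD, reported as the maximum
across trait SDs.

A useful analytic check (asserted in the tests, noise off, absolute
design): mean RT = trait + τ_p + sampling noise, so reliability approaches
trait_sd² / (trait_sd² + Var(τ_p) + E[σ²+τ²]/n) with Var(τ_p) = 50²/12 ≈
208 ms² and E[σ²+τ²] ≈ 8542 ms². The same algebra predicts the crossover
counts: relative scores carry 4·E[σ²+τ²]/n sampling variance but no τ_p or
device-constant variance, which places the no-noise crossover between 120
and 130 trials and the with-noise crossover near 40–50, as the simulation
reproduces.

## Problem sizes and tolerances

The package's own test suite runs the grid at 200 replicates (tolerance
widened from ±.02 to ±.03 on the absolute-design noise effects), renders
the full 120-sequence presentation experiment once for the round-trip
check (binomial 99% CI per method cell at n = 600; chi-square goodness of
fit on the pooled frame-difference counts at α = .01), and checks RT
round-trips at 300 trials (mean offset within ±0.5 ms, ≈5 Monte-Carlo
SEs). `scripts/acceptance.py` runs the full 1,000-replicate grid.

## Known limitations

* Frame differences and internal-estimate errors are i.i.d. across trials;
  real browsers show temporal autocorrelation under load.
* The trial matcher resynchronizes only at the granularity of whole
  sequences; a corrupted marker invalidates its sequence rather than
  attempting sub-sequence repair.
* The EM fitter is univariate and fixed at k = 2 components, matching the
  analysis it supports; no model selection over k is attempted.
* The quantization flag threshold (0.9) is intentionally blunt: it detects
  lattice-locked measurements, not partial or drifting quantization.
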