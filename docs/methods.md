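# Methods

This note documents the models, conventions and numerical choices behind
`ctquant`, and what the synthetic-data generators do and do not emulate.

## Spike-train model and metrics

**Renewal firing.** Stimulus-locked firing is a gamma renewal process with
shape k = 4. The downstream metric is the *mean instantaneous frequency*
(mean of reciprocal inter-spike intervals), so the generator calibrates the
ISI scale for that metric: for Gamma(k, θ), E[1/ISI] = 1/(θ(k−1)), hence a
target mean IF of f uses θ = 1/(f(k−1)) (event rate (k−1)/k·f ≈ 0.75 f).
A Poisson process is unusable here — its mean reciprocal ISI diverges —
which is why the shape is fixed above 1. Rate profiles are flat within a
stimulus epoch; real stroke responses are modulated within the stroke, but
no quantitative time course is available to calibrate one, and the
windowed IF metrics are insensitive to the profile shape.

**Waveforms and classes.** Each spike inserts a 3-ms biphasic template with
a dominant leading phase (unique global extremum, so peak alignment is
unambiguous) — downward-leading for C fibres, upward-leading for A-beta,
following the recording convention in which polarity encodes conduction
class. Spikes are delayed by a conduction latency of 0.3 m divided by the
unit's conduction velocity (~0.28 s for a 1.09 m/s CT). Rapidly adapting
units fire only during the first 200 ms of a monofilament hold.

**Mean IF convention.** "Mean instantaneous frequency between the first and
last spike" is implemented as the arithmetic mean of reciprocal ISIs, which
is consistent with peak IF being the maximum of the same sequence. The
alternative (N−1)/span reading is available via
`spike_metrics(..., mean_if_mode="span")`. Both require at least two spikes;
below that the metrics are reported absent, never zero. By Jensen's
inequality mean(1/ISI) ≥ (N−1)/span, with equality only for regular trains.

**Detection.** Candidates are voltage-magnitude peaks above a threshold
(default 5 robust noise SDs, MAD-based) separated by a 2-ms refractory
period. The matching template is the mean candidate waveform inside brush
epochs — the stimulus used to verify spike morphology — and candidates pass
at a normalized cross-correlation ≥ 0.8. Without a brush epoch the
highest-amplitude candidate seeds the template and the train is flagged.
Multi-unit recordings are out of scope: the pipeline assumes one unit per
trace, as mixed recordings are discarded at acquisition time.

**After-discharge.** Discharge durations are drawn from Normal(7.1 s,
3.2 s) with non-positive draws resampled; firing decays linearly from
10 spikes/s toward a 2.5 spikes/s floor and the final spike is placed
exactly at the drawn duration, which *defines* the ground-truth discharge
length as the time of the last spike. The detector scans post-stimulus
spikes and terminates at the last spike before the first gap exceeding the
gap rule (default 2 s ≈ 10–20× the typical discharge ISI); a first spike
arriving later than the gap rule counts as no discharge. Truncation of the
Normal at zero raises the expected drawn mean by ≈ 0.11 s; the detector's
mean over 500 trials stays within ±0.3 s of 7.1 s.

**Thresholds.** The monofilament force set is fixed to a standard
Semmes-Weinstein sequence (0.08–3000 mN); non-member forces are rejected.
The estimate is the lowest tested force with response proportion ≥ 0.5,
confirmed by re-test (≥ 2 trials; a single-trial qualifier is flagged
low-confidence). The simulated staircase descends from 4 mN with three
trials per force, a 2% lapse rate, and stops after the first silent force.
The CT threshold population is categorical over {0.4, 0.7, 1.6, 4.0} mN
with weights (3, 10, 1, 1)/15, whose mean (0.92 mN) and SD (0.87 mN) match
the recorded population summary. The "≤ 4 mN" criterion is inclusive.

## OCT M-mode displacement

**Rendering.** The skin appears as a bright band under a dark air gap; the
air/skin boundary is a linear intensity ramp spanning exactly two depth
samples. Threshold-crossing segmentation with linear interpolation of the
crossing is then *exact* for noiseless data at any sub-sample surface
position — the basis for the < 0.01 µm deterministic recovery checks.
Depth resolution is 5.5 µm/sample; depth increases away from the probe, so
indentation is a positive step and displacements are reported as
magnitudes.

**Segmentation.** Threshold = background mean + 5 background SDs, estimated
from the shallow rows, falling back to the half-contrast level on
effectively noiseless data; the track is median-filtered (1 ms at 10 kHz;
5 ms in the reduced-rate pipeline runs). A-lines without a crossing are
flagged invalid and excluded from window means (each window requires ≥ 50%
valid samples).

**Events and windows.** The event is the extremal step of the smoothed
track (largest positive step for monofilament contact; largest magnitude
for hair release). Displacement = |mean(pre) − mean(post)| over 200-ms
windows separated from the event by a 20-ms guard gap that excludes the
transition; the idle estimator subtracts two consecutive 500-ms windows
placed at the start of the recording (the longer windows average biological
motion). Hair-release trials use the same 200-ms windows as indentation.

**Artefacts and rejection.** Injected artefacts: beam-crossing occlusion
(600 ms of air-level A-lines), heartbeat (8 µm, 1.2 Hz surface
oscillation), gross motion (30 µm/s drift). Rejection criteria: > 5%
invalid A-lines ("beam-crossing"); a 0.8–2 Hz spectral amplitude above
3 µm in the detrended first 1.2 s ("heartbeat"); linear drift above
10 µm/s ("motion" — set above the idle condition's physiological
4.1 µm/s so resting trials are not self-rejected). The generator tags
round(0.23 × n_trials) trials, and the detector recovers that fraction.

**Condition calibration and top-10 selection.** Per-trial ground-truth
displacements model imperfect instrument placement: 4 of 9 grid locations
are "optimal", the rest attenuate to 20–60% of the nominal amplitude. The
optimal pool (20 trials) is sized so that ≥ 10 trials survive a 23%
rejection rate with high probability. Because the analysis keeps only the
ten largest displacements, optimal trials are drawn from a distribution
back-solved through normal order statistics (top-10-of-m moments, m = the
expected surviving pool), so that the **selected** top ten form a sample
whose mean and SD match the calibrated per-condition group statistics
(idle 2.04 ± 1.59, hair release 8.14 ± 3.72, 0.4 mN 17.09 ± 4.83, 0.7 mN
25.28 ± 6.05, 4.0 mN 60.93 ± 6.35, 6.0 mN 79.18 ± 10.46 µm; spreads
derived from the reported 95% CIs at n = 10). Idle drifts are signed, the
magnitude being what the estimator reports.

**Statistics.** Tukey HSD (studentized-range, family-wise α = 0.05) via
`scipy.stats.tukey_hsd`, cross-checked against a permutation oracle in the
tests; per-condition 95% CIs are t-based on the selected ten values. A
caveat the test suite makes explicit: at these calibrated group
statistics, the 0.4 vs 0.7 mN contrast lies almost exactly at the Tukey
significance boundary (q ≈ 4.2 vs critical ≈ 4.17) and hair vs 0.4 mN is
only slightly clearer, so the *exact* all-pairs-but-one significance
pattern replicates in only a minority of random protocol realizations; the
robust sub-pattern (idle vs hair release indistinguishable, all
non-marginal pairs separated) is the stable prediction and is what the
regular suite asserts.

**Problem sizes.** Single-trial analyses run at the acquisition geometry
(3 s × 10 kHz, 160 depth samples). Full-protocol runs (270 trials) use a
1 kHz A-line rate and 128 depth samples — the windowed estimators are
rate-independent, and this keeps a protocol run at a few seconds.

## Optical flow

The polynomial expansion fits, per pixel, a quadratic form over a poly_n
neighborhood with Gaussian applicability (σ = poly_sigma), computed by
separable correlations with reflective borders; displacement solves
A·d = −½(b₂ − b₁) in a least-squares sense over a winsize box window,
iterated 8 times with bilinear warping inside a 4-level pyramid
(scale 0.6, Gaussian anti-aliasing before resampling). The 2×2 normal
equations carry a Tikhonov term of 10⁻⁶ × trace: low-contrast regions have
small but well-conditioned equations that an absolute epsilon would crush
to zero flow, while genuinely flat regions still fall back to zero. Flow
within poly_n of the border is flagged low-confidence. Cumulative fields
sum incremental flow at fixed pixel locations (Eulerian); they describe
displacement reported at each pixel, not material-point trajectories.
Independent cross-checks in the tests use `skimage` iterative Lucas-Kanade
flow and subpixel phase correlation on pure translations; the
package-under-test route is never used as its own oracle. The background
for the "minimal skin motion" summary is, by convention, everything below
the 90th magnitude percentile (overridable with an explicit mask).

## Tip tracking

Segmentation is automatic intensity thresholding (between-class variance),
justified by the acquisition's strong dark-instrument/light-skin contrast;
externally supplied masks (e.g. from a learned segmenter) plug in via
`track_video(masks=...)`. The mask is refined by morphological closing
(radius 2); opening is off by default because it erodes several pixels from
a narrow apex while isolated specks are already removed by the
largest-component rule. The boundary is traced with high connectivity
(keeps thin diagonal tips), at sub-pixel precision from the iso-intensity
level of the masked grayscale frame, and simplified at 0.4 px maximum
deviation — sub-pixel flank fidelity is what the apex refinement depends
on. Curvature is the turning angle over a ±3-vertex span on a uniformly
resampled (2 px) polyline; without resampling, the angle/arc normalization
spuriously favors closely spaced vertices. The tip is the maximal-curvature
vertex within the search radius (default 30 px ≈ 0.65 mm) of the previous
tip, ties broken by proximity then index, frame-border vertices excluded;
it is then refined to the intersection of total-least-squares line fits to
the two flanks, which recovers the geometric apex where the instrument
narrows below one pixel and segmentation recedes. Speed is the per-frame
Euclidean step × fps / calibration, Gaussian-smoothed with σ = 5 frames
(treated as frames, matching the per-frame speed series) with reflective
ends, which preserves the mean of a constant-speed segment to < 2%.

The video generator renders the wedge with 4× supersampled area-coverage
anti-aliasing (a hard-rasterized apex flickers by ±1 px frame to frame) on
a low-contrast textured background. It does not emulate motion blur,
shadows, specular highlights on the instrument, or hair occlusion of the
tip — tracking through those requires the pluggable external-mask front
end.

## Determinism and limitations

Every generator and pipeline takes a single seed; child streams are spawned
from it, and protocol ground truths use a separate `structure_seed` so that
varying the noise seed leaves truths bit-identical. Re-running any pipeline
with the same configuration reproduces outputs exactly.

What passing tests show — and what they do not: the synthetic traces carry
stationary Gaussian noise and stereotyped waveforms, so detection results
bound performance only for recordings with comparable SNR and single-unit
isolation; the OCT model has no speckle decorrelation, refraction or probe
tilt; the video model's contrast is idealized. The generators exist to
verify the estimators' correctness and calibration, not to certify
performance on arbitrary real recordings.
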