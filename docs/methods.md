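# Methods

This note documents the models, numerical choices and limitations behind
`rehabsig`. Units throughout: milliseconds for time, volts for signal
amplitude, hertz for rates, kPa for pressure.

## Synthetic signal models

The package is exercised end to end on synthetic signals, so the
generators define the study conditions.

**R–R interval series.** Intervals are Gaussian-jittered around a mean of
800 ms (excited, ≈75 bpm) or 900 ms (fatigue, ≈67 bpm) with jitter SD
30 ms (excited) vs 1 ms (fatigue). The two classes are made unambiguous
with respect to the 10-beat/5-ms fatigue rule *by construction*: fatigue
jitter is rejection-resampled into ±2.4 ms, so the range of any 10
consecutive intervals is below 4.8 ms; any excited 10-interval window
whose range falls below 5 ms is redrawn (with SD 30 ms this essentially
never happens). Consequences for interpretation: rule-trigger and
false-alarm rates of 100%/0% on generator output demonstrate correct
plumbing, not clinical sensitivity/specificity — real drowsiness produces
graded, drifting regularity, not a hard two-class separation.

**ECG.** One sum-of-Gaussians PQRST template per beat: bumps at offsets
(−160, −25, 0, +25, +180) ms from the R apex, widths (25, 8, 12, 8, 60) ms,
amplitudes (0.15, −0.10, 1.00, −0.20, 0.30) V. The R bump is the per-beat
global maximum, so the apex time is exact ground truth. For R–R intervals
under 600 ms the P/T offsets compress proportionally so beats do not
collide at high heart rates. Default sampling 500 Hz (the QRS is resolved
with ~6 samples per R-bump sigma). Noise model: sinusoidal baseline wander,
50 Hz powerline pickup, Poisson-timed Gaussian motion-artifact bumps, and
white noise. The `ambulatory` preset uses wander 0.15 V at 0.3 Hz,
powerline 0.02 V, artifacts 4/min at 2.0 V with 15 ms sigma, white noise
0.02 V — artifact bumps twice the R amplitude, the regime the artifact
filter exists for. The `gen_ecg_at_bpm` convenience floors intervals at
306 ms so that near the 180 bpm end of the tested range the jitter cannot
create true beats inside the detector's 300 ms refractory period, which
the detector is forbidden (by its own contract) to report.

**EMG.** White noise band-passed to 20–450 Hz, normalized to unit RMS,
then amplitude-modulated: baseline envelope 0.05 V RMS, and a trapezoidal
envelope (10% ramps) per motion window with peak 1.5 V on the dominant
channel and 0.8 V on the other. Dominance follows the motion: FCR for
forearm pronation and finger flexion, ECRL for hand closing and wrist
extension. Default sampling 1000 Hz (Nyquist above the 450 Hz band edge).
This surrogate has controllable RMS but none of the structure of real
surface EMG (motor-unit firing statistics, spectral compression under
fatigue, crosstalk), so passing tests show feature extraction and
discrimination logic are correct, not that the thresholds would transfer
to electrodes on skin.

**Training sessions** cycle the four motions (2 s burst, 3 s rest) with
envelope peaks decaying multiplicatively at a configured rate per hour —
a burst at elapsed time *t* has peak `peak0 · (1−decay)^(t/1h)`. Initial
peaks are 2.0/1.6 V (dominant/non-dominant) for excited sessions and
1.8/1.5 V for fatigued ones, matching the first-minute intensities of a
representative one-subject session; per-minute mean envelope peaks are
stored as ground truth.

## ECG processing

- **Low-pass**: 4th-order Butterworth at 40 Hz applied forward–backward.
  Because filtfilt squares the magnitude response, the design cutoff is
  pre-warped (×1.116 at order 4) so the *combined* response is −3 dB at
  the nominal cutoff; DC gain is exactly 1 and the ≤20 Hz passband is
  flat to <0.2%.
- **Baseline removal**: subtract a 600 ms sliding-window median
  (reflect-padded). The window is longer than any QRS, shorter than a
  wander period; a 0.3 Hz wander is attenuated >80%.
- **Artifact suppression**: samples deviating from a 2 s running median
  by more than `max(8 × running MAD, 1.5 × q99.5(|deviation|))` are
  replaced by linear interpolation, with the flagged mask dilated by
  30 ms to catch artifact shoulders. The quantile floor is essential: an
  ECG is sparse and spiky, so a raw MAD sits at the noise level and an
  8-MAD threshold would flag every R wave; flooring at 1.5× the robust
  maximum deviation keeps clean traces bit-identical while still removing
  bumps that dwarf the QRS. A constant signal (MAD ≡ 0) passes through.
- **R-peak detection**: local maxima from a first-order-difference sign
  change; amplitude threshold = half the maximum candidate amplitude,
  evaluated per 10 s chunk (bounding slow amplitude drift) with a global
  floor of 0.25× the overall maximum so beat-free chunks contribute
  nothing; candidates closer than the 300 ms refractory period are pruned
  largest-amplitude-first. Measured on generator output: clean recall =
  precision = 100% within one sample over 40–180 bpm; ambulatory-preset
  recall ≈ 99.5% and precision 100% within 20 ms (the few misses are
  beats whose QRS is engulfed by an artifact bump and removed with it).
- **HRV**: sliding windows (stride 1) of k = 10 intervals; variation
  (max−min), mean, SDNN (ddof = 1), RMSSD. P/Q/S/T annotation is provided
  relative to each detected R (nearest flanking minima / windowed maxima)
  but feeds nothing downstream.

## Fatigue classification

The rule detector flags fatigue as soon as any 10-interval window has
variation < 5 ms. The SVM uses a linear kernel (C = 10) on standardized
(mean R–R, SDNN, RMSSD, variation) windows of 10 intervals at stride 5;
the standardization statistics come from the learning-phase windows and
are persisted with the model, carrying the per-individual calibration.
When no labels exist for the learning phase, the CLI bootstraps them from
the rule (per-window variation threshold), extending the phase forward
until both classes have been seen. Label streams are majority-smoothed
over 3 trailing windows to suppress alert chatter; an alert is emitted on
each excited→fatigue transition. Held-out accuracy at the generator's
default class separation is at ceiling; the permuted-label control trains
to chance (~50%), confirming the accuracy is carried by the features.

## EMG processing

Segment RMS uses non-overlapping windows of N = 200 samples (0.2 s at
1 kHz), trailing remainder dropped. Calibration takes the maximum segment
RMS of each of three maximal-effort trials and averages them into RMS_M;
normalized RMS may exceed 1 when activity surpasses calibration, and
values above 0.95 are annotated as possibly saturated (the sensor's RMS
stops tracking intensity in strong contractions; no alternative strong-
activity estimator is implemented). Activity events are maximal runs of
≥3 segments above a normalized threshold of 0.2, after merging runs
separated by <2 sub-threshold segments; two-channel detection segments
the elementwise max of the two normalized series so either muscle can
announce activity. Events are assigned a dominance *group* (FCR-dominant
vs ECRL-dominant) from peak normalized RMS; two forearm channels cannot
separate the two motions within a group, so per-motion labels are only
ever attached from ground truth. Exact ties are reported as indeterminate
rather than raised.

## Closed-loop control

Discrete proportional control at the EMG segment cadence (0.2 s):
`p ← p + g·(setpoint − measured)`, clipped to the pump's [0, 75] kPa; on
each fatigue-confirmed step the pressure is additionally scaled by 0.8
and the setpoint ramped down 10%. The plant is the minimal model able to
reproduce both training regimes: intrinsic intensity decaying
multiplicatively with elapsed time plus a linear assistance term,
`measured = b₀(1−decay)^(t/1h) + a·p + noise`. With defaults
g = 10 kPa/V and a = 0.05 V/kPa the loop gain g·a = 0.5 gives monotone
convergence; the noise-free fixed point satisfies measured = setpoint
exactly for any loop gain in (0, 2). The reference contrast uses a 60-min
session with 0.3/h decay and 0.02 V sensor noise: without adaptation the
final-third mean intensity falls ~21% below the first third (the closed
form for this decay integral gives 21.2%); with adaptation it stays
within a fraction of a percent of the 1.5 V setpoint.

## Sizes and determinism

Every stochastic component draws from a `numpy.random.Generator` passed
explicitly; identical seeds give identical signals, traces and summaries
(the pipeline summary is byte-reproducible). Test and acceptance problem
sizes — 100 clean + 20 ambulatory ECG cases, 10,000 rule sequences, 400
SVM windows per split, 20 four-motion scenes, 60-min control sessions at
18,000 steps — were chosen so the full suite completes in about a minute
while keeping binomial noise on the reported rates well below the margins
being checked.

## Known limitations

- All validation is against the package's own generators; no human data.
- The ECG surrogate has no arrhythmias, ectopic beats or electrode-motion
  spectral overlap with the QRS; the artifact filter is tuned for bump-
  like artifacts larger than the R wave.
- Frequency-domain HRV (LF/HF) and EMG fatigue spectra (median-frequency
  shift) are out of scope.
- The controller has no actuator dynamics, valve timing or safety
  interlocks beyond pressure clipping; it is a strategy simulation, not a
  device controller.
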