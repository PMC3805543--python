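# Methods

## Problem

A fingertip photoplethysmogram (PPG) records pulsatile blood-volume changes;
each cardiac cycle shows a dominant systolic wave followed by a smaller
diastolic wave. Systolic-peak detection is the first step of any PPG-based
heart-rate or heart-rate-variability analysis, and it becomes hard on
recordings taken after exercise in hot, humid conditions: beat amplitudes
drift and drop suddenly, premature beats break the rhythm, and the
signal-to-noise ratio falls. `ppgpeaks` implements a detector built for that
regime — two event-related moving averages with a dynamic offset threshold —
together with three classical comparators, the evaluation statistics used to
compare them, a brute-force parameter optimizer, and a ground-truthed
synthetic generator that emulates the recording conditions.

All sample indexing is 0-based; intervals are half-open `[onset, offset)`;
amplitudes are treated as arbitrary units; the sampling rate (367 Hz for the
emulated device) is supplied out-of-band and never inferred from files.

## The event-related moving-average detector (`detect_elgendi`)

Stages, in order, on a record x[n] sampled at f_s:

1. **Bandpass.** Zero-phase Butterworth, design order 2, passband
   F1–F2 = 0.5–8 Hz, realized as cascaded second-order sections applied
   forward–backward (`sosfiltfilt`). The forward–backward pass cancels phase
   lag (event timing is preserved exactly) and squares the magnitude
   response, so the effective attenuation order is 4. The 0.5 Hz corner
   removes baseline wander; the 8 Hz corner removes high-frequency noise
   while keeping the systolic upstroke.
2. **Clipping and squaring.** y[n] → max(y[n], 0) → z[n] = y[n]².
   Squaring emphasises the systolic lobe over the diastolic wave and noise.
3. **Two moving averages.** MA_peak = MA(z, W1) with W1 = 111 ms
   (systolic-duration scale) and MA_beat = MA(z, W2) with W2 = 667 ms
   (beat-duration scale). Window lengths in samples are the *nearest odd
   integer* to W·f_s (41 and 245 samples at 367 Hz); averages are centered,
   consistent with the zero-phase pipeline, and shrink to the available
   samples at the record edges (no padding is fabricated).
4. **Dynamic threshold.** THR1[n] = MA_beat[n] + α with α = β·mean(z),
   β = 0.02. *Blocks of interest* are the maximal runs where
   MA_peak[n] > THR1[n].
5. **Width rejection.** THR2 = W1 in samples (41). Blocks narrower than
   THR2 are noise or diastolic residue and are dropped.
6. **Peak extraction.** Each surviving block contributes the argmax of z
   within it (earliest index on ties, for determinism). z is a monotone
   transform of the clipped filtered signal, so this is the filtered-signal
   argmax wherever the signal is positive.

Because z, MA_beat and α all scale with the square of the signal amplitude,
the block geometry — and hence the detections — is invariant to positive
rescaling of the record. That is the property that lets the detector run
without any patient-specific threshold. Raising β can only remove blocks,
never create them, so the detection count is non-increasing in β.

Defaults (F1, F2, W1, W2, β) = (0.5 Hz, 8 Hz, 111 ms, 667 ms, 0.02) are the
outcome of brute-force optimization on rest-condition data; `optimize`
reproduces the procedure.

## Comparator detectors

**Local extrema (`detect_billauer`).** An alternating peak/valley state
machine: a running maximum becomes a peak once the signal falls more than δ
below it, after which a valley is sought symmetrically. δ = 0.1 is an
*absolute* amplitude, so the method is not scale invariant; the CLI
max-abs-normalizes the signal first so that δ = 0.1 is meaningful on
arbitrary units. A 0.5–8 Hz bandpass is applied by default (disable with
`use_bandpass=false` to recover the original unfiltered behavior). The
method has no notion of beat morphology, so the diastolic wave of a
well-separated beat is reported as a peak — its characteristic
false-positive mode at rest.

**First derivative with adaptive thresholds (`detect_li`).** Zero-phase
low-pass (8 Hz) then a first difference. Prominent derivative maxima
(maximal inflections of the upslope) are paired with the following
negative-going zero crossing of the derivative, which sits on the signal's
local maximum — the systolic-peak candidate. Amplitude and beat-interval
thresholds are initialized from 2 s selective windows at the start of each
of 3 equal divisions of the record and updated beat-by-beat as running
means over the last 8 accepted beats. Candidates closer than 0.5× the
running interval to the previous beat are rejected; once a gap exceeds
1.5× the running interval the amplitude threshold is halved (search-back).
The low-pass cutoff, division count, amplitude factor (0.5) and interval
gates (0.5/1.5) are this package's choices — the original publication does
not fix them — and all are exposed in `LiParams`.

**Slope sum with adaptive threshold (`detect_zong`).** Zero-phase low-pass
(16 Hz, chosen to preserve the pulse upslope and exposed as a parameter),
then the slope sum function

    SSF[n] = Σ_{k=n-w+1..n} max(x[k] − x[k−1], 0),   w = 128 ms (47 samples)

which amplifies the upslope and suppresses the rest of the waveform. The
threshold base initializes to 3× the mean SSF over the first 8 s; the
working threshold is 60% of the base and the base updates to each accepted
pulse's SSF maximum. A crossing is accepted when the SSF min/max excursion
in the 150 ms windows around it exceeds 10% of the base (the original rule
says "a certain value"; the 10% fraction is exposed as a parameter). The
pulse onset is found by walking back to where SSF first exceeds 1% of the
pulse maximum, then shifting 20 ms earlier to compensate the low-pass lag;
a 300 ms refractory period suppresses double detections, and is enforced on
the emitted peak indices as well. Because this formulation detects *pulses*,
not systolic peaks, the returned index is the maximum of the band-limited
signal between the onset and the end of the post-crossing search window —
without this mapping the method could not be scored against systolic-peak
annotations. The window end is `max(onset + 2·150 ms, crossing + 150 ms)`:
anchoring the end to the crossing matters for the first beat of a record,
where the SSF's truncated leading history pulls the 1%-rule onset to sample
0 and a window anchored on the onset alone would end before the apex.

## Evaluation

Detections are matched to annotations one-to-one within an inclusive
±50 ms window, greedily in order of increasing absolute time difference.
With beats separated by far more than the tolerance (cardiac refractoriness
guarantees this), each detection can match at most one annotation, and
greedy matching equals the maximum bipartite matching; the test suite
checks this equivalence against an independent `scipy` matching oracle and
documents one constructed pathological chain where greedy pairs fewer —
greedy is the contract. SE = TP/(TP+FN), +P = TP/(TP+FP), overall accuracy
= (SE + +P)/2. Dataset-level figures pool TP/FP/FN across records
(micro-averaging). When a record has no annotations (or no detections) the
corresponding rate is defined as 1.0 and a warning is logged.

## Parameter optimization

`grid_search` evaluates every valid combination of a `GridSpec`
(f1 < f2 enforced; W1 < W2 enforced; β given in percent) over a training
set and ranks rows by overall accuracy, breaking ties deterministically by
higher SE, then lower W1, lower β, lower F2, lower W2. Two grids ship:

* `reconstruction_grid()` — the published search ranges (0.5–1 Hz ×
  7–15 Hz × 54–111 ms × 545–694 ms × 0–10%); the original step sizes are
  not recoverable, so this is a reconstruction, not a replica.
* `coarse_grid()` — 27 combinations around the defaults, used by the
  `pipeline` command and sized so a full train/test run takes seconds.

The `pipeline` command implements the train/test protocol: optimize on
rest-condition records only, freeze the winner, evaluate all four detectors
on every condition without further adjustment.

## Synthetic data

Each record is a sum of per-beat templates plus baseline wander and white
noise. A beat is two Gaussians: a unit-amplitude systolic bump (FWHM
150 ms) and a diastolic bump delayed 280 ms at 0.4 relative amplitude
(FWHM 220 ms) — the simplest shape with the PPG's two-wave morphology and
an unambiguous apex. Beat apices accumulate intervals
(60/HR)·(1 + U(±3%)); per-beat amplitude is modulated by a slow 0.1 Hz
sinusoid (depth 0.2) and, with per-beat probability `amp_drop_prob`,
suddenly dropped to 25% — the false-negative mode of heat-stressed
recordings. Premature beats are inserted at 55% of the current interval
with 60% amplitude and *are* annotated as true beats. Baseline wander is a
0.25 Hz sinusoid at 0.3 amplitude; white noise is added last.

Presets: `rest` = 76 bpm (the emulated cohort's mean resting rate), noise
SD 0.02, no artifacts; `after_exercise` = 120 bpm, noise SD 0.10, 5%
amplitude drops, 3% premature beats. Both at 367 Hz, 20 s. The "clean"
condition used by the recovery tests is the rest preset with `noise_sd=0`;
wander and drift stay on because they are scene structure the filters must
remove, not additive noise.

Ground truth is the systolic apex sample, defined before noise addition;
noise can move the observed local maximum by a few samples, which the
±50 ms scoring tolerance absorbs by design. Because the apex generally
falls between sample instants, the diastolic tail can shift the noise-free
argmax by up to about half a sample; the generator invariant is therefore
"truth is within one sample of a local maximum", not exact equality. A
beat whose apex would fall within one systolic width of the record end is
not scheduled: its descent would lie outside the record, making it
undetectable in principle and un-annotatable by a human marker.

What the generator does *not* emulate: real arterial hemodynamics
(no Windkessel model), motion-artifact waveforms, respiration-modulated
morphology, or waveform compression at high heart rate — the diastolic
delay is fixed at 280 ms, so above ~140 bpm the diastolic wave runs into
the following systole and consecutive beats can merge after filtering.
Detector sensitivities in that regime (≈98–100%) reflect this template
limitation as much as the detectors themselves; the robustness tests
therefore assert perfect recovery over 60–120 bpm (the study-relevant
range) and ≥97% above it. Passing tests consequently show correct
*algorithmic* behavior under the modelled difficulty modes, not clinical
performance on real heat-stress recordings.

An empirical note the stress tests surface: the local-extrema method's
positive predictivity *improves* at 120 bpm because its diastolic false
positives merge away at fast rhythm — the same fast-rhythm effect seen on
real post-exercise recordings — so the degradation checks compare
sensitivity, which falls for every method under the stress preset.

## Numerical choices

* Millisecond-to-sample conversions round half away from zero; moving
  averages additionally apply the nearest-odd rule (111 ms → 41 samples,
  667 ms → 245 at 367 Hz; 128 ms SSF window → 47).
* The SSF's first w samples sum over the truncated available history so the
  output stays index-aligned; the first difference defines out[0] = 0 for
  the same reason.
* Argmax ties resolve to the earliest index.
* Records shorter than the zero-phase filter's edge padding, than one
  selective window (method II), than the 8 s initialization (method III) or
  than W2 (method IV) are rejected with explicit validation errors.
* Filters are designed in second-order sections; at 367 Hz with a 0.5 Hz
  corner a transfer-function realization would be poorly conditioned.
* Everything is deterministic: the synthesizer takes an explicit seed
  (dataset records derive per-record seeds by counter), and the pipeline's
  reports are byte-identical across reruns on the same inputs.

## Problem sizes

The shipped checks use 20-second records at 367 Hz throughout: 20 clean
rest records (~500 beats) for clean recovery, 50 after-exercise records
(~2,000 beats) for the robustness ordering, 10 records × 27 grid points
for parameter recovery, and a 5-record two-condition manifest for the
end-to-end pipeline determinism check. The full suite runs in well under a
minute on one CPU.

## Known limitations

* Method II's division count, threshold-update arithmetic and cutoff are
  package choices where the original description is silent; results for
  that comparator characterize this implementation, not the original code.
* The greedy matcher is the contract even where an optimal matcher would
  pair one more peak (only possible when detections are closer than twice
  the tolerance — not a physiological regime).
* Only systolic peaks are reported: no onsets, dicrotic notches, diastolic
  annotations, or HRV analysis.
* δ for the local-extrema method is meaningful only relative to signal
  scale; the library function does not normalize unless asked
  (`normalize=true`), the CLI always does.
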