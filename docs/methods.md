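# Methods note

This note records the models behind `cuespindle`, the defaults and why they
were chosen, the numerical decisions, and what the synthetic-data generator
does and does not emulate.

## Synthetic polysomnography

**Hypnogram.**  Sleep is generated as repetitions of a cyclic template of
(stage, mean epoch count) segments — by default
W(2) → N1(3) → N2(30) → N3(25) → N2(15) → REM(15) epochs of 30 s, i.e. a
~90-minute cycle — with multiplicative Gaussian jitter (15 %) on each
segment length.  Arousals arrive as a Poisson process at 4/h of sleep
(a typical scored-arousal rate for healthy young adults), placed uniformly
within sleep epochs with durations uniform on 3–10 s.

**Cue schedule.**  Tones are delivered only during *stable* target sleep,
operationalised as: the epoch containing the tone **and the preceding
epoch** are both N2 or N3, and the block does not overlap an arousal.  This
mirrors an experimenter who starts replay only after the target stage is
established and pauses on arousal.  Blocks hold exactly 12 tones with
inter-trial intervals uniform on 2.5–3.5 s and are followed by at least 20 s
of silence; generation stops at `target_total_tones` (default 1,000) or
when eligible sleep runs out.

**EEG.**  Background activity is pink (1/f) noise per channel, scaled per
stage (default RMS 15/20/30/45/20 µV for W/N1/N2/N3/REM).  The paper trail
for an RMS-percentile detector requires nothing more structured than a
scale-varying coloured background, and 1/f is the minimal spectrally
realistic choice.  Spindle-band bursts are raised-cosine (Hann) enveloped
sinusoids; the Hann envelope makes the injected duration well defined.
Burst *density* is configured per (stage, period) pair, where the period
labels cue/no-cue/other are derived from the generated cue schedule with the
same window definitions the analysis uses — so the generator can plant a
cue-locked density contrast for the analysis to recover.  Default densities
(N2: 2.4/2.0/2.0 per min for cue/no-cue/other; N3: 1.8/1.5/1.5) encode a
modest cue surplus and an N2 > N3 gradient, matching the qualitative
pattern such studies report; absolute per-stage densities are free
parameters of the generator, not calibrated to any dataset.  Burst
amplitude is expressed as the ratio of burst peak amplitude to the
channel's background sigma-band RMS (default 8; validation configurations
use 10).  Bursts never straddle arousals and never overlap on a channel
(bounded rejection sampling; a configuration too dense to place raises).
Mastoid channels (TP9/TP10) carry scaled-down noise and no bursts — they
exist to exercise re-referencing, not detection.

**Behaviour.**  Reaction time for a trial is

```
rt = baseline + subject intercept + A_session · exp(−k · block)
     + penalty · [random block] − effect_session · [cued sequence] + ε
```

floored at 150 ms (a conservative lower bound on human choice reaction
time).  Defaults: baseline 400 ms, subject SD 40 ms, residual SD 80 ms,
random-block penalty 60 ms, per-session learning amplitudes/rates
(120 ms, 0.08) for S1 and (30–40 ms, 0.06) for the re-test sessions, and
cueing effects 0/5/10/25 ms for S1/S2/S3/S4 — an effect that emerges over
post-stimulation time, the behavioural signature this class of experiment
looks for.  Each session holds 24 cued + 24 uncued sequence blocks
interleaved with runs of at most two, followed by 4 random blocks
(alternating tone sets); every block is 3 repetitions of a 12-item
sequence.  Random-block item orders satisfy the task's constraints: equal
item counts, no immediate repeats, no > 4-item run shared with either fixed
sequence.

All randomness derives from one seed split into named substreams
(hypnogram/cues/eeg/behaviour), so a (seed, config) pair is byte-reproducible
and perturbing one stage leaves the others untouched.

**What the generator does not emulate:** slow oscillations, K-complexes,
spindle–slow-oscillation coupling, EOG/EMG, topographic correlation between
channels, stage-transition EEG dynamics, and reaction-time autocorrelation
beyond the block level.  Passing tests therefore demonstrate correctness of
the *pipeline* under its stated assumptions, not detector performance on
real polysomnography.

## Preprocessing

Resampling is polyphase with linear-extension edge padding; the working
rate is 250 Hz.  The broadband filter is a minimum-order Chebyshev Type II
band-pass designed from the printed edges (passband 0.3–35 Hz, stopbands
< 0.1 and > 45 Hz) with passband ripple 1 dB and stopband attenuation
40 dB — the order/ripple are design choices, as only the edges are given —
applied forward–backward so spindle timing is phase-true for cue-locked
windowing.  Bad-channel interpolation is the unweighted mean of the named
neighbours (the simplest faithful reading when only the neighbour set is
specified).  Re-referencing subtracts the mean of TP9/TP10 from every
non-mastoid channel.

## Spindle detection: numerical choices

* The threshold percentile (86.64 = two-sided Gaussian coverage at 1.5 SD)
  is computed per channel over samples staged N2/N3, since detection only
  concerns those stages; a whole-record span is available via
  `DetectorParams(percentile_span="all")`.
* Thresholding is strict (`>`); percentiles use linear interpolation of
  order statistics; supra-threshold runs are never merged across gaps.
* Oscillations are counted as sign-transition pairs of the mean-removed
  sigma-filtered segment, rounding half-cycles up so that whole-period
  tones count their leading boundary zero (1 s of 13 Hz → 13).
* The unimodality check evaluates a Blackman-tapered periodogram of the
  broadband segment (`spectrum_source="sigma"` switches to the filtered
  segment), zero-padded to 0.5 Hz bins and smoothed with a 3-bin moving
  average.  The taper matters: with a boxcar, the interpolation sidelobes
  of a clean burst show up as extra in-band maxima, while windows with wide
  main lobes cannot separate 12 from 15 Hz.  Blackman at 0.5 Hz bins passes
  a pure 13 Hz burst, rejects an equal-power 12 + 15 Hz mixture, and
  rejects segments dominated by out-of-band power.
* Events are assigned the stage of their midpoint epoch; boundary events
  are not split.

A structural consequence of the envelope definition worth knowing: the
supra-threshold run of a burst is roughly its duration plus the RMS window,
truncated where the envelope re-crosses the threshold.  Bursts just outside
the duration criteria (0.3 s or 2.5 s) can therefore occasionally produce
*measured* events inside [0.5, 2.0] s.  The detector guarantees the
criteria on its measured output — never on what was physically injected —
and the validation suite checks exactly that.

## Cue windows and density

Intervals are half-open; "wholly within" means `start ≥ period start` and
`end ≤ period end`.  Spindles overlapping an arousal by any amount are
excluded; boundary-straddling spindles are dropped from density.  Arousal
time is *not* subtracted from density denominators by default (the
convention is genuinely ambiguous; `subtract_arousal_time=True` flips it).
Zero-minute cells report an undefined (NaN) density with a flag rather
than 0.  Stage percentages exclude wake from the denominator.

## Behavioural scoring

"Exceeding 1,000 ms" is read strictly: `rt == 1000` is retained.  The
random-block pool for SeqSpecS is all four random blocks of a session,
pooled across tone sets.  Early/late windows are fixed at 4 blocks.
Explicit-recall chance is the mean score of 10 random sequences drawn with
equal item representation (three of each, matching the task's structure);
an i.i.d.-uniform alternative is available.  Session-to-days mapping for
the cueing-benefit time model is S2 → 1, S3 → 10, S4 → 20 days.

## Statistics

The Shapiro–Wilk gate is fixed at α = 0.05.  Mixed models are fitted by
maximum likelihood (not REML) because the likelihood-ratio test compares
models with different fixed-effect structures; REML estimation is exposed
for completeness.  The optimiser falls back across L-BFGS/BFGS/Powell/
Nelder–Mead and keeps the best finite likelihood; if a nested pair comes
back with the full model below the reduced one, both are refitted
exhaustively before the LR statistic is formed.  Boundary fits
(random-effect variance ≈ 0) are flagged `singular`, not silenced.
Post-hoc pairwise contrasts are coefficient differences of the
treatment-coded factor with model-based covariance and a normal reference,
Holm-adjusted — an estimated-marginal-means simplification that is exact
for additive models; Kenward–Roger degrees of freedom are not reproduced.
The 1.5·IQR outlier rule is applied algorithmically only (no visual
inspection step); quartiles use linear interpolation.

The type-I-error calibration of the mixed-model LRT (rejection rate in
[0.025, 0.085] at nominal 0.05 over 400 null simulations of 20 subjects ×
3 sessions × 2 sequences) runs as part of the test suite.

## Problem sizes used in the test and validation suites

Detector validation uses 10-minute single-channel records (250 Hz) with 30
injected bursts, 10 seeds; whole-night simulations in the pipeline tests
use 10–20-minute multichannel excerpts with 2–3 subjects; behavioural
recovery uses 20 subjects.  These sizes give the statistical power the
assertions need (3-SE bands, F1 ≥ 0.85) while keeping the suite quick to
run; all scale linearly if larger runs are wanted.

## Known limitations

* The detector's false-alarm rate on burst-free pink noise is ~1 event/min
  per channel at the default threshold: an envelope-percentile detector
  with these acceptance rules admits occasional noise runs.  Real analyses
  mitigate this the same way the validation suite does — by comparing
  densities between conditions, where the noise floor is common mode.
* No slow/fast spindle split, no topographic statistics, no artifact
  rejection beyond scored arousals, no ICA.
* Effect sizes for post-hoc contrasts are not reported (the choice of
  measure is not pinned down; estimates and Holm-adjusted p-values are).
* The EDF writer emits plain 16-bit EDF with 1 s records and requires an
  integer sampling rate.
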