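# Methods

This note documents the models, estimators, and numerical choices behind
the package, and what its synthetic data can and cannot establish.

## Task model

A trial of the visual-metronome task presents three visible *entrainment*
intervals of duration T ∈ {500, 750, 1000} ms, defined by a stimulus that
alternates between the left and right sides of a screen, followed by up to
four *maintenance* intervals in which the alternation continues only
virtually. A go-cue arrives at the middle of one maintenance interval
(uniformly the 1st–4th) and the subject reports the stimulus's inferred
side. All trial-relative times are in milliseconds with zero at the first
stimulus onset; epochs are half-open `[onset, offset)`. A 500 ms
pre-trial baseline precedes each trial.

## Scalar-variability timing model

The behavioral model assumes the subjective elapsed time since
maintenance onset, t̂, is Gaussian,

    t̂ ~ Normal(t_go / g, (w · t_go)²),

where `w` is the Weber fraction (timing noise proportional to the timed
duration — the scalar property), and `g` is the clock gain: the internal
interval is `g·T`, so `g > 1` means a slow internal metronome that lags
fast tempos, `g < 1` one that leads slow tempos. The reported side
follows the parity of `floor(t̂ / T)` counted on top of the known
entrainment intervals (noise is assumed to accrue only once the external
rhythm disappears; an accrual-from-trial-onset flag exists). With
probability λ the report is a fair coin (lapse).

The closed-form probability of a correct report
(`behavior.pcorrect_scalar`) sums Gaussian interval masses over intervals
of the true parity within `|j − j₀| ≤ J` (default J = 10; widening to
J = 20 changes no probability in the task's parameter range by more than
1e-10; residual mass outside the window is split evenly between
parities, which also yields the exact 1/2 limit for a diffuse clock).
Parity is evaluated over the whole real line — negative subjective times
keep the parity of their mathematical floor — keeping the closed form
identical to the simulated agent.

Fitting (`behavior.fit_scalar_model`) is binomial maximum likelihood over
(w, λ) with g fixed at 1 (a free-gain flag exists for the lag/lead
question); data are aggregated to tempo × go-cue cells, so the fit cost
is independent of trial count. Confidence intervals are
profile-likelihood intervals at the χ²(1) cutoff; estimates at the lower
`w` bound are flagged as boundary solutions. The reaction-time analysis
regresses the *median* RT per elapsed-time point on elapsed time
(trial-level regression available). The 4th-interval performance uplift
seen in the original behavioral data (attributed to the known maximum of
four intervals) is deliberately not modelled.

## Synthetic sessions

The generator (`metronome.synth`) is the ground-truth engine for every
analysis stage. Design choices, with defaults:

- **Trials**: balanced crossing of tempo × start side × go-cue interval,
  order shuffled by seed.
- **Internal clock**: a single per-trial realized clock, period
  `T · t_go / t̂`, drives both the behavioral report and the maintenance
  burst schedule, so neural and behavioral errors are mutually
  consistent. Error trials at `g = 1.15` therefore carry genuinely slower
  burst rhythms; at `g = 0.9`, faster.
- **LFP**: each channel is 1/f^1.5 Gaussian background, rescaled so the
  baseline 30–40 Hz analytic envelope has unit mean (so "two-fold over
  baseline" is amplitude 2). Gamma bursts are a ~35 Hz carrier under a
  piecewise-exponential envelope (rise 50 ms, decay 150 ms), one per
  switch event, *centered so the envelope peak falls on the event* —
  mean gamma then peaks at the switches, as the switch-vs-mid t-test
  expects. Peak amplitude grows linearly with total elapsed time,
  `1.5 · (1 + 0.5 t)` (an exponential growth model is selectable); the
  growth is strong enough that late-trial bursts dominate the upper
  amplitude decile, which is what makes the 90th-percentile burst
  definition behave as in the source recordings. Onset jitter is scalar
  (sd = 0.05 × elapsed time), accruing from maintenance onset for
  maintenance events and from trial onset for the externally cued
  entrainment events.
- **Coherence structure**: the burst carrier is shared across channels
  with weight `exp(−d/λ_mix)` (d = distance from the array centre,
  λ_mix = 300 µm default) plus a channel-private narrow-band component
  (relative amplitude 0.25); together with the independent in-band
  background this gives a phase-locking value that decays with
  electrode separation and stays below 1 at zero distance.
- **Spikes**: inhomogeneous Poisson,
  `(baseline + ramp·t) · side_gain^[preferred side] · (1 + κ cos(φ − φ₀))`,
  with φ the instantaneous gamma phase of the unit's channel. During
  maintenance the side factor follows the trial's internal clock.

What the generator does *not* emulate: movement-related activity (the
go-cue-to-movement period is excluded from spike–field analyses),
eye-movement artifacts, non-stationary electrode drift, unit waveform or
sorting noise, cross-frequency coupling beyond the single gamma band, and
session-to-session heterogeneity of burst parameters. Tests passing on
synthetic sessions therefore validate the estimators and the pipeline
logic — not claims about any particular biological dataset.

## Spectral estimation

The time–frequency map is a sliding-window estimate: 200 ms windows at
5 ms steps, one Slepian taper with time-half-bandwidth NW = 1 (the
"one taper, 5 Hz bandwidth" configuration), frequency axis restricted to
5–80 Hz. Edge windows are dropped, never padded — padding would bias the
baseline normalization. Each time–frequency bin is divided by the mean
power of a 500 ms pre-trial baseline at the same frequency, per trial (a
session-mean flag is available; the per-trial choice is an acknowledged
ambiguity).

The gamma envelope is the mean of the normalized spectrogram over the
30–40 Hz rows (band edges inclusive, membership by bin centre). A
cross-check path band-passes (4th-order Butterworth, zero-phase
forward–backward) and takes the analytic-signal magnitude scaled by its
baseline mean; the two methods agree in rank order and are
interchangeable for burst timing. The analytic path is used where many
sessions must be processed (it is ~5× faster and has no 200 ms
smoothing); note its values are amplitudes while the spectrogram path
yields power, so only the spectrogram path should be quoted in
"power over baseline" units.

**Permutation test.** The published analysis states only "permutation
test of the time-frequency bins, 1000 permutations"; our concrete scheme
pairs each trial's task bin with one randomly chosen baseline bin of the
same trial and frequency and sign-flips the paired differences (1000
draws, two-sided, p floored at 1/1001). The pairing makes the test exact
under exchangeability; its false-positive rate is verified at α = 0.05.

**Envelope periodogram.** Per-trial periodogram of the mean-subtracted
envelope over a common-length epoch, averaged across trials; the slow
1/T alternation of gamma amplitude appears as a peak near 1/T. To
compare correct and error rhythms, we use the spectral centroid
restricted to 0.5–1.5 × the nominal rhythm frequency: the full 0–5 Hz
centroid is diluted by burst-shape harmonics and growth-trend power and
does not isolate the alternation rate.

## Burst analysis

A burst is a maximal run of envelope samples strictly above the 90th
percentile of the pooled amplitude distribution lasting ≥ 100 ms (four
gamma cycles). Pooling is per session × tempo over whole trials
(baseline through maintenance); whether the original thresholds pooled
maintenance only is not stated, so the scope is a labelled argument.
Sub-threshold dips split bursts (a merge-gap parameter defaults to 0);
percentiles interpolate linearly between order statistics; a burst's
interval is the one containing its onset. Growth fits regress burst
amplitude (mean within burst by default; peak also reported) on onset
elapsed time, linear or exponential (fit in log-amplitude, R² on the
native scale), optionally on interval means — the form in which the
published growth curves are plotted.

Because the threshold is a fixed quantile, only ~10% of samples can ever
be supra-threshold; with one burst per switch this caps detections at
roughly two to three per trial, concentrated on the late, largest
bursts. That is the expected regime, and the tempo-recovery check
(median onset-to-onset interval within 5% of each tempo) holds in it.

## Decoding

Features are mean gamma amplitude in 10 equal bins per maintenance
interval; with the go-cue at the middle of the 4th interval a trial has
35 bins. Trials with earlier go-cues contribute bins up to the cue
(attrition; zero-padding behind a flag). The classifier is logistic
regression with a quadratic penalty of 1e-4 on the slopes only (the
original specifies none; the penalty guarantees a unique optimum under
separation and is reported in metadata). Accuracy curves re-fit per time
bin — cumulative (bins 1..k) or sliding (k..k+4) — and score 100 random
held-out sets of 50 correct + 50 error trials; the spread is the s.e.
across iterations. Decoding is per tempo (pooled mode available). The
mean accuracy curve has bin-to-bin sampling fluctuation of ~0.01–0.02
beyond its nominal s.e. (held-out draws share one finite trial pool), so
monotonicity checks on it carry a 0.02 allowance.

## Spike–field analyses

Rates: 1 ms binning convolved with a Gaussian kernel (sd 25 ms; the
original does not state its smoother). Side preference: sign of the peak
of the normalized cross-correlogram between the concatenated
left-/right-start mean rates and the matching ±1 position signal.
Detrending subtracts the across-condition grand mean. The correct/error
lag analysis cross-correlates per-outcome *alternation components*
(preferred-start mean minus all-trials mean, computed within correct and
within error trials, averaged over units); the reported sign convention
is negative lag = error series delayed (lagging). Note that detrending
across only two conditions produces mirror-image traces whose
cross-correlation is degenerate — the alternation-component construction
avoids this.

STA: 200 ms LFP windows centered on each spike (snippets crossing the
recording edge are skipped and counted); the average is normalized
peak-to-valley to [0, 1] *before* spectral decomposition, so band powers
compare waveform shape across epochs regardless of the amplitude growth;
the raw average is retained for the attenuation law. Band powers are
bin-mean periodogram power over alpha 6–10, beta 15–24, gamma 30–40 Hz.
Statistics: fixed-effects condition (baseline/entrainment/maintenance) ×
band ANOVA with units as replicates, Bonferroni-corrected paired t-tests
of gamma power. The jitter control displaces each spike by
Uniform(−15, +15) ms (default one repeat; averaging repeats reduces the
noise floor) and multiplies the expected STA amplitude at frequency f by
|sinc(2 f h)| — at 35 Hz and h = 15 ms a 21× attenuation, i.e. the gamma
peak collapses to the incoherent floor. Spikes between go-cue and trial
end are excluded throughout (movement-related activity out of scope).

## Field–field coherence

Instantaneous phase: zero-phase 30–40 Hz band-pass, analytic-signal
argument. The phase-locking value of a pair is the modulus of the mean
unit phasor of the phase differences pooled over all trial time points.
Pairs are sorted by electrode distance (stable sort, ties broken by
channel index), split into 50 equal-count bins, and mean PLV is
regressed on mean distance; a negative slope indicates locally generated
fields. The seven-electrode geometry of the original array is not
published; the synthetic geometry (hexagonal, 350 µm spacing, or random
within a square) is configurable and recorded.

## Problem sizes and determinism

All generators and resampling procedures are pure functions of
(parameters, seed). The replication studies (`metronome.studies`) use:
mixed-tempo sessions of 960 trials for tempo recovery; 100 sessions of
192 equal-length trials per clock-bias configuration; 400 trials for the
decoder; 10⁴ spikes for the attenuation law; 100 replicates of 5000
trials for estimator coverage; 200 simulations per null-calibration
test. These sizes put Monte-Carlo error comfortably below the effects
being measured while keeping each study in the minutes range on one
core.

## Known limitations

- The hierarchical container stores LFP as float32 (ample for
  microvolt-scale signals); trial fields round-trip at float64.
- The permutation scheme and the burst-threshold pooling scope are
  concrete choices for procedures the original text leaves open; both
  are labelled in outputs.
- The exponential growth fit minimizes log-amplitude least squares, not
  native-scale least squares; R² is reported on the native scale.
- `attrition_mean` masks times beyond the design's maximum delay rather
  than extrapolating.
- No spike-field coherence spectra beyond the STA, no wavelet analysis
  beyond the envelope cross-check, no analysis above 80 Hz.
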