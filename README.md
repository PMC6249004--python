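# metronome

Analysis toolkit for **rhythm entrainment and maintenance in premotor
cortex recordings**. During a visual-metronome task — three visible
intervals of an alternating left/right stimulus (tempo T ∈ {500, 750,
1000} ms) followed by up to four internally-maintained intervals and a
go-cue — local field potentials in the supplementary motor area exhibit
low-gamma (30–40 Hz) bursts whose *timing* tracks the internally
maintained tempo and whose *amplitude* tracks total elapsed time. This
package implements that complete analysis chain for anyone studying
interval timing or beat maintenance in electrophysiological recordings,
together with a synthetic-session generator that reproduces the task's
statistical structure so every stage can be validated against ground
truth without any data download.

## What it computes

- **Behavior** — scalar-variability (Weber's-law) psychometrics: with
  subjective elapsed time t̂ ~ 𝒩(t/g, (w·t)²), the probability of
  reporting the correct side is the Gaussian parity mass
  p(t) = (1−λ)·P[⌊t̂/T⌋ ≡ ⌊t/T⌋ (mod 2)] + λ/2, fitted by binomial
  maximum likelihood; reaction-time regression on elapsed time.
- **Spectral** — sliding-window multitaper spectrograms (200 ms / 5 ms,
  one Slepian taper, 5 Hz bandwidth), per-trial baseline normalization,
  a seedable per-bin permutation test, and the single-trial gamma
  amplitude envelope (spectrogram band-average or analytic-signal).
- **Bursts** — events where the envelope exceeds the 90th percentile of
  pooled activity for ≥ 100 ms; onset sorting and alignment, switch vs
  mid-interval t-tests, onset-phase chi-squared homogeneity tests, and
  linear/exponential amplitude-growth fits.
- **Decoding** — logistic classification of correct vs error trials from
  binned gamma amplitude (10 bins/interval, 35 bins/trial), cumulative
  and sliding-window accuracy curves over 100 held-out 50+50 splits.
- **Spike–field** — kernel firing rates, side-preference via
  rate × stimulus-position cross-correlation, correct/error
  cross-correlogram lags (negative lag = errors lag the true tempo),
  spike-triggered-average LFP with peak-to-valley normalization, band
  powers, condition × band ANOVA, and a ±15 ms spike-jitter control
  obeying the |sinc(2fh)| attenuation law.
- **Coherence** — phase-locking value (mean resultant vector of 30–40 Hz
  phase differences) per electrode pair, binned into 50 equal-count
  distance bins and regressed on distance.
- **Synthesis** — trials, behavior, multi-channel LFP (1/f background +
  switch-locked growing gamma bursts with a distance-mixed shared
  carrier) and gamma-phase-locked Poisson spike trains, all pure
  functions of (parameters, seed), with a ground-truth sidecar.

## Worked example

```bash
python examples/01_behavioral_model.py
```

prints (seeds fixed in the script):

```
3600 trials, 90.1% correct overall
fitted Weber fraction w = 0.125 (95% CI 0.119-0.131), lapse = 0.015
  tempo 500 ms: P(correct) by interval = 0.99, 0.98, 0.88, 0.74
  tempo 750 ms: P(correct) by interval = 0.99, 0.98, 0.88, 0.74
  tempo 1000 ms: P(correct) by interval = 0.99, 0.98, 0.88, 0.74
RT slope = 11.4 ms/s, R^2 = 0.99
```

The generating Weber fraction was 0.12: the fit recovers it, accuracy
declines with elapsed maintenance time identically across tempos (the
scalar property — noise scales with *time*, not with interval count),
and reaction times rise ~11 ms per elapsed second. Next,

```bash
python examples/02_gamma_bursts.py
```

```
755 bursts on 360 trials (90th percentile, >=100 ms)
  tempo 500 ms: median inter-burst interval 537 ms (n=102)
  tempo 750 ms: median inter-burst interval 726 ms (n=159)
  tempo 1000 ms: median inter-burst interval 979 ms (n=222)
gamma at switches vs mid-interval: t = 15.5, p = 3.7e-45 (df 539)
```

The onset-to-onset intervals of detected gamma bursts recover each
tempo, and gamma amplitude is reliably higher at the (virtual) stimulus
switches than halfway between them — the neural metronome. The other
examples cover error decoding (`03`), spike–field coupling and the
jitter control (`04`), and coherence-vs-distance plus the end-to-end
stage runner (`05`).

A thin CLI wraps the stage runner for shell use:

```bash
metronome simulate spectrogram bursts behavior report \
    --in session.h5 --out results_dir --seed 7
```

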