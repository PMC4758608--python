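# Methods

This document describes the statistical model, the analysis pipeline, the
synthetic-data generator, and the numerical choices made in `thetawhisk`.
Every quantitative statement here refers to something the package computes;
nothing is asserted about real recordings.

## 1. Scientific setting

The package analyzes phase synchronization between three rhythmic signals
recorded during a whisker-guided discrimination task:

- a hippocampal local field potential (LFP) dominated by the theta rhythm
  (5–12 Hz),
- the whisking angle of the vibrissae, which oscillates in the same band, and
- spike trains of barrel-cortex neurons.

Each trial contains a stereotyped sequence of behavioral episodes — baseline,
approach toward the stimulus, whisker–stimulus touch, turn, and reward — and
ends with a binary outcome (correct / incorrect choice). The analysis asks:

1. Do LFP and whisking share a narrow-band spectral peak, and does its power
   change across episodes?
2. Does the phase synchronization between theta and whisking exceed chance,
   and does it increase from approach to touch?
3. Is the within-trial change in synchronization related to behavior
   (decision speed, outcome)?
4. Are cortical spikes phase-locked to theta, and does the proportion of
   locked neurons differ between episodes?

## 2. Data model

`data_model.py` defines the on-disk and in-memory representation:

- `ContinuousSignal` — uniformly sampled trace (samples, rate, start time).
- `SpikeTrain` — sorted spike times for one unit.
- `TrialEvents` — per-trial timestamps (trial start, approach onset, contact
  onset/offset, turn, reward) plus texture side and outcome.
- `SessionBundle` — LFP + whisking + spike trains + events (+ optional
  ground-truth table for synthetic sessions).

Sessions round-trip through HDF5 (`write_session` / `read_session`) with a
schema check that raises `SchemaError` on missing groups. `segment_episodes`
converts events into labeled `EpisodeWindow`s and rejects overlapping or
inverted windows; `waiting_windows` returns the inter-trial intervals that
avoid all trials.

## 3. Spectral analysis

- **Episode spectra** (`episode_spectrum`): Hann-tapered periodograms of
  equal-length episode windows, zero-padded onto a fixed 0.25 Hz frequency
  grid and averaged across windows. Equal lengths are required so that
  windows are exchangeable under shuffling.
- **Peak detection** (`peak_theta_frequency`): argmax of the averaged
  spectrum restricted to 5–12 Hz.
- **Normalization** (`normalize_power`): power expressed relative to a
  reference bin (e.g., 4 Hz) so that sessions with different absolute
  amplitudes are comparable.
- **Adaptive spectrogram** (`spectrogram_adaptive`): frequency-adaptive
  window length (a fixed number of cycles per estimate), normalized either
  as a ratio to a pre-contact baseline interval or left raw. Requesting a
  baseline interval outside the time grid is an error rather than silent
  NaN output.
- **Power randomization test** (`power_randomization_test`): two sets of
  windows are compared bin-by-bin by shuffling window labels; p-values use
  the add-one convention p = (k + 1) / (n_shuffles + 1) and are
  Bonferroni-corrected over frequency bins. With B shuffles the smallest
  attainable p is 1/(B + 1), so the shuffle count must exceed
  m/α − 1 for m bins at family-wise level α; the implementation warns when
  it cannot reach the corrected threshold.

## 4. Phase extraction and synchronization

- **Bandpass** (`bandpass_theta`): zero-phase (forward–backward) order-4
  Butterworth filter, 5–12 Hz, applied via second-order sections
  (`sosfiltfilt`) for numerical stability.
- **Instantaneous phase** (`instantaneous_phase`): analytic signal via the
  Hilbert transform. The signal is reflect-padded by 1 s at both ends before
  the FFT (length rounded up to `next_fast_len`) to suppress edge artifacts,
  then the padding is discarded. Phase 0 corresponds to the cosine peak.
- **Alignment** (`align_phase_to`): whisking phase is unwrapped, linearly
  interpolated onto the LFP time grid, and re-wrapped, so the two phase
  series share one clock.
- **Phase synchronization index** (PSI, `compute_psi`): the mean resultant
  length of the 1:1 phase difference,
  `PSI = |mean(exp(i(φ_theta − φ_whisk)))|`, with the circular mean of the
  difference reported as the phase delay. n:m locking is supported by
  integer multipliers on each phase.
- **Per-trial windows** (`per_trial_psi`): PSI is computed on fixed-length
  250 ms windows on every trial — the window immediately before contact
  onset ("approach") and immediately after it ("touch"). Using the same
  window length on all trials keeps the estimator bias (which depends on
  the number of samples) identical across trials; otherwise short-touch
  trials would receive upward-biased PSI values correlated with duration,
  contaminating the behavioral analysis.
- **Small-sample bias correction** (`psi_bias_correct`): optional
  transformation that maps the null expectation of the resultant length for
  n samples back toward zero.
- **Chance level** (`psi_chance_level`): the across-trial shuffle null.
  Trial pairings between theta windows and whisking windows are permuted by
  derangements (no window paired with itself), the mean PSI over trials is
  recomputed for each of the shuffle sets (default 2,000), and the chance
  level is the 97.5th percentile of that null distribution (a normal
  approximation is also available). This requires at least 10 trials and
  equal window lengths.

## 5. Behavioral coupling statistics

`trial_metrics` derives per-trial quantities: `psi_change = psi_touch −
psi_approach`, touch duration, and a normalized duration (duration divided
by the maximum over retained trials). Trials with touch durations outside
[0.15 s, 2.0 s] are flagged `excluded`. `psi_behavior_tests` then computes:

- Pearson correlation between `psi_change` and normalized touch duration
  (overall and per rat when a rat label is present),
- correct-vs-incorrect differences in touch-window PSI via a two-sample
  randomization test (`two_sample_randomization_test`): outcome labels are
  permuted, the difference of means is recomputed, and the add-one p-value
  is reported,
- group summaries after splitting trials at ±0.4/0.5 SD of `psi_change`.

`phase_delay_stats` takes the circular mean of per-trial touch phase delays
over trials whose PSI exceeds the chance level and tests its non-uniformity
with the Rayleigh test.

## 6. Spike phase-locking

`assign_spike_phases` samples the theta phase at each spike time within a
set of episode windows. For each unit and episode condition, `rayleigh_test`
(Z = 2nr², p = exp(−Z/2)) decides significance at α = 0.05, and
`fit_von_mises` estimates the preferred phase (circular mean) and
concentration κ by maximum likelihood (κ capped at 10³, where the
distribution is indistinguishable from a point mass at double precision).
`population_phase_summary` aggregates preferred phases over significantly
locked units; `two_proportion_ztest` compares the proportion of locked
neurons between conditions; `bootstrap_equal_size` resamples conditions to
a common neuron count to check that proportion differences are not sample
size artifacts.

## 7. Synthetic session generator

The generator (`synthetic.py`) produces sessions with known ground truth so
that every stage of the pipeline can be verified against planted values.

### 7.1 Oscillator model

Two phases evolve by Euler–Maruyama integration at the LFP rate (2 kHz):

```
dφx = 2π f_theta dt + σ dWx                                  (theta)
dφy = 2π f_whisk dt + ε(t) sin(φx − φy − lag) dt + σ dWy      (whisking)
```

a Kuramoto-style unidirectional sine pull on the whisking phase. The
coupling strength ε(t) and the oscillation amplitude are stepwise functions
of the behavioral episode (baseline: no coupling; approach: moderate;
touch: strongest). The LFP is `A·amp(t)·cos(φx)` plus 1/f (pink) background
noise; the whisking angle is an offset plus `amp(t)·cos(φy)` at its own
rate (1 kHz) plus pink noise. Spike trains are inhomogeneous Poisson with
von Mises phase modulation around the true theta phase.

Each trial occupies an independent 9 s block with fresh random initial
phases and its own child RNG stream (spawned from a `SeedSequence`), which
makes the across-trial shuffle null exactly exchangeable and every output
bit-reproducible per seed.

### 7.2 Measured-path planting of behavioral links

Trial durations and outcomes must correlate with the PSI *the analysis
measures*, not with a latent quantity the pipeline never sees. The
generator therefore proceeds in two passes per trial:

1. Integrate the "head" of the trial (through contact onset plus the 250 ms
   touch window plus padding), render the noisy LFP/whisking signals for
   that extent, and push them through the same path the pipeline uses —
   bandpass, Hilbert phase, interpolation onto the LFP grid, 250 ms PSI
   windows — yielding measured `psi_approach` and `psi_touch` per trial.
2. Plant the behavioral links on those measured values:
   touch durations are drawn so that `corr(psi_change, duration)` targets
   `behavior_r_target`, and outcome probabilities follow
   `P(correct) = base + psi_diff·sign(psi_touch − median)` style coupling
   via `plant_behavioral_link`. Then integrate each trial's tail from the
   stored boundary phase and assemble the full session, reusing the
   identical per-block noise so the session signals equal the plant-time
   signals over the head extent.

Two details are required for the planted correlation to survive the
pipeline:

- **Persistent contact gains.** The touch-episode coupling and amplitude
  gains are held over the full head extent (onset → onset + 250 ms +
  padding) regardless of the realized touch duration. If the gains switched
  off at touch offset, short-touch trials would have part of their
  measurement window in a low-coupling regime, creating a
  duration-correlated measurement error that attenuates the planted r.
- **Fixed-length analysis windows** (Section 4): duration-dependent window
  lengths would add duration-correlated estimator bias.

With both in place, the correlation between plant-time PSI and the
pipeline's recovered PSI change exceeds 0.999, and the planted behavioral
correlation is recovered within sampling error at study scale
(n = 915 trials).

The ground-truth table stored with each synthetic session includes the true
coupling parameters, the planted durations/outcomes, and the plant-time
measured PSI values (`psi_approach_meas`, `psi_touch_meas`).

### 7.3 Default parameters

| Parameter | Value | Meaning |
|---|---|---|
| `lfp_rate_hz` / `whisk_rate_hz` | 2000 / 1000 | sampling rates (Hz) |
| `f_theta_hz` / `f_whisk_hz` | 8.0 / 10.0 | center frequencies (Hz) |
| `f_theta_sd_hz` / `f_whisk_sd_hz` | 0.4 / 1.0 | trial-to-trial SD of center frequencies |
| `phase_noise_sd` | 5.5 | phase diffusion (rad/√s) |
| `coupling_eps` | 25.0 | base coupling strength (1/s) |
| `coupling_lag_rad` | 1.63 | planted theta→whisking phase lag |
| episode gains (amplitude / coupling) | baseline 1.0/0.0, approach 1.3/1.2, touch 1.6/2.0, turn 1.0/0.5, reward 0.8/0.0 | stepwise modulation |
| `kappa_gen`, `theta_gen` | 1.0, 2.9 | spike phase-locking concentration and preferred phase |
| `base_rate_hz`, `n_units` | 5.0, 4 | Poisson rate and unit count |
| `behavior_r_target` | 0.146 | planted PSI-change ↔ duration correlation |
| `p_correct_link` | base 0.75, psi_diff 0.05 | outcome coupling |
| `duration_mean_s` / `duration_sd_s` / clip | 0.54 / 0.224 / [0.05, 2.2] | touch-duration model |
| `trial_period_s` / `contact_lead_s` | 9.0 / 4.0 | trial block layout |
| `lfp_amp_uv` / `lfp_noise_sd` | 100 / 25 | LFP amplitude and pink-noise SD (µV) |
| `whisk_amp_deg` / offset / noise | 15 / 60 / 1.5 | whisking amplitude, set point, pink-noise SD (deg) |

## 8. Numerical and statistical choices

- Euler–Maruyama at 2 kHz (Δt = 0.5 ms) for phase integration; the
  stiffest term (ε up to 50/s at touch) gives εΔt ≤ 0.025, well inside the
  stability region. The integrator is JIT-compiled with numba.
- Pink noise is generated by FFT shaping (amplitude ∝ f^−1/2) with the
  variance normalized after shaping.
- All randomness flows from `numpy.random.Generator` objects seeded via
  `SeedSequence.spawn`; no global RNG state is used. Derived seeds are
  drawn below 2³¹.
- Randomization/shuffle tests use the add-one p-value
  p = (k + 1)/(B + 1), which is valid (never anti-conservative) and never
  exactly zero.
- Derangement shuffles for the PSI chance level exclude identity pairings
  so every shuffled set is a genuine mispairing.
- Filtering uses second-order sections throughout; transfer-function forms
  of an order-4 bandpass are ill-conditioned at 2 kHz.

## 9. Limitations

- The generator's oscillators are phase oscillators with sinusoidal
  waveforms; real theta and whisking are non-sinusoidal, so harmonic
  structure and waveform-asymmetry effects on Hilbert phase are not
  modeled.
- Coupling is unidirectional (theta → whisking) and stepwise in time;
  directionality measures and within-episode dynamics are out of scope.
- The outcome model couples accuracy to touch-window PSI through a single
  logistic-style offset; richer behavioral models (reaction-time
  distributions, learning across the session) are not simulated.
- Spike generation uses thinning of a rate function tied to the true phase;
  spike-sorting noise and bursting are not modeled.
- The PSI chance level assumes trials are exchangeable; slow non-stationarities
  spanning many trials would violate this and are absent by construction in
  the generator.
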