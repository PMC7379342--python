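# Methods

This note documents the models, estimators, conventions and design
decisions behind the package, and what the synthetic testbench does and
does not establish about real recordings.

## Artifact model and filter estimation

The recorded artifact is modelled as a linear, time-invariant map from the
N stimulation currents (µA) to the M recording channels (µV):
`y_m[k] = Σ_n (x_n ∗ h_nm)[k]`, with each electrode pair carrying its own
FIR impulse response `h_nm` of L taps.  Linearity is the load-bearing
assumption — it holds for passive tissue conduction and
capacitive/inductive pickup, and the `linearity` module provides the
scaling (peak-to-peak vs input amplitude) and additivity (response to
summed inputs vs summed responses) diagnostics to check it on data.

The filters minimise the mean squared prediction error via the normal
equations `(C_xx + ridge·I) ĥ = R_yx`.  Conventions, all configurable:

* **Lag layout** is channel-major (input 0 lags 0..L−1, input 1 lags
  0..L−1, …) and serialized with every filter bank.  Tap `lag0` multiplies
  the zero-lag sample; the default `lag0 = 0` is purely causal, matching
  the physics of the coupling, and a positive `lag0` absorbs
  recording-chain group delay.
* **Correlation estimates** are *biased* (divide by K) by default, which
  keeps `C_xx` positive semidefinite.  `C_xx` and `R_yx` are defined as the
  exact Gram products `ZᵀZ/K` and `ZᵀY/K` of the K-row lagged design matrix
  with zero padding outside the record; they are computed by FFT
  cross-correlation plus explicit corrections for the ≤ L−1 design rows
  that fall outside [0, K−1], never by materialising Z.  The familiar
  Toeplitz-block form is the large-K limit of this estimate; the edge terms
  are a small-K bias of order L/K.  The *unbiased* mode rescales entries by
  `K/(K−|Δlag|)` and is intended for diagnostics only.
* **Solver**: Cholesky factorization of `C_xx + ridge·I`, reused for all M
  right-hand sides (per-output and joint solves are therefore identical to
  float64 round-off).  If the matrix is not positive definite with
  `ridge = 0`, the solver either raises an error naming the input channels
  dominating the null space (`fallback=False`) or retries with automatic
  loading `1e-8·trace(C_xx)/NL` and, failing that, a least-squares
  pseudo-solve, with a warning.
* **Units**: filters carry µV/µA; estimation refuses a stimulus slot holding
  microvolts or a recording slot holding microamps.  Dimensionless signals
  are accepted everywhere (synthetic work).
* **Default L = 40 taps**, the standard single-channel filter order for
  these recordings; at 12 kHz that spans 3.3 ms of coupling memory.
* **Splits**: filters can be estimated on a training partition (first half,
  even trials, or arbitrary segment lists).  Each training segment is
  correlated as an independent zero-padded record and the sums pooled, so
  trial boundaries never leak across segments.

A trial-template control (`template_baseline`) subtracts one trial (or the
mean of the others) from a held-out trial of identical stimulation.  It
needs no linearity assumption but carries the trial noise of the template:
residual variance 2σ² for a single template, σ²(1 + 1/(T−1)) for a
T−1-trial mean template.  Both closed forms are verified in the tests.

## Spectral evaluation

All spectra are Welch average periodograms with a Kaiser window, defaults
β = 5, 256-sample segments (~21 ms at 12 kHz), 50% overlap (the overlap is
a package choice), one-sided density scaling without detrending so the PSD
integrates to the signal variance.

With two trials of identical stimulation, `y = y_n + y_a` and
`y′ = y_n′ + y_a`, the artifact `y_a` is shared and the neural components
are trial-varying, so

* noise (artifact) spectrum `Φ_noise = |Re CSD(y, y′)|` — the shared
  artifact makes the cross-spectrum real and positive in expectation; the
  real part is taken by default (`|CSD|` available);
* signal spectrum `Φ_signal = max(PSD(y) − Φ_noise, 0)` — the subtraction
  can go negative at noisy bins and is clipped at zero since spectra are
  nonnegative by definition (a small positive floor is available for dB
  reporting);
* `SNR = Φ_signal/Φ_noise`, clipped below at a configurable floor
  (default 1e-12) to keep dB finite;
* `ARR = Φ_noise,pre/Φ_noise,post`, equal to `SNR_post/SNR_pre` because the
  subtraction leaves the neural spectrum unchanged (identity verified to
  1e-10 in the tests).

For periodic pulse-train stimulation the artifact has power only at
harmonics of the pulse rate, so a harmonic mode samples the curves at the
FFT bins nearest `k·f0 ≤ fmax` (nearest bin, no interpolation).  Band
summaries average *linear* power ratios over the selected bins and convert
to dB (dB-domain averaging available behind a flag).

**Validity and floors.**  The noise-spectrum estimate assumes the shared
artifact dominates the trial-varying activity.  Two distinct failure modes
matter and are easy to conflate:

* *Bias* arises from neural activity that is correlated across trials
  (stimulus-locked evoked responses): it survives in the cross-spectrum and
  inflates the noise estimate by its own power, a contribution that is
  fixed in absolute terms and therefore shrinks relative to an increasingly
  dominant artifact.  The tests demonstrate this monotone shrinkage over
  artifact-to-neural ratios 10/100/1000 with an injected evoked component.
  With fully trial-independent activity the estimator is essentially
  unbiased at every ratio.
* *Variance* of the signal estimate grows with artifact dominance at fixed
  record length, because `PSD − CSD` becomes a small difference of large
  numbers (relative error ~ √(2·Φ_a/(Φ_n·N_seg)) per bin).  Consequently
  the per-bin SNR error is variance-dominated in long, clean recordings,
  and more artifact does not mean a better per-bin SNR estimate.

The shuffled-trial ARR additionally saturates at a *neural-variability
floor*: once the residual artifact falls below roughly the trial-varying
power divided by √N_seg, the post-removal cross-spectrum measures that
fluctuation floor rather than the residual, and the estimate stops tracking
the true attenuation.  The cross-module consistency test therefore runs in
a regime (25 training pulses) where the residual sits above the floor; with
generous training data the oracle ARR exceeds the shuffled estimate, and
only the oracle is meaningful.

## Stimulation generators

Every generator returns the sampled µA waveform *and* the event list that
produced it; rebuilding the waveform from the events reproduces it exactly,
and identical seeds give bit-identical programs.

* `monophasic_protocol` — 120 s of 0.5 Hz cathodic 0.2-ms pulses, six
  amplitudes (10–320 µA, octave steps) × 10 repeats in seed-controlled
  pseudo-random order.
* `ci_pulse_train` — bilateral 300-pulses/s trains of anode-leading
  triphasic pulses (three equal 40.96-µs phases — one sample per phase at
  the stimulator's native 24 414 Hz), 200 ms per train, optional Hanning
  amplitude envelope.  The interaural time difference is realised as an
  integer sample shift of the right channel (±40.96, ±81.9 and ±163.8 µs
  at 24 414 Hz for the nominal ±40/80/160 µs grid): the
  nominal microsecond grid is not representable at the hardware rate and
  the rounding is documented rather than hidden.
* `poisson_train` — exponential inter-pulse intervals at 16 Hz for 86 s,
  charge-balanced biphasic 164-µs / 40-µA pulses.
* `rqp_sequence` — random quad-pulse program: every 40 ms exactly 4 of 16
  channels fire concurrently (100 pulses/s average); amplitudes fixed at
  10 µA or drawn per pulse from 11 logarithmic steps spanning 0.1–10 µA
  (consecutive levels 10^0.2 ≈ 1.585 apart).  `count_rqp_conditions`
  reports the condition-space size C(n_channels, n_active) × amplitudes;
  the amplitude count is a parameter because fixed- and variable-amplitude
  variants of the protocol use different level sets.

Charge balance of the biphasic/triphasic kernels is exact by construction
(equal sample counts per phase), not approximate.

## Synthetic testbench

The benchmark composes, per trial, `composite = artifact + neural + noise`
with every component stored:

* **Coupling** kernels per electrode pair: single-tap gains, RC-style
  exponential decays `g·exp(−(k−d)/τ)`, damped random FIR, or a mix;
  per-pair parameters drawn from seeded streams (defaults: gains
  0.5–2 µV/µA, delays 0–4 samples, τ 2–6 samples, length ≤ 24–40 taps —
  coupling memory well under a millisecond, typical of electrode pickup).
* **Neural activity**: Poisson spikes of a fixed biphasic template
  (20 Hz, 80 µV default), LFP as low-passed Gaussian noise (150 Hz cutoff,
  50 µV RMS default), and optional first-difference-filtered Gaussian
  "hash" emulating unresolved multi-unit background; trials are mutually
  independent unless an evoked component is injected explicitly.
* **Measurement noise**: white Gaussian by default (the recording-noise
  spectrum is otherwise unconstrained); artifact-to-neural power ratios are
  realised by rescaling the neural components against the rendered artifact.

The artifact component is bit-identical across trials, which is exactly the
assumption the shuffled-trial estimators rely on.  What the testbench does
*not* emulate: electrode drift and impedance changes over time, amplifier
saturation, stimulus-locked evoked activity (unless injected), or neural
statistics beyond second order — so green tests here establish correctness
of the estimators under their stated assumptions, not robustness to every
failure mode of real hardware.

`evaluate_benchmark` sweeps the training-data length: for each length the
filters are re-estimated on the first portion of trial 0 and scored on
held-out data by relative tap RMSE against the true kernels and by the
*oracle* ARR — in-band true-artifact power over in-band residual-artifact
power, a band-integrated power ratio.  (Per-bin ratio curves are available
via `oracle_arr` but their band means are heavy-tailed, dominated by bins
where the residual happens to vanish.)  Under independent measurement
noise, least-squares error variance scales as 1/K, so the oracle ARR gains
3 dB per doubling of training length and the tap RMSE falls as K^(−1/2);
both are verified over seeds.  Heavy-tailed amplitude distributions (the
2-decade logarithmic RQP grid) concentrate the Fisher information in few
pulses and steepen the apparent finite-sample slopes; the scaling tests use
fixed-amplitude trains, where the asymptotics hold at desk scale.

## Problem sizes

The test suite runs single-input benchmarks at 12 kHz with 20–50 s records,
10 seeds for the scaling laws, and a 16×4-channel configuration for the
end-to-end pipeline; the acceptance script uses the full 2.5–160 s training
ladder (10 seeds) and 60–86 s realizations for the SNR and Poisson checks.
These sizes were chosen so every scaling regime (estimation-noise limited,
floor limited) is actually reached while a full run stays in the minutes
range on one CPU.

## Known limitations

* Zero-padded boundaries bias correlations and convolutions by O(L/K);
  irrelevant for records seconds long but visible in few-hundred-sample
  fixtures.
* The shuffled-trial SNR/ARR estimators inherit the floors described above;
  they cannot certify removal much beyond the neural-variability floor.
* No adaptive/recursive coefficient updating or real-time streaming: the
  filters are batch estimates, refit on demand.
* The CSV container carries no units metadata and infers the sampling rate
  from the time column; HDF5 is the lossless interchange format.
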