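# artifact — MIMO Wiener-filter removal of electrical-stimulation artifacts

Concurrent electrical stimulation and extracellular recording — cochlear
implants, deep-brain and peripheral-nerve stimulators, multi-site midbrain
arrays — produces stimulus-evoked voltage artifacts on the recording
electrodes that are often orders of magnitude larger than the neural signals
of interest.  Because the coupling between stimulation currents and recorded
artifacts is passive and linear (resistive/capacitive/inductive), the
artifact is *predictable* from the known current waveforms.  This package is
for electrophysiologists and BMI engineers who know the currents they
delivered and want the artifacts gone without distorting the neural signal.

## The method

Model the artifact on recording channel *m* as the sum over stimulation
channels *n* of the currents convolved with per-pair FIR impulse responses:

    y_m[k] = Σ_n (x_n ∗ h_nm)[k],   n = 1..N,  m = 1..M

Stacking the L taps of all N inputs, the minimum mean-squared-error filter
bank solves the Wiener–Hopf normal equations

    ĥ = C_xx⁻¹ R_yx

where `C_xx` (NL × NL) is the blockwise lagged covariance of the stimulation
channels and `R_yx` (NL × M) stacks the input–output cross-correlations.
The predicted artifact `ŷ = Σ_n x_n ∗ ĥ_nm` is then subtracted from the
recording.  One symmetric factorization serves all M outputs, so
per-channel and joint matrix solves are identical to machine precision.

Removal quality is quantified spectrally from two repeats of identical
stimulation: the artifact is reproducible across trials while neural
activity is not, so the between-trial cross-spectrum estimates the artifact
("noise") spectrum, `Φ_signal ≈ Φ_yy − |Re Φ_yy′|` estimates the neural
spectrum, and

    SNR(ω) = Φ_signal/Φ_noise,    ARR(ω) = Φ_noise,pre / Φ_noise,post

where the artifact reduction ratio (ARR) compares the artifact spectrum
before and after removal.  A ground-truth synthetic testbench (known
coupling kernels, trial-identical artifacts, independent neural + noise
components) validates the whole chain.

## Worked example

Sixteen-channel random quad-pulse stimulation (4 of 16 channels every
40 ms, 100 pulses/s) coupled into 4 recording channels through RC-decay
kernels, with trial-varying neural background 20 dB below the artifact:

```python
import numpy as np
from artifact import (
    CouplingModel, NeuralModel, WienerConfig, TrialPair,
    make_coupling_filters, simulate_recording, rqp_sequence,
    fit_and_clean, clean, noise_spectrum, snr_shuffled, band_average,
)

fs = 12000.0
stim = rqp_sequence(n_channels=16, n_active=4, duration=20.0, fs=fs, seed=0)
coupling = make_coupling_filters(16, 4, 24, CouplingModel(kind="rc_decay", seed=1), fs=fs)
ds = simulate_recording(stim, coupling, neural=NeuralModel(hash_rms_uv=20.0),
                        noise_sigma_uv=0.5, n_trials=2, seed=2,
                        artifact_to_neural_db=20.0)

fit = fit_and_clean(stim.signal, ds.composite[0], WienerConfig(L=40), split="halves")
cleaned_1 = clean(ds.composite[1], fit.predicted)

pre, post = TrialPair(ds.composite[0], ds.composite[1]), TrialPair(fit.cleaned, cleaned_1)
n_pre, n_post = noise_spectrum(pre), noise_spectrum(post)
sel = (n_pre.freqs >= 300) & (n_pre.freqs <= 6000)
arr_db = 10 * np.log10(n_pre.values[sel].sum(axis=0) / n_post.values[sel].sum(axis=0))
print("ARR per recording channel (dB):", np.round(arr_db, 1))
print("band SNR before removal (dB):", np.round(band_average(snr_shuffled(pre), 300, 6000), 1))
print("band SNR after removal  (dB):", np.round(band_average(snr_shuffled(post), 300, 6000), 1))
```

prints

```
ARR per recording channel (dB): [28.2 27.8 27.9 26.4]
band SNR before removal (dB): [-9.3 -9.4 -9.1 -8. ]
band SNR after removal  (dB): [24.  23.1 26.3 21.7]
```

i.e. the artifact power in the 300–6000 Hz analysis band drops by ~27 dB
and the recording flips from artifact-dominated (−9 dB SNR) to
signal-dominated (+23 dB).  The filters were estimated on the first half of
trial 0 only, so the trial-1 numbers are cross-validated.

An sklearn-style estimator wraps the same machinery for array-in/array-out
workflows:

```python
from artifact import WienerArtifactFilter
est = WienerArtifactFilter(n_taps=40).fit(X_stim, Y_rec)   # (K, N), (K, M)
residual = est.clean(X_stim, Y_rec)
```

A CLI mirrors the pipeline: `artifact simulate stim|bench`, `artifact
estimate`, `artifact clean`, `artifact evaluate`, `artifact linearity`,
`artifact benchmark`, `artifact run` (see `--help` on each).

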