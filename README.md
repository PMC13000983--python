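# prioshift

Analysis toolkit for EEG studies of **priority switching in visual working
memory**: when a retro-cue tells an observer which of two memorized oriented
bars is currently relevant, switching priority from one item to the other
carries a behavioral cost and a distinct oscillatory signature — increased
frontal theta (4–8 Hz) power and decreased central-parietal beta (15–25 Hz)
power, with the beta reduction scaling with the angular distance between the
two items and predicting how well the newly prioritized orientation can be
decoded from the EEG.

The package implements the full analysis chain for this paradigm and a
synthetic-data generator that plants each of these effects with known
magnitude, so every stage can be validated end to end without any recordings:

* **`prioshift.synth`** — task structure (128 blocks × 16 trials, two
  orientations per block from a 16-value grid at 11.25° spacing, never
  identical or orthogonal; cue-repeat run lengths 1–7 from a truncated
  geometric law), behavioral responses from the psychometric model, and
  61-channel epochs (−0.75 to +2.5 s around the cue, 250 Hz) with planted
  orientation tuning and condition-dependent theta/beta amplitudes.
* **`prioshift.behavior`** — psychometric model
  `P(cw | θ) = (1 − λ) Φ(θ; 0, σ) + λ` with lapse rate λ and inverse
  precision σ, the swap-extended variant
  `(1 − p_swap − λ) Φ(θ_cued) + p_swap Φ(θ_uncued) + λ`, bounded
  maximum-likelihood fitting (`PsychometricModel`, scikit-learn style),
  switch-cost summaries, item-distance slopes, and residualization.
* **`prioshift.spectral`** — spherical-spline surface Laplacian
  (`SurfaceLaplacian`), 5-cycle Hanning-taper time–frequency transform in dB
  (`HanningTFR`, 2–40 Hz, 40 ms steps), pre-cue (−0.75..−0.25 s) baseline
  correction, and named band/channel presets (beta @ central, theta @
  frontal, alpha @ posterior).
* **`prioshift.decoding`** — Mahalanobis-distance decoding of memorized
  orientations (`MahalanobisOrientationDecoder`): 17 posterior sensors × 37
  timepoints of a 450 ms backward window = 629 features, Ledoit–Wolf
  shrinkage noise covariance, 13-fold blockwise cross-validation, and the
  trial-wise score `decodingᵢ = Σⱼ cos(2θⱼ) D′ᵢⱼ` (cosine vector mean of the
  re-centered, sign-flipped 16-point tuning curve; flat curve → 0).
* **`prioshift.stats`** — per-participant z-scored (multiple) regression,
  one-sample/paired t-tests with Cohen's d, cluster-based sign-flip
  permutation correction, the 8-bin power-vs-decoding analysis, and one-way
  repeated-measures ANOVA with Greenhouse–Geisser correction.
* **`prioshift.pipeline`** — end-to-end synthetic-study runs (`prioshift
  simulate` CLI) and import of epochs/trial tables from files.

## Worked example

```python
import numpy as np
from prioshift import spectral, stats
from prioshift.decoding import crossval_decode
from prioshift.synth import SignalSpec, TaskConfig, simulate_dataset

trials, epochs = simulate_dataset(TaskConfig(n_blocks=16), SignalSpec(), seed=11)

csd = spectral.surface_laplacian(epochs)
tfr = spectral.baseline_db(spectral.tfr_hanning(
    csd, freqs=np.arange(14.0, 27.0),
    channels=spectral.BAND_PRESETS["beta"]["channels"]))
trials["beta_power"] = spectral.band_power(tfr, preset="beta")

sw = (trials["condition"] == "switch").to_numpy()
rep = trials["condition"].isin(["repeat1", "repeat2plus"]).to_numpy()
print("beta switch-repeat: %.2f dB"
      % (trials.loc[sw, "beta_power"].mean() - trials.loc[rep, "beta_power"].mean()))

scores = crossval_decode(epochs, trials, target="cued", timepoints=[1.0, 1.1, 1.2])
print("mean cued decoding score: %.1f" % scores["score"].mean())
```

prints

```
beta switch-repeat: -1.50 dB
mean cued decoding score: 4.0
```

The −1.5 dB is the planted beta desynchronization on switch trials recovered
through the CSD → TFR → baseline → band-power chain (default
`beta_switch_gain=0.15` plus the distance-dependent term), and the positive
decoding score means the post-probe tuning curves peak at the cued
orientation (the score's absolute scale is arbitrary; 0 is chance).

A full multi-participant report bundle (switch costs, psychometric fits,
cluster-corrected time–frequency contrasts, power→decoding regressions,
8-bin analysis) is produced by:

```bash
prioshift simulate --profile ci --seed 1 --out out/run
```

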