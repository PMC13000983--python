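# Methods

## The scientific setting

The package analyzes a two-item orientation working-memory task with frequent
retro-cued priority switches. Each block begins with the encoding of two
oriented bars; on every trial an auditory cue designates one of them as
relevant and a briefly flashed probe must be judged clockwise or
counterclockwise relative to the cued orientation. Because the next trial can
cue either item, observers must keep both orientations in memory throughout
the block. The quantities of interest are (a) the behavioral switch cost and
its dependence on the angular distance between the two items, (b) switch-
related changes in oscillatory power (frontal theta up, central-parietal beta
down), and (c) the trial-wise link between beta power and the decodability of
the newly prioritized orientation from posterior EEG sensors.

## Task and behavior model

**Orientation grids.** Memory orientations live on a 16-value grid
2.8125° + k·11.25° and probes on the interleaved grid 8.4375° + k·11.25°, so
probe offsets are never exactly 0. The two items of a block may be neither
identical nor orthogonal, which restricts the circular "item distance" to the
seven values 11.25°…78.75°. All angular arithmetic is 180°-periodic; tuning
computations double the angle.

**Cue sequence.** After each switch (and at block start), the current cue
repeats r times with r drawn from a geometric distribution truncated and
renormalized on {1..7}. The success parameter p = 0.40 was chosen once, by
matching the simulated proportions of switch / first-repeat / later-repeat
trials to the observed ≈0.28 : 0.33 : 0.39 split; it is a design constant,
not a fitted quantity.

**Balanced orientations.** By default the first item of successive blocks
cycles through shuffled permutations of the grid
(`TaskConfig.balanced_orientations`). At the full 128-block design this is
statistically indistinguishable from uniform draws; in scaled-down runs it
guarantees that all 16 orientation classes exist, which the decoder requires.
Uniform draws remain available via the flag.

**Psychometric model.** The probability of a clockwise response is
(1−λ)Φ(θ;0,σ)+λ, with θ the signed probe offset folded to (−90°, +90°], λ the
lapse rate and σ the inverse precision. This printed form is asymmetric
(asymptotes λ and 1); the conventional symmetric form (1−2λ)Φ+λ is available
via `symmetric_lapse=True`. The swap extension replaces a fraction p_swap of
comparisons with the offset to the uncued item, sharing a single σ. Note that
trial *accuracy* is condition-symmetric under either form, so the choice does
not affect accuracy-based summaries. Fitting maximizes the Bernoulli
likelihood with L-BFGS-B under box constraints (λ, p_swap ∈ [0, 0.5] — which
also enforces λ + p_swap ≤ 1 — and σ ∈ [1°, 90°]) from 10 starts (1 fixed +
9 random); μ is fixed at 0. Boundary solutions are flagged rather than
rejected: with degenerate data (e.g. one response category) σ is
unidentifiable and the flag is the signal.

**Generator defaults.** Per-condition behavioral parameters default to the
fitted values of the study this paradigm comes from (switch: λ=0.092,
σ=18.2°; repeat: λ=0.070, σ=17.6°; small, switch-elevated swap rates). Raw
simulated accuracies (~89%) are higher than the observed ~78–80% because the
synthetic probe offsets are uniform on the grid; the generator's conditions
are the stated parameter values, not the raw accuracy. Reaction times are
generator plumbing only: a shifted lognormal whose intercept and
item-distance slope depend on condition, with defaults chosen to mimic the
observed medians (~690 vs ~610 ms) and slopes (~22 vs ~6 ms per 10°).

## Synthetic epochs

Epochs are trials × 61 channels × 813 samples (−0.75 to +2.5 s, 250 Hz) in
units of the background-noise SD. The background is 24 independent 1/f
(α = 1) sources mixed through a random spatial matrix plus white sensor noise
(0.5 SD). Planted components:

* **Evoked orientation pattern** on the 17 posterior decoding sensors: channel
  c carries weight cos(2(θ − φ_c)) with participant-fixed random preferred
  angles φ_c, multiplied by a smooth random temporal waveform confined to a
  post-probe envelope (0.85–1.45 s). The uncued orientation adds an analogous
  pattern at half amplitude. With `uncued_shares_weights=True` (default) it
  uses the same spatial weights and waveform — i.e. the same representational
  format — which is what makes cross-decoding (train on cued, test on uncued)
  succeed; with independent weights cross-decoding collapses to chance.
* **Frontal theta**: a sustained 6 Hz sinusoid (random phase per trial) at the
  six frontal channels whose amplitude increases by `theta_switch_gain`
  (default 20%) on switch trials.
* **Central beta**: a tonic 20 Hz sinusoid at the nine central channels whose
  amplitude, inside a 0.2–1.0 s modulation window, is multiplied by
  (1 − switch·(g + s·distance))·J, with g = `beta_switch_gain` (0.15),
  s = `beta_distance_slope` (0.002 per degree) and J a lognormal trial jitter
  (σ = 0.2, mean 1). On switch trials the evoked-pattern amplitude is coupled
  to this beta factor with correlation `beta_decoding_coupling` (−0.3), the
  planted analog of "lower beta → better decoding".

Amplitudes were set so baseline-relative log-power changes are O(1 dB). With
all gains and the evoked SNR at zero the output is pure noise with no
condition differences.

## Spectral analysis

**Surface Laplacian.** Spherical-spline CSD after Perrin: interpolation
matrix G and Laplacian matrix H are truncated Legendre series (10 terms,
stiffness m = 4) over the cosines of inter-electrode angles on the unit
sphere; G is regularized with λ = 10⁻⁵ on the diagonal, the spline
coefficients are solved under a zero-sum constraint, and the result is scaled
by 1/conductivity (0.33 S/m). The whole estimate is a single channels ×
channels linear operator, so constant topographies map to zero and the output
is reference-free. Electrode coordinates come from the standard 10-20
template bundled with MNE, re-centered on the best-fitting sphere.

**Time–frequency transform.** Sliding-window complex demodulation with a
Hann taper spanning five cycles of each frequency (2–40 Hz, 1 Hz steps),
evaluated every 40 ms, normalized so a sinusoid of amplitude A yields linear
power A²/2, then converted to dB (10·log₁₀). Window positions whose 5-cycle
support does not fit inside the epoch are NaN rather than zero-padded, so
edge artifacts can never contaminate the −0.75..−0.25 s baseline. A
consequence worth knowing: at 4 Hz the 1.25 s half-window exceeds the
pre-cue interval, the baseline is undefined, and baselined 4 Hz power is NaN —
theta-band (4–8 Hz) summaries therefore effectively average 5–8 Hz. All
band/channel/window means are NaN-aware.

**Baseline.** Default is the dB mean over trials and baseline timepoints per
channel × frequency (condition-independent, so condition contrasts are
unchanged by baselining); a per-trial variant is available by flag.

## Decoding

At each decoding timepoint t (default 0.8–1.4 s after cue in 50 ms steps),
features are the 250 Hz samples at t, t−12 ms, …, decimated by 3 (83.3 Hz).
The span [t−450 ms, t] contains 38 such grid points; the 37 latest are kept
(earliest edge dropped) to give the canonical 37 × 17 = 629 features, demeaned
over the window within each sensor. Folds are 13 groups of contiguous blocks
(12 × 10 + 1 × 8 at 128 blocks). Per fold, the 16 orientation-mean patterns
and a Ledoit–Wolf shrinkage covariance of the class-mean residuals are
estimated from the training folds; Mahalanobis distances of each test trial to
the 16 means are re-centered on the trial's orientation, sign-flipped, and
reduced to the doubled-angle cosine vector mean. Distances are unsquared by
default (`squared=True` available; the cosine statistic is compatible with
either).

Two small-sample subtleties, relevant only to scaled-down designs:

* If an orientation is absent from the training folds its mean falls back to
  the mean over all available trials; any trial that would then be compared to
  a mean containing itself gets a leave-one-out corrected distance, so no
  information ever leaks.
* Because each block holds only two orientations, holding out blocks reduces
  the training count of the test trials' own class, which inflates the
  center-bin distance and biases scores slightly negative (≈ −0.3 a.u. at 16
  blocks, versus planted effects of ~10; decaying as 1/n and negligible at 128
  blocks). This is a property of the cross-validated distance estimator
  itself, not of this implementation; null-calibration tests therefore use
  trial tables with iid orientation labels, where the bias provably vanishes.

A related interaction affects the power→decoding analysis: when the uncued
item shares the cued item's representational format, its pattern contributes
to the cued tuning curve at the offset equal to the item distance, making the
cued score distance-dependent. Since beta power is also distance-dependent on
switch trials, the simple power–decoding correlation is confounded; the
package therefore estimates the coupling with the multiple regression
(power + item distance + interaction, all z-scored within participant), the
same control used in the original analysis.

## Group statistics

Per-participant effect maps (time, frequency, or time × frequency) are tested
with one-sample t-statistics per cell and corrected by cluster-based
sign-flip permutation: cells with two-sided p < .05 (configurable) form
4-connected clusters, cluster mass is the sum of t, and the null is the
maximum |mass| over random per-participant sign flips; corrected
p = (1 + #{null ≥ obs}) / (1 + n_perm), so 10,000 permutations give a floor
of ~10⁻⁴. Trial-level regressions z-score the outcome and every predictor
within participant (interaction terms are products of z-scored mains,
re-z-scored). The 8-bin analysis ranks trials by band power into equal-count
bins (remainder to the lowest bins) and tests the group slope of mean
decoding across bins. The one-way repeated-measures ANOVA reports the
sphericity-uncorrected F by default with a Greenhouse–Geisser option
(ε from the double-centered covariance, clamped to [1/(k−1), 1]), plus
partial η² = SS_effect/(SS_effect+SS_error); it is cross-checked against an
independent implementation in the test suite.

## Pipeline and problem sizes

`run_synthetic_study` simulates N independent participants (seeds spawned
from one master seed via `numpy.random.SeedSequence`) and runs: switch-cost
and psychometric summaries; cluster-corrected switch-vs-repeat
time–frequency contrasts at the central and frontal channel sets; band-power
× item-distance regressions and distance-level RM-ANOVAs; and power→decoding
regressions plus the 8-bin analysis for cued, uncued and cross targets. Two
profiles exist: `full` (43 participants × 128 blocks, 10,000 permutations,
decoding 0.8–1.4 s) matching the study scale, and `ci` (8 participants × 16
blocks, 1,000 permutations, decoding 1.0–1.2 s), the package's scaled-down
default used throughout the test suite; the tests themselves go down to 2–3
participants. Report bundles contain no wall-clock information (timestamps go
to stderr), so a fixed master seed reproduces every output byte for byte.

## What the synthetic data do and do not show

The generator plants linear, well-separated effects with Gaussian-ish mixed
1/f noise, stationary tuning patterns, and no artifacts, eye movements,
channel loss, or inter-trial dependence. Passing tests therefore demonstrate
that the analysis chain recovers effects of the hypothesized form with
correct sign, monotone magnitude, calibrated false-positive rates and no
information leakage — not that real EEG satisfies those assumptions, and not
the anatomical or physiological validity of the planted sources. Raw-EEG
cleaning (filtering, artifact rejection, ICA) is out of scope; imported data
are assumed preprocessed and epoched.
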