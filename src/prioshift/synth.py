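"""Synthetic task, behavior, and EEG-epoch generator.

The generator emulates a two-item orientation working-memory task with
frequent retro-cue priority switches: 128 blocks of 16 trials, two memorized
orientations per block drawn from a 16-value grid (11.25-degree spacing, never
identical or orthogonal), auditory cue repeats drawn from a truncated
geometric run-length distribution (1-7 repeats), and a clockwise /
counterclockwise probe judgment against the cued orientation.

Multichannel epochs (-0.75 to +2.5 s around cue, 250 Hz, 61-channel 10-20
montage) contain, on top of mixed 1/f + white noise:

* an orientation-tuned evoked pattern on posterior sensors carrying the cued
  (and, more weakly, the uncued) orientation in a post-probe time window;
* a frontal 6 Hz (theta) oscillation whose amplitude increases on switch
  trials;
* a central 20 Hz (beta) oscillation whose amplitude decreases on switch
  trials, more so the larger the angular distance between the two items, with
  trial-level lognormal amplitude jitter; on switch trials the evoked-pattern
  amplitude is coupled to the trial's beta amplitude with a configurable
  (negative by default) correlation.

All randomness flows through per-call integer seeds; the same seed reproduces
tables and epochs bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .circstats import circ_dist_180, fold_offset
from .containers import CONDITIONS, EpochSet
from .montage import CHANNELS_61, CENTRAL_CHANNELS, DECODING_CHANNELS, FRONTAL_CHANNELS, channel_indices, channel_positions

ORIENTATION_GRID = 2.8125 + 11.25 * np.arange(16)
PROBE_GRID = 8.4375 + 11.25 * np.arange(16)


def truncated_geometric_pmf(p: float = 0.40, support: tuple[int, int] = (1, 7)) -> np.ndarray:
    """Truncated, renormalized geometric pmf over repeat-run lengths.

    A "modified exponential" run-length law with hard minimum/maximum; p=0.40
    reproduces the observed switch : repeat1 : repeat2+ trial-count ratio
    (~0.28 : 0.33 : 0.39) to within a percentage point.
    """
    lo, hi = support
    k = np.arange(lo, hi + 1)
    pmf = p * (1 - p) ** (k - lo)
    return pmf / pmf.sum()


@dataclass
class TaskConfig:
    """Task-structure parameters (defaults reproduce the study design)."""

    n_blocks: int = 128
    trials_per_block: int = 16
    orientation_grid: np.ndarray = field(default_factory=lambda: ORIENTATION_GRID.copy())
    probe_grid: np.ndarray = field(default_factory=lambda: PROBE_GRID.copy())
    repeat_run_distribution: np.ndarray = field(default_factory=truncated_geometric_pmf)
    min_repeats: int = 1
    max_repeats: int = 7
    cue_soa: float = 0.8          # cue -> probe, seconds
    iti_range: tuple[float, float] = (0.4, 0.9)
    iti_mean: float = 0.55        # truncated-exponential mean, seconds
    exclude_identical_orthogonal: bool = True
    #: Cycle the first item of successive blocks through shuffled repetitions
    #: of the orientation grid. Statistically indistinguishable from uniform
    #: draws at 128 blocks but guarantees every orientation occurs in scaled-
    #: down runs, which the 16-class decoder requires.
    balanced_orientations: bool = True
    rng_seed: int | None = None

    def validate(self) -> None:
        grid = np.asarray(self.orientation_grid, dtype=float)
        probes = np.asarray(self.probe_grid, dtype=float)
        for name, g in (("orientation_grid", grid), ("probe_grid", probes)):
            if len(np.unique(np.mod(g, 180.0))) != len(g) or np.any(g < 0) or np.any(g >= 180):
                raise ValueError(f"{name} must hold distinct values in [0, 180)")
        pmf = np.asarray(self.repeat_run_distribution, dtype=float)
        if pmf.size != self.max_repeats - self.min_repeats + 1 or not np.isclose(pmf.sum(), 1.0):
            raise ValueError("repeat_run_distribution must sum to 1 over its support")
        if np.any(pmf < 0):
            raise ValueError("repeat_run_distribution must be non-negative")
        if self.n_blocks < 1 or self.trials_per_block < 2:
            raise ValueError("need at least 1 block of at least 2 trials")
        if self.exclude_identical_orthogonal and not admissible_pairs(grid).any():
            raise ValueError("orientation grid admits no item pair under the exclusion constraint")


def admissible_pairs(grid: np.ndarray) -> np.ndarray:
    """Boolean matrix of orientation pairs that are neither identical nor orthogonal."""
    d = circ_dist_180(grid[:, None], grid[None, :])
    return ~(np.isclose(d, 0.0) | np.isclose(d, 90.0))


def generate_task(config: TaskConfig | None = None, seed: int | None = None) -> pd.DataFrame:
    """Generate the per-trial task table (no behavior yet).

    Columns follow :data:`prioshift.containers.TRIAL_COLUMNS`; ``response``,
    ``correct`` and ``rt_ms`` are filled by :func:`simulate_responses`.
    """
    config = config or TaskConfig()
    config.validate()
    if seed is None:
        seed = config.rng_seed
    rng = np.random.default_rng(seed)
    grid = np.asarray(config.orientation_grid, dtype=float)
    probes = np.asarray(config.probe_grid, dtype=float)
    ok = admissible_pairs(grid) if config.exclude_identical_orthogonal else np.ones((len(grid),) * 2, bool)
    run_lengths = np.arange(config.min_repeats, config.max_repeats + 1)

    if config.balanced_orientations:
        n_rep = int(np.ceil(config.n_blocks / len(grid)))
        first_items = np.concatenate([rng.permutation(len(grid)) for _ in range(n_rep)])
    else:
        first_items = rng.integers(len(grid), size=config.n_blocks)

    rows = []
    for block in range(config.n_blocks):
        ia = int(first_items[block])
        ib = rng.choice(np.flatnonzero(ok[ia]))
        theta = {0: grid[ia], 1: grid[ib]}
        dist = circ_dist_180(theta[0], theta[1])

        # Cue sequence: runs of identical cues; every run after the first
        # starts with a switch trial followed by r ~ repeat_run_distribution
        # repeats. The block's first run is the block-start trial plus r repeats.
        cues: list[int] = []
        item = int(rng.integers(2))
        first = True
        while len(cues) < config.trials_per_block:
            r = int(rng.choice(run_lengths, p=np.asarray(config.repeat_run_distribution, dtype=float)))
            if not first:
                item = 1 - item
            first = False
            cues.extend([item] * (1 + r))
        cues = cues[: config.trials_per_block]

        for t_idx, cue in enumerate(cues):
            if t_idx == 0:
                cond = "block_start"
            elif cue != cues[t_idx - 1]:
                cond = "switch"
            elif t_idx == 1 or cues[t_idx - 2] != cue:
                cond = "repeat1"
            else:
                cond = "repeat2plus"
            probe = float(rng.choice(probes))
            rows.append(
                dict(
                    block_id=block,
                    trial_in_block=t_idx,
                    cued_item="A" if cue == 0 else "B",
                    condition=cond,
                    theta_cued=theta[cue],
                    theta_uncued=theta[1 - cue],
                    item_distance=dist,
                    probe=probe,
                    probe_offset=fold_offset(probe - theta[cue]),
                    response=pd.NA,
                    correct=pd.NA,
                    rt_ms=np.nan,
                )
            )
    trials = pd.DataFrame(rows)
    trials["condition"] = pd.Categorical(trials["condition"], categories=CONDITIONS)
    return trials


# ---------------------------------------------------------------------------
# Behavioral responses


@dataclass
class RTModel:
    """Shifted-lognormal reaction-time generator (plumbing for RT analyses).

    ``rt = intercept[cond] + slope[cond] * item_distance + LogNormal(median, sigma)``
    in milliseconds. Defaults roughly match the observed condition medians and
    distance slopes (e.g. switch RTs ~80 ms slower, ~22 ms per 10 degrees).
    """

    intercept_ms: dict = field(
        default_factory=lambda: {"switch": 392.0, "repeat1": 389.0, "repeat2plus": 377.0, "block_start": 389.0}
    )
    slope_ms_per_deg: dict = field(
        default_factory=lambda: {"switch": 2.25, "repeat1": 0.59, "repeat2plus": 0.59, "block_start": 0.59}
    )
    lognormal_median_ms: float = 200.0
    lognormal_sigma: float = 0.35


DEFAULT_BEHAVIOR_PARAMS = {
    # Fitted psychometric values from the study: switch trials show a higher
    # lapse rate at comparable precision; swap rates are small and elevated on
    # switches.
    "switch": dict(lapse=0.092, sigma=18.2, p_swap=0.04),
    "repeat1": dict(lapse=0.070, sigma=17.6, p_swap=0.02),
    "repeat2plus": dict(lapse=0.070, sigma=17.6, p_swap=0.02),
    "block_start": dict(lapse=0.070, sigma=17.6, p_swap=0.02),
}


def simulate_responses(
    trials: pd.DataFrame,
    params_by_condition: dict | None = None,
    rt_model: RTModel | None = None,
    seed: int | None = None,
    symmetric_lapse: bool = False,
) -> pd.DataFrame:
    """Draw clockwise/counterclockwise responses from the psychometric model.

    The clockwise probability is the swap-extended psychometric function
    evaluated at the probe's offsets to the cued and uncued orientations; RTs
    come from :class:`RTModel`. Returns a copy of ``trials`` with ``response``,
    ``correct`` and ``rt_ms`` filled.
    """
    from .behavior import PsychometricParams, psychometric_predict

    params_by_condition = params_by_condition or DEFAULT_BEHAVIOR_PARAMS
    rt_model = rt_model or RTModel()
    conds = trials["condition"].unique()
    missing = [c for c in conds if str(c) not in params_by_condition]
    if missing:
        raise ValueError(f"no psychometric parameters for conditions: {missing}")

    rng = np.random.default_rng(seed)
    out = trials.copy()
    theta_c = out["probe_offset"].to_numpy(dtype=float)
    theta_u = fold_offset(out["probe"].to_numpy(dtype=float) - out["theta_uncued"].to_numpy(dtype=float))

    p_cw = np.empty(len(out))
    for cond in conds:
        raw = params_by_condition[str(cond)]
        params = raw if isinstance(raw, PsychometricParams) else PsychometricParams(**raw)
        m = (out["condition"] == cond).to_numpy()
        p_cw[m] = psychometric_predict(theta_c[m], theta_u[m], params, symmetric_lapse=symmetric_lapse)

    cw = rng.random(len(out)) < p_cw
    out["response"] = np.where(cw, "cw", "ccw")
    out["correct"] = cw == (theta_c > 0)
    cond_str = out["condition"].astype(str)
    icpt = cond_str.map(rt_model.intercept_ms).to_numpy(dtype=float)
    slope = cond_str.map(rt_model.slope_ms_per_deg).to_numpy(dtype=float)
    noise = rng.lognormal(np.log(rt_model.lognormal_median_ms), rt_model.lognormal_sigma, len(out))
    out["rt_ms"] = icpt + slope * out["item_distance"].to_numpy(dtype=float) + noise
    return out


# ---------------------------------------------------------------------------
# Synthetic epochs


@dataclass
class SignalSpec:
    """Parameters of the synthetic multichannel signal.

    Amplitudes are in units of the background-noise standard deviation. Gains
    are fractional amplitude changes on switch trials; ``beta_distance_slope``
    is an additional fractional decrease per degree of item distance on switch
    trials. ``beta_decoding_coupling`` is the correlation planted, on switch
    trials, between the trial's beta amplitude factor and the evoked-pattern
    amplitude (negative: weaker beta, stronger orientation signal).
    """

    sfreq: float = 250.0
    tmin: float = -0.75
    tmax: float = 2.5
    channels: tuple[str, ...] = CHANNELS_61
    tuning_channels: tuple[str, ...] = DECODING_CHANNELS
    theta_channels: tuple[str, ...] = FRONTAL_CHANNELS
    beta_channels: tuple[str, ...] = CENTRAL_CHANNELS
    evoked_snr: float = 0.7
    uncued_snr_ratio: float = 0.5
    uncued_shares_weights: bool = True
    theta_freq: float = 6.0
    beta_freq: float = 20.0
    theta_amp: float = 1.0
    beta_amp: float = 1.0
    theta_switch_gain: float = 0.2
    beta_switch_gain: float = 0.15
    beta_distance_slope: float = 0.002
    beta_decoding_coupling: float = -0.3
    beta_jitter_sigma: float = 0.2
    snr_jitter_sd: float = 0.4
    noise_alpha: float = 1.0
    n_noise_sources: int = 24
    noise_amp: float = 1.0
    white_noise_amp: float = 0.5
    probe_time: float = 0.8
    rng_seed: int | None = None

    def validate(self) -> None:
        if self.sfreq <= 0 or self.tmax <= self.tmin:
            raise ValueError("invalid sampling rate or epoch window")
        for name in ("theta_amp", "beta_amp", "evoked_snr", "noise_amp", "white_noise_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        max_drop = self.beta_switch_gain + self.beta_distance_slope * 78.75
        if max_drop > 1.0:
            raise ValueError("beta switch gain + distance slope would produce negative amplitudes")
        if not -1.0 <= self.beta_decoding_coupling <= 1.0:
            raise ValueError("beta_decoding_coupling must be a correlation in [-1, 1]")
        for subset in (self.tuning_channels, self.theta_channels, self.beta_channels):
            channel_indices(self.channels, subset)  # raises on mismatch


def _smooth_window(times: np.ndarray, start: float, stop: float, ramp: float) -> np.ndarray:
    """Trapezoid with raised-cosine ramps; 1 on [start+ramp, stop-ramp], 0 outside."""
    w = np.zeros_like(times)
    up = (times >= start) & (times < start + ramp)
    flat = (times >= start + ramp) & (times <= stop - ramp)
    down = (times > stop - ramp) & (times <= stop)
    w[up] = 0.5 - 0.5 * np.cos(np.pi * (times[up] - start) / ramp)
    w[flat] = 1.0
    w[down] = 0.5 + 0.5 * np.cos(np.pi * (times[down] - (stop - ramp)) / ramp)
    return w


def _pink_noise(rng: np.random.Generator, shape: tuple, n_samples: int, sfreq: float, alpha: float) -> np.ndarray:
    """1/f^alpha noise, unit variance, shape + (n_samples,)."""
    freqs = np.fft.rfftfreq(n_samples, 1.0 / sfreq)
    gain = np.zeros_like(freqs)
    gain[1:] = freqs[1:] ** (-alpha / 2.0)
    spec = (rng.standard_normal(shape + (freqs.size,)) + 1j * rng.standard_normal(shape + (freqs.size,))) * gain
    x = np.fft.irfft(spec, n=n_samples, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def generate_epochs(trials: pd.DataFrame, spec: SignalSpec | None = None, seed: int | None = None) -> EpochSet:
    """Generate synthetic epochs carrying the planted effects for ``trials``."""
    spec = spec or SignalSpec()
    spec.validate()
    if len(trials) == 0:
        raise ValueError("trial table is empty")
    if seed is None:
        seed = spec.rng_seed
    rng = np.random.default_rng(seed)

    n_trials = len(trials)
    n_t = int(round((spec.tmax - spec.tmin) * spec.sfreq)) + 1
    times = spec.tmin + np.arange(n_t) / spec.sfreq
    n_ch = len(spec.channels)
    tune_idx = channel_indices(spec.channels, spec.tuning_channels)
    theta_idx = channel_indices(spec.channels, spec.theta_channels)
    beta_idx = channel_indices(spec.channels, spec.beta_channels)

    is_switch = (trials["condition"] == "switch").to_numpy()
    dist = trials["item_distance"].to_numpy(dtype=float)
    theta_cued = np.deg2rad(trials["theta_cued"].to_numpy(dtype=float))
    theta_uncued = np.deg2rad(trials["theta_uncued"].to_numpy(dtype=float))

    # --- background noise: mixed 1/f sources + white sensor noise
    sources = _pink_noise(rng, (n_trials, spec.n_noise_sources), n_t, spec.sfreq, spec.noise_alpha)
    mixing = rng.standard_normal((n_ch, spec.n_noise_sources)) / np.sqrt(spec.n_noise_sources)
    data = np.einsum("cs,tsn->tcn", mixing, sources) * spec.noise_amp
    data += spec.white_noise_amp * rng.standard_normal((n_trials, n_ch, n_t))

    # --- trial-level beta amplitude factor and coupled evoked amplitude
    jitter = rng.lognormal(-0.5 * spec.beta_jitter_sigma**2, spec.beta_jitter_sigma, n_trials)
    beta_factor = (1.0 - is_switch * (spec.beta_switch_gain + spec.beta_distance_slope * dist)) * jitter

    snr_mult = np.ones(n_trials)
    if spec.snr_jitter_sd > 0 and spec.evoked_snr > 0:
        eps = rng.standard_normal(n_trials)
        snr_mult = 1.0 + spec.snr_jitter_sd * eps
        rho = spec.beta_decoding_coupling
        if rho != 0 and is_switch.sum() >= 3:
            b = beta_factor[is_switch]
            z = (b - b.mean()) / (b.std() or 1.0)
            snr_mult[is_switch] = 1.0 + spec.snr_jitter_sd * (rho * z + np.sqrt(1 - rho**2) * eps[is_switch])
        snr_mult = np.clip(snr_mult, 0.05, None)

    # --- evoked orientation-tuned patterns (post-probe window)
    if spec.evoked_snr > 0:
        env = _smooth_window(times, spec.probe_time + 0.05, spec.probe_time + 0.65, 0.15)
        phi_cued = rng.uniform(0, np.pi, len(tune_idx))
        phi_uncued = phi_cued if spec.uncued_shares_weights else rng.uniform(0, np.pi, len(tune_idx))

        def waveforms() -> np.ndarray:
            w = gaussian_filter1d(rng.standard_normal((len(tune_idx), n_t)), sigma=8, axis=-1, mode="constant")
            w *= env
            rms = np.sqrt(np.mean(w[:, env > 0.5] ** 2, axis=-1, keepdims=True))
            rms[rms == 0] = 1.0
            return w / rms

        w_cued = waveforms()
        # Sharing the representational format means sharing both the spatial
        # weights and the temporal profile; otherwise the uncued pattern lives
        # in an independent subspace and cross-decoding stays at chance.
        w_uncued = w_cued if spec.uncued_shares_weights else waveforms()
        amp_cued = spec.evoked_snr * snr_mult
        pat_cued = np.cos(2.0 * (theta_cued[:, None] - phi_cued[None, :]))
        data[:, tune_idx, :] += (amp_cued[:, None] * pat_cued)[:, :, None] * w_cued[None, :, :]
        amp_unc = spec.evoked_snr * spec.uncued_snr_ratio
        pat_unc = np.cos(2.0 * (theta_uncued[:, None] - phi_uncued[None, :]))
        data[:, tune_idx, :] += (amp_unc * pat_unc)[:, :, None] * w_uncued[None, :, :]

    # --- frontal theta: sustained post-cue, amplitude up on switches
    if spec.theta_amp > 0:
        env_theta = _smooth_window(times, 0.0, float(times[-1]), 0.15)
        phase = rng.uniform(0, 2 * np.pi, n_trials)
        amp = spec.theta_amp * (1.0 + spec.theta_switch_gain * is_switch)
        wave = amp[:, None] * np.sin(2 * np.pi * spec.theta_freq * times[None, :] + phase[:, None]) * env_theta
        data[:, theta_idx, :] += wave[:, None, :]

    # --- central beta: tonic throughout, amplitude modulated in the cue period
    if spec.beta_amp > 0:
        w_b = _smooth_window(times, 0.2, 1.0, 0.2)
        phase = np.asarray(rng.uniform(0, 2 * np.pi, n_trials))
        carrier = np.sin(2 * np.pi * spec.beta_freq * times[None, :] + phase[:, None])
        amp_t = spec.beta_amp * (1.0 + (beta_factor[:, None] - 1.0) * w_b[None, :])
        data[:, beta_idx, :] += (amp_t * carrier)[:, None, :]

    return EpochSet(
        data=data.astype(np.float32),
        times=times,
        sfreq=spec.sfreq,
        channels=spec.channels,
        positions=channel_positions(spec.channels),
        csd_applied=False,
    )


def simulate_dataset(
    task_config: TaskConfig | None = None,
    signal_spec: SignalSpec | None = None,
    params_by_condition: dict | None = None,
    rt_model: RTModel | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, EpochSet]:
    """One participant's full dataset: task table with behavior, plus epochs."""
    ss = np.random.SeedSequence(seed)
    s_task, s_resp, s_epoch = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3))
    trials = generate_task(task_config, seed=s_task)
    trials = simulate_responses(trials, params_by_condition, rt_model, seed=s_resp)
    epochs = generate_epochs(trials, signal_spec, seed=s_epoch)
    return trials, epochs
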