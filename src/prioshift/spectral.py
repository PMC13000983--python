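"""Surface-Laplacian preprocessing and Hanning-taper time-frequency analysis.

The surface Laplacian (current-source density, CSD) is estimated with
spherical splines: scalp potentials are interpolated with spline basis
functions g(cos angle) built from a truncated Legendre series, and the CSD is
the corresponding surface Laplacian h-series applied to the spline
coefficients. Defaults: 10 Legendre terms ("degree"), stiffness m=4,
regularization lambda=1e-5 on the diagonal of G, conductivity 0.33 S/m as an
overall scale.

Time-frequency power uses a sliding Hann-tapered complex demodulation with a
window of five cycles per frequency, normalized so a pure sinusoid of
amplitude A yields linear power A^2/2 at its frequency. Power is expressed as
10*log10 (dB); window positions whose 5-cycle support does not fit inside the
epoch are NaN, so that the pre-cue baseline is never contaminated by edge
effects.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from numpy.polynomial import legendre as npleg
from scipy.signal import fftconvolve
from scipy.signal.windows import hann
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import EpochSet, TFRSet
from .montage import CENTRAL_CHANNELS, FRONTAL_CHANNELS, POSTERIOR_ALPHA_CHANNELS

__all__ = [
    "SurfaceLaplacian",
    "surface_laplacian",
    "HanningTFR",
    "tfr_hanning",
    "baseline_db",
    "band_power",
    "BAND_PRESETS",
]

#: Named band / channel-set / time-window presets used throughout the analyses.
BAND_PRESETS = {
    "beta": dict(band=(15.0, 25.0), channels=CENTRAL_CHANNELS, time_window=(0.4, 0.8)),
    "theta": dict(band=(4.0, 8.0), channels=FRONTAL_CHANNELS, time_window=(0.4, 0.8)),
    "alpha": dict(band=(8.0, 14.0), channels=POSTERIOR_ALPHA_CHANNELS, time_window=(0.4, 0.8)),
}


def _legendre_series(x: np.ndarray, n_terms: int, exponent: float) -> np.ndarray:
    """sum_{n=1..N} (2n+1) / (n(n+1))^exponent * P_n(x), divided by 4 pi."""
    n = np.arange(1, n_terms + 1, dtype=float)
    coef = np.zeros(n_terms + 1)
    coef[1:] = (2 * n + 1) / (n * (n + 1)) ** exponent
    return npleg.legval(np.clip(x, -1.0, 1.0), coef) / (4 * np.pi)


class SurfaceLaplacian(BaseEstimator, TransformerMixin):
    """Spherical-spline current-source-density transformer.

    Parameters: ``n_legendre`` (spline degree, number of Legendre terms),
    ``stiffness`` (m of the spline), ``lambda_reg`` (ridge added to the
    diagonal of G) and ``conductivity`` (S/m, overall scale). ``fit`` builds
    the linear CSD operator from the montage positions; ``transform`` applies
    it sample-wise.
    """

    def __init__(self, n_legendre: int = 10, stiffness: int = 4,
                 lambda_reg: float = 1e-5, conductivity: float = 0.33):
        self.n_legendre = n_legendre
        self.stiffness = stiffness
        self.lambda_reg = lambda_reg
        self.conductivity = conductivity

    def fit(self, epochs: EpochSet, y=None):
        if epochs.positions is None:
            raise ValueError("EpochSet has no channel positions")
        if len(epochs.channels) < 32:
            raise ValueError("surface Laplacian needs >= 32 channels")
        pos = np.asarray(epochs.positions, dtype=float)
        pos = pos / np.linalg.norm(pos, axis=1, keepdims=True)
        cosang = pos @ pos.T
        if np.any(cosang[~np.eye(len(pos), dtype=bool)] > 1 - 1e-10):
            raise ValueError("duplicate channel positions")
        G = _legendre_series(cosang, self.n_legendre, float(self.stiffness))
        H = _legendre_series(cosang, self.n_legendre, float(self.stiffness) - 1.0)
        n = len(pos)
        Gs = G + self.lambda_reg * np.eye(n)
        Gi = np.linalg.inv(Gs)
        # Spline coefficients c solve Gs c + c0 = V with sum(c) = 0; the
        # constrained solve is linear in V, so the whole CSD map is one matrix.
        gi_sum = Gi.sum(axis=1)
        total = gi_sum.sum()
        C = Gi - np.outer(gi_sum, gi_sum) / total  # V -> c
        self.operator_ = (H @ C) / self.conductivity
        self.n_channels_ = n
        return self

    def transform(self, epochs: EpochSet) -> EpochSet:
        if epochs.csd_applied:
            raise ValueError("surface Laplacian already applied")
        if epochs.data.shape[1] != self.n_channels_:
            raise ValueError("channel count mismatch with fitted operator")
        n_tr, n_ch, n_t = epochs.data.shape
        flat = epochs.data.astype(np.float64).transpose(1, 0, 2).reshape(n_ch, -1)
        out = (self.operator_ @ flat).reshape(n_ch, n_tr, n_t).transpose(1, 0, 2)
        return replace(epochs, data=out.astype(epochs.data.dtype), csd_applied=True)


def surface_laplacian(epochs: EpochSet, **kwargs) -> EpochSet:
    """Apply the spherical-spline CSD with the study's default parameters."""
    return SurfaceLaplacian(**kwargs).fit(epochs).transform(epochs)


class HanningTFR(BaseEstimator, TransformerMixin):
    """Sliding-window Hann-taper time-frequency transform (dB output).

    ``freqs`` in Hz (default 2-40 in 1 Hz steps), output ``step`` seconds
    between time bins (default 0.04), ``n_cycles`` per window (default 5).
    Optionally restrict to a channel subset before transforming.
    """

    def __init__(self, freqs=None, step: float = 0.04, n_cycles: float = 5.0, channels=None):
        self.freqs = freqs
        self.step = step
        self.n_cycles = n_cycles
        self.channels = channels

    def fit(self, epochs: EpochSet, y=None):
        return self

    def transform(self, epochs: EpochSet) -> TFRSet:
        freqs = np.arange(2.0, 41.0) if self.freqs is None else np.asarray(self.freqs, dtype=float)
        if np.any(freqs <= 0) or np.any(freqs > epochs.sfreq / 2):
            raise ValueError("frequencies must lie in (0, Nyquist]")
        if self.channels is not None:
            epochs = epochs.pick(tuple(self.channels))
        sfreq = epochs.sfreq
        data = epochs.data.astype(np.float64)
        n_tr, n_ch, n_t = data.shape

        step_n = max(1, int(round(self.step * sfreq)))
        out_idx = np.arange(0, n_t, step_n)
        out_times = epochs.times[out_idx]
        power = np.full((n_tr, n_ch, freqs.size, out_idx.size), np.nan)

        flat = data.reshape(n_tr * n_ch, n_t)
        t_rel = np.arange(n_t) / sfreq
        for fi, f in enumerate(freqs):
            n_win = int(round(self.n_cycles / f * sfreq))
            n_win = n_win if n_win % 2 == 1 else n_win + 1
            if n_win > n_t:
                continue
            taper = hann(n_win, sym=True)
            k = np.arange(n_win) / sfreq
            kernel = taper * np.exp(-2j * np.pi * f * k)
            scale = 2.0 / taper.sum()
            conv = fftconvolve(flat, kernel[None, ::-1].conj(), mode="same", axes=1)
            amp2 = (np.abs(conv) * scale) ** 2 / 2.0  # sinusoid amplitude A -> A^2/2
            half = n_win // 2
            valid = np.zeros(n_t, dtype=bool)
            valid[half : n_t - half] = True
            sel = amp2[:, out_idx]
            sel[:, ~valid[out_idx]] = np.nan
            power[:, :, fi, :] = sel.reshape(n_tr, n_ch, -1)
        with np.errstate(divide="ignore"):
            power_db = 10.0 * np.log10(power)
        return TFRSet(power=power_db, freqs=freqs, times=out_times, channels=epochs.channels)


def tfr_hanning(epochs: EpochSet, freqs=None, step: float = 0.04, n_cycles: float = 5.0,
                channels=None) -> TFRSet:
    """Five-cycle Hann-taper TFR in dB (thin wrapper over :class:`HanningTFR`)."""
    return HanningTFR(freqs=freqs, step=step, n_cycles=n_cycles, channels=channels).transform(epochs)


def baseline_db(tfr: TFRSet, window: tuple[float, float] = (-0.75, -0.25),
                per_trial: bool = False) -> TFRSet:
    """Subtract pre-cue baseline dB per channel x frequency.

    By default the baseline is the dB mean across trials and baseline
    timepoints (condition-independent); ``per_trial=True`` subtracts each
    trial's own baseline. NaN-aware: frequencies with no valid baseline
    estimate stay NaN.
    """
    if tfr.baseline_corrected:
        raise ValueError("TFR is already baseline-corrected")
    lo, hi = window
    if lo < tfr.times[0] - 1e-9 or hi > tfr.times[-1] + 1e-9:
        raise ValueError("baseline window outside epoch")
    m = (tfr.times >= lo) & (tfr.times <= hi)
    if not m.any():
        raise ValueError("baseline window contains no timepoints")
    import warnings

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        # frequencies whose 5-cycle window never fits in the baseline are all-NaN
        warnings.filterwarnings("ignore", "Mean of empty slice")
        if per_trial:
            base = np.nanmean(tfr.power[:, :, :, m], axis=3, keepdims=True)
        else:
            base = np.nanmean(tfr.power[:, :, :, m], axis=(0, 3), keepdims=True)
    return replace(tfr, power=tfr.power - base, baseline_corrected=True, baseline_window=(lo, hi))


def band_power(tfr: TFRSet, band=None, channels=None, time_window=None,
               preset: str | None = None) -> np.ndarray:
    """Per-trial mean power over a band x channel-set x time-window selection.

    Either give ``preset`` ('beta', 'theta', 'alpha') or explicit selections.
    NaN cells (edge windows) are ignored in the mean.
    """
    if preset is not None:
        cfg = BAND_PRESETS[preset]
        band = band or cfg["band"]
        channels = channels or cfg["channels"]
        time_window = time_window or cfg["time_window"]
    if band is None or channels is None or time_window is None:
        raise ValueError("band, channels and time_window are required without a preset")
    fm = (tfr.freqs >= band[0]) & (tfr.freqs <= band[1])
    tm = (tfr.times >= time_window[0]) & (tfr.times <= time_window[1])
    from .montage import channel_indices

    ci = channel_indices(tfr.channels, channels)
    if not fm.any() or not tm.any() or ci.size == 0:
        raise ValueError("empty band/channel/time selection")
    sel = tfr.power[:, ci][:, :, fm][:, :, :, tm]
    with np.errstate(invalid="ignore"):
        return np.nanmean(sel, axis=(1, 2, 3))
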