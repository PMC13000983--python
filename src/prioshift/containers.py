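"""In-memory containers shared across modules.

``TrialTable`` is a plain :class:`pandas.DataFrame` with a fixed column schema
(validated by :func:`validate_trial_table`); ``EpochSet`` and ``TFRSet`` are
lightweight dataclasses wrapping numpy arrays with axis metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

#: Conditions a trial can be in. ``block_start`` is neither a switch nor a repeat
#: and is excluded from switch-cost contrasts.
CONDITIONS = ("block_start", "switch", "repeat1", "repeat2plus")

TRIAL_COLUMNS = (
    "block_id",
    "trial_in_block",
    "cued_item",
    "condition",
    "theta_cued",
    "theta_uncued",
    "item_distance",
    "probe",
    "probe_offset",
    "response",
    "correct",
    "rt_ms",
)


def validate_trial_table(trials: pd.DataFrame, require_behavior: bool = False) -> None:
    needed = set(TRIAL_COLUMNS[:9]) | ({"response", "correct", "rt_ms"} if require_behavior else set())
    missing = needed - set(trials.columns)
    if missing:
        raise ValueError(f"trial table is missing columns: {sorted(missing)}")
    bad = set(trials["condition"].unique()) - set(CONDITIONS)
    if bad:
        raise ValueError(f"unknown conditions: {sorted(bad)}")


@dataclass
class EpochSet:
    """Trials x channels x samples array with a uniform time axis.

    ``data`` is in arbitrary amplitude units (uV-like) before the surface
    Laplacian, and in CSD units afterwards (``csd_applied`` is then True).
    ``times`` is in seconds relative to cue onset.
    """

    data: np.ndarray
    times: np.ndarray
    sfreq: float
    channels: tuple[str, ...]
    positions: np.ndarray | None = None
    csd_applied: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.times = np.asarray(self.times, dtype=float)
        self.channels = tuple(self.channels)
        if self.data.ndim != 3:
            raise ValueError("EpochSet.data must be trials x channels x samples")
        if self.data.shape[1] != len(self.channels):
            raise ValueError("channel count does not match label count")
        if self.data.shape[2] != self.times.size:
            raise ValueError("sample count does not match time axis")
        dt = np.diff(self.times)
        if self.times.size > 1 and (np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6)):
            raise ValueError("time axis must be strictly increasing and uniform")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def pick(self, channels) -> "EpochSet":
        from .montage import channel_indices

        idx = channel_indices(self.channels, channels)
        return replace(
            self,
            data=self.data[:, idx],
            channels=tuple(channels),
            positions=None if self.positions is None else self.positions[idx],
        )

    def time_index(self, t: float) -> int:
        """Index of the sample closest to time ``t`` (seconds)."""
        return int(np.argmin(np.abs(self.times - t)))


@dataclass
class TFRSet:
    """Trials x channels x frequencies x times log-power (dB).

    Cells whose analysis window does not fit inside the epoch are NaN.  After
    :func:`prioshift.spectral.baseline_db` the values are dB differences from
    the pre-cue baseline and ``baseline_corrected`` is True.
    """

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    channels: tuple[str, ...]
    baseline_corrected: bool = False
    baseline_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.channels = tuple(self.channels)
        if self.power.ndim != 4:
            raise ValueError("TFRSet.power must be trials x channels x freqs x times")
        if self.power.shape[1:] != (len(self.channels), self.freqs.size, self.times.size):
            raise ValueError("TFR axis metadata does not match array shape")

    @property
    def n_trials(self) -> int:
        return self.power.shape[0]
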