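"""61-channel extended 10-20 montage and the named channel sets used by the analyses.

Coordinates come from MNE's bundled standard-1005 template and are projected
onto the best-fitting sphere (unit radius) for the spherical-spline surface
Laplacian.
"""

from __future__ import annotations

import warnings

import numpy as np

# 61 scalp channels of the extended 10-20 system (no Fpz; EOG/EMG/mastoids excluded).
CHANNELS_61: tuple[str, ...] = (
    "Fp1", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO5", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2",
)

# Channel sets used for band-power and decoding analyses.
CENTRAL_CHANNELS = ("C1", "Cz", "C2", "CP1", "CPz", "CP2", "P1", "Pz", "P2")
FRONTAL_CHANNELS = ("AF3", "AFz", "AF4", "F1", "Fz", "F2")
POSTERIOR_ALPHA_CHANNELS = ("O1", "Oz", "O2", "PO7", "PO3", "POz", "PO4", "PO8")
DECODING_CHANNELS = (
    "P7", "P5", "P3", "P1", "P2", "P4", "P6", "P8",
    "PO7", "PO5", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2",
)

assert len(CHANNELS_61) == 61
assert set(CENTRAL_CHANNELS) <= set(CHANNELS_61)
assert set(FRONTAL_CHANNELS) <= set(CHANNELS_61)
assert set(POSTERIOR_ALPHA_CHANNELS) <= set(CHANNELS_61)
assert set(DECODING_CHANNELS) <= set(CHANNELS_61)

_POSITIONS_CACHE: dict[tuple[str, ...], np.ndarray] = {}


def channel_positions(channels: tuple[str, ...] = CHANNELS_61) -> np.ndarray:
    """Unit-sphere positions (n_channels, 3) for the given 10-20 labels.

    Template head positions are re-centered on the best-fitting sphere and
    normalized to unit radius, which is the geometry assumed by the
    spherical-spline CSD estimator.
    """
    key = tuple(channels)
    if key in _POSITIONS_CACHE:
        return _POSITIONS_CACHE[key]
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            mont = mne.channels.make_standard_montage("standard_1005")
        except ValueError:  # pragma: no cover - newer template name
            mont = mne.channels.make_standard_montage("colin27_1005")
    pos_map = mont.get_positions()["ch_pos"]
    missing = [ch for ch in channels if ch not in pos_map]
    if missing:
        raise ValueError(f"channels missing from template montage: {missing}")
    pos = np.array([pos_map[ch] for ch in channels], dtype=float)
    center = _fit_sphere_center(pos)
    pos = pos - center
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    _POSITIONS_CACHE[key] = pos
    return pos


def _fit_sphere_center(points: np.ndarray) -> np.ndarray:
    """Least-squares center of the sphere through ``points``."""
    A = np.hstack([2 * points, np.ones((len(points), 1))])
    b = (points**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    return sol[:3]


def channel_indices(all_channels, subset) -> np.ndarray:
    """Indices of ``subset`` labels within ``all_channels`` (order preserved)."""
    lookup = {ch: i for i, ch in enumerate(all_channels)}
    missing = [ch for ch in subset if ch not in lookup]
    if missing:
        raise ValueError(f"channels not present: {missing}")
    return np.array([lookup[ch] for ch in subset], dtype=int)
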