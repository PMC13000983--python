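"""Cross-validated Mahalanobis-distance decoding of memorized orientations.

For each decoding timepoint t, the signal of 17 posterior sensors over a
450 ms backward-looking window is resampled to one sample per 12 ms (37
samples), demeaned across timepoints within each sensor, and concatenated
into 629 features. Training data (all folds but one, folds = contiguous
block groups) provide 16 orientation-mean patterns and a Ledoit-Wolf
shrinkage estimate of the noise covariance (computed on residuals after
subtracting the orientation means). Each test trial yields 16 Mahalanobis
distances which, circularly re-centered on the test orientation and
sign-flipped, form a tuning curve; the trial's decoding score is the
cosine vector mean of that curve with doubled angles:

    score_i = sum_j cos(2 theta_j) * D'_ij,   theta_j in {-78.75 .. +90} deg.

A flat tuning curve gives a score of exactly 0 (the cosine weights sum to 0);
a curve peaked at the true orientation gives a positive score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from sklearn.base import BaseEstimator
from sklearn.covariance import LedoitWolf

from .containers import EpochSet
from .montage import DECODING_CHANNELS, channel_indices
from .synth import ORIENTATION_GRID

__all__ = [
    "FeatureMatrix",
    "build_features",
    "shrinkage_covariance",
    "MahalanobisOrientationDecoder",
    "mahalanobis_tuning",
    "decoding_score",
    "crossval_decode",
    "TUNING_OFFSETS_DEG",
]

#: Tuning-curve offset grid, centered so index 7 is the 0-degree bin.
TUNING_OFFSETS_DEG = (np.arange(16) - 7) * 11.25  # -78.75 .. +90
_COS_WEIGHTS = np.cos(2.0 * np.deg2rad(TUNING_OFFSETS_DEG))


@dataclass
class FeatureMatrix:
    """Trials x features block for one decoding timepoint."""

    X: np.ndarray
    sensors: tuple[str, ...]
    time_offsets: np.ndarray  # seconds, relative to the decoding timepoint
    timepoint: float

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


def build_features(epochs: EpochSet, t: float, sensors=DECODING_CHANNELS,
                   window: float = 0.45, resample_step: float = 0.012,
                   demean: bool = True) -> FeatureMatrix:
    """Pooled spatiotemporal features for decoding at time ``t``.

    Takes the samples at ``t, t-12ms, ..."`` strictly inside ``(t-window, t]``
    (37 for the default 450 ms window), per sensor, demeaned across the
    window's timepoints, concatenated sensor-by-sensor.
    """
    dec = max(1, int(round(resample_step * epochs.sfreq)))
    # Backward grid t, t-step, t-2*step, ...; the [t-window, t] span holds 38
    # grid points for the default 450 ms / 12 ms combination, of which the 37
    # latest are kept (earliest edge dropped), reproducing 37 x 17 = 629.
    n_keep = int(np.floor(window / resample_step + 1e-9))
    i_t = epochs.time_index(t)
    if abs(epochs.times[i_t] - t) > 0.5 / epochs.sfreq + 1e-9:
        raise ValueError(f"timepoint {t} not on the epoch time axis")
    idx = i_t - dec * np.arange(n_keep)[::-1]
    if idx[0] < 0:
        raise ValueError("decoding window extends before the epoch start")
    ci = channel_indices(epochs.channels, sensors)
    block = epochs.data[:, ci][:, :, idx].astype(np.float64)  # trials x sensors x samples
    if demean:
        block = block - block.mean(axis=2, keepdims=True)
    X = block.reshape(block.shape[0], -1)
    return FeatureMatrix(
        X=X,
        sensors=tuple(sensors),
        time_offsets=(idx - i_t) / epochs.sfreq,
        timepoint=float(epochs.times[i_t]),
    )


def shrinkage_covariance(residuals: np.ndarray) -> tuple[np.ndarray, float]:
    """Ledoit-Wolf analytic-shrinkage covariance of residual rows.

    Returns the (symmetric positive-definite) covariance and the shrinkage
    intensity. Invertible even when features outnumber rows.
    """
    residuals = np.asarray(residuals, dtype=float)
    if residuals.shape[0] < 2:
        raise ValueError("need at least 2 residual rows")
    lw = LedoitWolf(assume_centered=True).fit(residuals)
    return lw.covariance_, float(lw.shrinkage_)


class MahalanobisOrientationDecoder(BaseEstimator):
    """Mahalanobis-distance orientation decoder over a fixed circular grid.

    ``fit(X, y)`` stores per-orientation mean patterns and the Ledoit-Wolf
    noise covariance of the residuals. ``tuning_curves(X, y)`` returns
    sign-flipped, re-centered distance curves; ``score_trials`` reduces them
    to cosine-vector-mean decoding scores.
    """

    def __init__(self, orientations=None, squared: bool = False):
        self.orientations = orientations
        self.squared = squared

    def fit(self, X, y, fallback_means: np.ndarray | None = None):
        """Fit class means and noise covariance.

        ``fallback_means`` (n_orientations x n_features) supplies mean
        patterns for orientations absent from the training rows (cross-
        validation folds may lack a class; the fallback is the mean over all
        available trials). Without a fallback, a missing class is an error.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        grid = ORIENTATION_GRID if self.orientations is None else np.asarray(self.orientations, float)
        self.grid_ = grid
        means = np.empty((len(grid), X.shape[1]))
        labels = self._grid_index(y)
        for k in range(len(grid)):
            m = labels == k
            if m.any():
                means[k] = X[m].mean(axis=0)
            elif fallback_means is not None and np.isfinite(fallback_means[k]).all():
                means[k] = fallback_means[k]
            else:
                raise ValueError(f"orientation {grid[k]} missing from training data")
        resid = X - means[labels]
        self.class_means_ = means
        self.covariance_, self.shrinkage_ = shrinkage_covariance(resid)
        self._cho = cho_factor(self.covariance_)
        return self

    def _grid_index(self, y) -> np.ndarray:
        y = np.mod(np.asarray(y, dtype=float), 180.0)
        d = np.abs(y[:, None] - self.grid_[None, :])
        d = np.minimum(d, 180.0 - d)
        idx = d.argmin(axis=1)
        if np.any(d[np.arange(len(y)), idx] > 1e-6):
            raise ValueError("orientation labels do not lie on the grid")
        return idx

    def distances(self, X) -> np.ndarray:
        """Mahalanobis distances (trials x n_orientations, grid order)."""
        X = np.asarray(X, dtype=float)
        diff = X[:, None, :] - self.class_means_[None, :, :]  # trials x K x p
        n_tr, K, p = diff.shape
        solved = cho_solve(self._cho, diff.reshape(-1, p).T).T.reshape(n_tr, K, p)
        q = np.einsum("tkp,tkp->tk", diff, solved)
        return q if self.squared else np.sqrt(np.maximum(q, 0.0))

    def tuning_curves(self, X, y) -> np.ndarray:
        """Centered, sign-flipped tuning curves (trials x 16).

        Column j holds D' at offset ``TUNING_OFFSETS_DEG[j]`` from each
        trial's true orientation ``y``; larger D' = more similar.
        """
        d = self.distances(X)
        idx = self._grid_index(y)
        n_k = len(self.grid_)
        cols = (idx[:, None] + np.arange(n_k)[None, :] - (n_k // 2 - 1)) % n_k
        return -np.take_along_axis(d, cols, axis=1)

    def score_trials(self, X, y) -> np.ndarray:
        return decoding_score(self.tuning_curves(X, y))


def mahalanobis_tuning(train_X, train_y, test_row, covariance, orientations=None,
                       squared: bool = False) -> np.ndarray:
    """Tuning curve of one test row against training class means (spec op).

    Functional form of the decoder path with an externally supplied
    covariance; returns the 16-point centered, sign-flipped curve. ``test_row``
    is ``(features, orientation)``.
    """
    x, theta = test_row
    dec = MahalanobisOrientationDecoder(orientations=orientations, squared=squared)
    dec.fit(np.asarray(train_X, float), np.asarray(train_y, float))
    dec.covariance_ = np.asarray(covariance, dtype=float)
    dec._cho = cho_factor(dec.covariance_)
    return dec.tuning_curves(np.atleast_2d(x), np.atleast_1d(theta))[0]


def decoding_score(curves) -> np.ndarray:
    """Cosine vector mean of tuning curves with doubled angles.

    Accepts a single 16-point curve or an array of curves (..., 16). The
    cosine weights sum to zero over the full grid, so the score is invariant
    to adding a constant to all curve values and is exactly 0 for a flat curve.
    """
    curves = np.asarray(curves, dtype=float)
    if curves.shape[-1] != len(_COS_WEIGHTS):
        raise ValueError("tuning curves must have 16 points")
    return curves @ _COS_WEIGHTS


def _make_folds(block_ids: np.ndarray, n_folds: int = 13, blocks_per_fold: int = 10) -> list[np.ndarray]:
    """Contiguous block groups; with 128 blocks: 12 folds of 10 + one of 8."""
    blocks = np.unique(block_ids)
    if len(blocks) < n_folds:
        raise ValueError(f"need at least {n_folds} blocks, got {len(blocks)}")
    if len(blocks) >= n_folds * blocks_per_fold - (blocks_per_fold - 1):
        sizes = [blocks_per_fold] * (n_folds - 1)
        sizes.append(len(blocks) - sum(sizes))
        groups, start = [], 0
        for s in sizes:
            groups.append(blocks[start : start + s])
            start += s
    else:
        groups = np.array_split(blocks, n_folds)
    return [np.asarray(g) for g in groups]


def crossval_decode(
    epochs: EpochSet,
    trials: pd.DataFrame,
    target="cued",
    timepoints=None,
    sensors=DECODING_CHANNELS,
    n_folds: int = 13,
    window: float = 0.45,
    demean: bool = True,
    squared: bool = False,
) -> pd.DataFrame:
    """Cross-validated per-trial decoding scores.

    ``target='cued'`` trains and tests on the cued orientation, ``'uncued'``
    on the uncued orientation, and ``'cross'`` trains on cued labels but tests
    on uncued labels; a sequence of targets computes them in one pass (targets
    sharing training labels share decoder fits). Folds are contiguous block
    groups (13 by default, 10 blocks serving as test data per fold where block
    counts allow). Returns a tidy frame (trial, timepoint, target, score, fold).
    """
    targets = [target] if isinstance(target, str) else list(target)
    for tg in targets:
        if tg not in ("cued", "uncued", "cross"):
            raise ValueError("target must be cued, uncued or cross")
    if len(trials) != epochs.n_trials:
        raise ValueError("trial table and epochs disagree on trial count")
    if timepoints is None:
        timepoints = np.round(np.arange(0.8, 1.4001, 0.05), 10)
    cols = {"cued": ("theta_cued", "theta_cued"), "uncued": ("theta_uncued", "theta_uncued"),
            "cross": ("theta_cued", "theta_uncued")}
    block_ids = trials["block_id"].to_numpy()
    folds = _make_folds(block_ids, n_folds=n_folds)
    grid = ORIENTATION_GRID
    n_k = len(grid)

    records = []
    trial_idx = np.arange(len(trials))
    by_train: dict[str, list[str]] = {}
    for tg in targets:
        by_train.setdefault(cols[tg][0], []).append(tg)

    for t in timepoints:
        feats = build_features(epochs, float(t), sensors=sensors, window=window, demean=demean)
        for train_col, tgroup in by_train.items():
            y_train_all = trials[train_col].to_numpy(dtype=float)
            ref = MahalanobisOrientationDecoder(squared=squared)
            ref.grid_ = grid
            all_idx = ref._grid_index(y_train_all)
            counts = np.bincount(all_idx, minlength=n_k)
            if np.any(counts == 0):
                raise ValueError(
                    f"orientations absent from the entire dataset: {grid[counts == 0]}"
                )
            # dataset-wide class sums/means: the fallback for folds missing a class
            sums = np.zeros((n_k, feats.X.shape[1]))
            np.add.at(sums, all_idx, feats.X)
            fallback = sums / counts[:, None]
            for fold_id, test_blocks in enumerate(folds):
                test_m = np.isin(block_ids, test_blocks)
                dec = MahalanobisOrientationDecoder(squared=squared)
                dec.fit(feats.X[~test_m], y_train_all[~test_m], fallback_means=fallback)
                X_test = feats.X[test_m]
                train_counts = np.bincount(all_idx[~test_m], minlength=n_k)
                missing = np.flatnonzero(train_counts == 0)
                loo_curve_fix = []
                # Orientations absent from the training folds use dataset-wide
                # fallback means, which include the held-out trials: replace
                # the affected trials' distance to that class with a leave-one-
                # out version so no trial is compared to a mean containing itself.
                if missing.size:
                    test_train_labels = all_idx[test_m]
                    for k in missing:
                        for i in np.flatnonzero(test_train_labels == k):
                            if counts[k] < 2:
                                raise ValueError(
                                    f"orientation {grid[k]} has a single trial; cannot cross-validate"
                                )
                            mu = (sums[k] - X_test[i]) / (counts[k] - 1)
                            diff = X_test[i] - mu
                            q = float(diff @ cho_solve(dec._cho, diff))
                            loo_curve_fix.append((i, k, -(q if squared else np.sqrt(max(q, 0.0)))))
                for tg in tgroup:
                    y_test = trials[cols[tg][1]].to_numpy(dtype=float)[test_m]
                    curves = dec.tuning_curves(X_test, y_test)
                    if loo_curve_fix:
                        test_center = dec._grid_index(y_test)
                        for i, k, dprime in loo_curve_fix:
                            j = (k - test_center[i] + (n_k // 2 - 1)) % n_k
                            curves[i, j] = dprime
                    scores = decoding_score(curves)
                    for i, s in zip(trial_idx[test_m], scores):
                        records.append((int(i), float(t), tg, float(s), fold_id))
    return pd.DataFrame(records, columns=["trial", "timepoint", "target", "score", "fold"])
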