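"""Psychometric modeling and behavioral switch-cost / item-distance analyses.

The psychometric model describes the probability of a "clockwise" judgment as
a function of the signed probe offset theta (degrees, folded to (-90, +90])
relative to the cued orientation:

    P(cw | theta) = (1 - lambda) * Phi(theta; 0, sigma) + lambda

with Phi the normal CDF, ``sigma`` the inverse precision and ``lambda`` the
lapse rate. As printed this form is asymmetric (asymptotes at ``lambda`` and
1); the standard symmetric variant ``(1 - 2 lambda) Phi + lambda`` is
available via ``symmetric_lapse=True``. The swap-extended model adds a
probability ``p_swap`` of comparing the probe to the *uncued* item:

    P(cw) = (1 - p_swap - lambda) Phi(theta_cued) + p_swap Phi(theta_uncued) + lambda.

Fitting is bounded maximum likelihood (L-BFGS-B, multi-start) with the bias
``mu`` fixed at 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator

from .containers import validate_trial_table
from .circstats import fold_offset

__all__ = [
    "PsychometricParams",
    "PsychometricModel",
    "psychometric_predict",
    "fit_psychometric",
    "switch_cost_summary",
    "distance_effect",
    "residualize",
]


@dataclass
class PsychometricParams:
    """Psychometric parameters; ``mu`` is fixed to 0 throughout."""

    lapse: float = 0.0
    sigma: float = 15.0
    mu: float = 0.0
    p_swap: float = 0.0
    neg_log_lik: float = np.nan
    n_trials: int = 0
    converged: bool = True
    boundary: bool = False

    def validate(self) -> None:
        if not (0.0 <= self.lapse <= 1.0 and 0.0 <= self.p_swap <= 1.0):
            raise ValueError("lapse and p_swap must lie in [0, 1]")
        if self.lapse + self.p_swap > 1.0 + 1e-12:
            raise ValueError("lapse + p_swap must not exceed 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


def _phi(x):
    return special.ndtr(x)


def psychometric_predict(theta_cued_offset, theta_uncued_offset=None, params: PsychometricParams | None = None,
                         symmetric_lapse: bool = False):
    """Clockwise-response probability for signed probe offsets in degrees.

    ``theta_uncued_offset`` may be None (basic model / p_swap ignored).
    Offsets must already be folded to (-90, +90]; values outside are rejected.
    """
    params = params or PsychometricParams()
    params.validate()
    th_c = np.asarray(theta_cued_offset, dtype=float)
    if np.any((th_c <= -90.0 - 1e-9) | (th_c > 90.0 + 1e-9)):
        raise ValueError("theta offsets must be folded to (-90, +90] degrees")
    phi_c = _phi((th_c - params.mu) / params.sigma)
    lam, ps = params.lapse, params.p_swap
    if theta_uncued_offset is None or ps == 0.0:
        ps_eff = 0.0
        phi_u = 0.0
    else:
        th_u = np.asarray(theta_uncued_offset, dtype=float)
        if np.any((th_u <= -90.0 - 1e-9) | (th_u > 90.0 + 1e-9)):
            raise ValueError("theta offsets must be folded to (-90, +90] degrees")
        ps_eff = ps
        phi_u = _phi((th_u - params.mu) / params.sigma)
    if symmetric_lapse:
        return (1.0 - 2.0 * lam - ps_eff) * phi_c + ps_eff * phi_u + lam
    return (1.0 - lam - ps_eff) * phi_c + ps_eff * phi_u + lam


class PsychometricModel(BaseEstimator):
    """Maximum-likelihood psychometric fit, sklearn-style.

    Parameters
    ----------
    include_swap : bool
        Free ``p_swap`` (requires the uncued offset column in X).
    symmetric_lapse : bool
        Use the symmetric lapse form instead of the printed asymmetric one.
    n_restarts : int
        Random multi-starts for the bounded L-BFGS-B optimizer.
    lapse_bounds, swap_bounds, sigma_bounds :
        Box constraints; the 0.5 caps keep lapse + p_swap <= 1 automatically.

    After ``fit(X, y)`` (X: offsets in degrees, column 0 cued and optional
    column 1 uncued; y: 1 for clockwise) the fitted attributes are
    ``lapse_``, ``sigma_``, ``p_swap_``, ``nll_``, ``n_trials_``,
    ``converged_`` and ``boundary_``.
    """

    def __init__(self, include_swap: bool = False, symmetric_lapse: bool = False,
                 n_restarts: int = 10, lapse_bounds=(0.0, 0.5), swap_bounds=(0.0, 0.5),
                 sigma_bounds=(1.0, 90.0), random_state: int = 0):
        self.include_swap = include_swap
        self.symmetric_lapse = symmetric_lapse
        self.n_restarts = n_restarts
        self.lapse_bounds = lapse_bounds
        self.swap_bounds = swap_bounds
        self.sigma_bounds = sigma_bounds
        self.random_state = random_state

    def _nll(self, theta_vec, th_c, th_u, y):
        lam, sig = theta_vec[0], theta_vec[1]
        ps = theta_vec[2] if self.include_swap else 0.0
        params = PsychometricParams(lapse=lam, sigma=sig, p_swap=ps)
        p = psychometric_predict(th_c, th_u if self.include_swap else None, params,
                                 symmetric_lapse=self.symmetric_lapse)
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return -np.sum(np.where(y, np.log(p), np.log1p(-p)))

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] == 1 and X.shape[1] > 2:
            X = X.T
        y = np.asarray(y).astype(bool)
        if len(y) != X.shape[0]:
            raise ValueError("X and y length mismatch")
        if len(y) < 2:
            raise ValueError("need at least 2 responded trials")
        th_c = X[:, 0]
        th_u = X[:, 1] if (self.include_swap and X.shape[1] > 1) else None
        if self.include_swap and th_u is None:
            raise ValueError("include_swap=True requires an uncued-offset column")

        rng = np.random.default_rng(self.random_state)
        bounds = [self.lapse_bounds, self.sigma_bounds]
        if self.include_swap:
            bounds.append(self.swap_bounds)
        best = None
        self.converged_ = False
        for k in range(max(1, self.n_restarts)):
            if k == 0:
                x0 = [0.05, 15.0] + ([0.02] if self.include_swap else [])
            else:
                x0 = [rng.uniform(lo, hi) for lo, hi in bounds]
            res = optimize.minimize(self._nll, x0, args=(th_c, th_u, y), method="L-BFGS-B", bounds=bounds)
            if best is None or res.fun < best.fun:
                best = res
            self.converged_ = self.converged_ or bool(res.success)
        lam, sig = best.x[0], best.x[1]
        ps = best.x[2] if self.include_swap else 0.0
        self.lapse_ = float(lam)
        self.sigma_ = float(sig)
        self.p_swap_ = float(ps)
        self.nll_ = float(best.fun)
        self.n_trials_ = int(len(y))
        tol = 1e-4
        self.boundary_ = bool(
            min(abs(lam - self.lapse_bounds[0]), abs(lam - self.lapse_bounds[1])) < tol
            or min(abs(sig - self.sigma_bounds[0]), abs(sig - self.sigma_bounds[1])) < tol
        )
        return self

    def predict_proba(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        p = psychometric_predict(
            X[:, 0],
            X[:, 1] if (self.include_swap and X.shape[1] > 1) else None,
            self.params_,
            symmetric_lapse=self.symmetric_lapse,
        )
        return np.column_stack([1 - p, p])

    @property
    def params_(self) -> PsychometricParams:
        return PsychometricParams(
            lapse=self.lapse_, sigma=self.sigma_, p_swap=self.p_swap_,
            neg_log_lik=self.nll_, n_trials=self.n_trials_,
            converged=self.converged_, boundary=self.boundary_,
        )


def fit_psychometric(trials: pd.DataFrame, include_swap: bool = False,
                     condition_filter=None, symmetric_lapse: bool = False,
                     min_trials: int = 50, random_state: int = 0) -> PsychometricParams:
    """Fit the psychometric model to responded trials of a trial table.

    ``condition_filter`` may be a condition name or a list of names ("repeat"
    pools repeat1 and repeat2plus).
    """
    validate_trial_table(trials, require_behavior=True)
    df = trials.dropna(subset=["response"])
    df = df[df["response"].isin(["cw", "ccw"])]
    if condition_filter is not None:
        if isinstance(condition_filter, str):
            condition_filter = (
                ["repeat1", "repeat2plus"] if condition_filter == "repeat" else [condition_filter]
            )
        df = df[df["condition"].isin(condition_filter)]
    if len(df) < min_trials:
        raise ValueError(f"need at least {min_trials} responded trials, got {len(df)}")
    th_c = df["probe_offset"].to_numpy(dtype=float)
    th_u = fold_offset(df["probe"].to_numpy(dtype=float) - df["theta_uncued"].to_numpy(dtype=float))
    y = (df["response"] == "cw").to_numpy()
    model = PsychometricModel(include_swap=include_swap, symmetric_lapse=symmetric_lapse,
                              random_state=random_state)
    model.fit(np.column_stack([th_c, th_u]), y)
    return model.params_


# ---------------------------------------------------------------------------
# Switch-cost and item-distance summaries


def _cohen_d_paired(a: np.ndarray, b: np.ndarray) -> float:
    d = a - b
    sd = d.std(ddof=1)
    return float(d.mean() / sd) if sd > 0 else np.nan


def switch_cost_summary(trials: pd.DataFrame, participant_col: str = "participant") -> dict:
    """Per-condition accuracy and correct-trial median RT, plus paired tests.

    Block-start trials are excluded. With a ``participant`` column, returns
    per-participant condition means and paired t-tests (with Cohen's d)
    between switch / repeat1 / repeat2plus; without one, the single dataset is
    treated as one participant and only the summary is returned.
    """
    validate_trial_table(trials, require_behavior=True)
    df = trials[trials["condition"] != "block_start"].copy()
    if participant_col not in df.columns:
        df[participant_col] = 0
    conds = ["switch", "repeat1", "repeat2plus"]
    present = [c for c in conds if (df["condition"] == c).any()]
    if len(present) < 2:
        raise ValueError("need at least two of switch/repeat1/repeat2plus present")

    rows = []
    for (pid, cond), g in df.groupby([participant_col, "condition"], observed=True):
        if cond not in conds or len(g) == 0:
            continue
        corr = g["correct"].astype(bool)
        rows.append(
            dict(participant=pid, condition=str(cond), n_trials=len(g),
                 accuracy=float(corr.mean()),
                 median_rt_ms=float(g.loc[corr, "rt_ms"].median()) if corr.any() else np.nan)
        )
    summary = pd.DataFrame(rows)

    tests = []
    wide_acc = summary.pivot(index="participant", columns="condition", values="accuracy")
    wide_rt = summary.pivot(index="participant", columns="condition", values="median_rt_ms")
    if wide_acc.shape[0] >= 2:
        for a, b in [("switch", "repeat1"), ("switch", "repeat2plus"), ("repeat1", "repeat2plus")]:
            if a not in wide_acc or b not in wide_acc:
                continue
            for measure, wide in [("accuracy", wide_acc), ("median_rt_ms", wide_rt)]:
                x, yv = wide[a].to_numpy(), wide[b].to_numpy()
                t, p = stats.ttest_rel(x, yv)
                tests.append(dict(measure=measure, contrast=f"{a}-{b}", t=float(t), p=float(p),
                                  df=len(x) - 1, cohen_d=_cohen_d_paired(x, yv),
                                  mean_diff=float(np.mean(x - yv))))
    return {"summary": summary, "tests": pd.DataFrame(tests)}


def distance_effect(trials: pd.DataFrame, outcome: str = "accuracy",
                    participant_col: str = "participant", pool_repeats: bool = True) -> dict:
    """Per-participant linear slope of accuracy or RT on item distance.

    Slopes are reported per 10 degrees of item distance, separately for switch
    and repeat trials, with one-sample t-tests per condition and a paired test
    on the condition difference. For ``outcome='rt'`` only correct trials
    enter (median-free least squares on single trials).
    """
    if outcome not in ("accuracy", "rt"):
        raise ValueError("outcome must be 'accuracy' or 'rt'")
    validate_trial_table(trials, require_behavior=True)
    df = trials[trials["condition"] != "block_start"].copy()
    if participant_col not in df.columns:
        df[participant_col] = 0
    if pool_repeats:
        df["cond2"] = np.where(df["condition"] == "switch", "switch", "repeat")
    else:
        df["cond2"] = df["condition"].astype(str)
    if outcome == "rt":
        df = df[df["correct"].astype(bool)]
        yname = "rt_ms"
    else:
        yname = "correct"

    rows = []
    for (pid, cond), g in df.groupby([participant_col, "cond2"], observed=True):
        x = g["item_distance"].to_numpy(dtype=float)
        if np.unique(x).size < 2:
            raise ValueError("need at least 2 distance levels per condition")
        y = g[yname].to_numpy(dtype=float)
        slope, intercept = np.polyfit(x, y, 1)
        rows.append(dict(participant=pid, condition=cond,
                         slope_per_10deg=float(slope * 10.0), intercept=float(intercept)))
    slopes = pd.DataFrame(rows)

    tests = []
    wide = slopes.pivot(index="participant", columns="condition", values="slope_per_10deg")
    if wide.shape[0] >= 2:
        for cond in wide.columns:
            v = wide[cond].to_numpy()
            t, p = stats.ttest_1samp(v, 0.0)
            sd = v.std(ddof=1)
            tests.append(dict(contrast=f"{cond} vs 0", t=float(t), p=float(p), df=len(v) - 1,
                              cohen_d=float(v.mean() / sd) if sd > 0 else np.nan))
        if {"switch", "repeat"} <= set(wide.columns):
            t, p = stats.ttest_rel(wide["switch"], wide["repeat"])
            tests.append(dict(contrast="switch-repeat", t=float(t), p=float(p),
                              df=wide.shape[0] - 1,
                              cohen_d=_cohen_d_paired(wide["switch"].to_numpy(), wide["repeat"].to_numpy())))
    return {"slopes": slopes, "tests": pd.DataFrame(tests)}


def residualize(y, x, groups=None) -> np.ndarray:
    """Per-group OLS residuals of ``y`` on ``x`` (with intercept).

    Used to regress item distance out of trial-wise outcomes before condition
    contrasts. ``groups=None`` treats all trials as one group.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if groups is None:
        groups = np.zeros(len(y), dtype=int)
    groups = np.asarray(groups)
    out = np.empty_like(y)
    for g in np.unique(groups):
        m = groups == g
        X = np.column_stack([np.ones(m.sum()), x[m]])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("singular design in residualization")
        beta, *_ = np.linalg.lstsq(X, y[m], rcond=None)
        out[m] = y[m] - X @ beta
    return out
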