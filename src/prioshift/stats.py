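"""Group-level statistics: z-scored trial regressions, one-sample/paired
tests, cluster-based sign-flip permutation correction, the 8-bin
power-vs-decoding analysis, and one-way repeated-measures ANOVA.

The cluster test follows the standard nonparametric framework for
neuroimaging data: per-cell one-sample t across participants, two-sided
cluster-forming threshold (default p < .05), connected components under
4-neighborhood adjacency, cluster mass = sum of t, and a max-mass null built
from random per-participant sign flips; corrected p uses the +1 correction,
so with 10,000 permutations the floor is ~1e-4.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats as sps

__all__ = [
    "ztrial_regress",
    "group_ttest",
    "cluster_permutation",
    "ClusterStat",
    "bin_analysis",
    "rm_anova_1way",
]


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise ValueError("constant variable cannot be z-scored")
    return (x - x.mean()) / sd


def ztrial_regress(
    df: pd.DataFrame,
    y: str,
    predictors,
    participant_col: str = "participant",
    condition_col: str | None = None,
    interaction: bool = False,
    min_trials: int = 10,
) -> pd.DataFrame:
    """Per-participant standardized multiple regression.

    Within each participant (x condition cell when ``condition_col`` is
    given): the outcome and every predictor are z-scored, an optional
    interaction column is formed as the product of the (z-scored) first two
    predictors and then itself z-scored, and OLS coefficients are returned in
    a tidy frame (participant, condition, term, coef).
    """
    predictors = list(predictors)
    if interaction and len(predictors) < 2:
        raise ValueError("interaction requires at least two predictors")
    group_cols = [participant_col] + ([condition_col] if condition_col else [])
    rows = []
    for keys, g in df.groupby(group_cols, observed=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        g = g.dropna(subset=[y] + predictors)
        if len(g) < min_trials:
            raise ValueError(
                f"cell {keys} has {len(g)} trials; need at least {min_trials}"
            )
        yv = _zscore(g[y].to_numpy(dtype=float))
        cols = [_zscore(g[p].to_numpy(dtype=float)) for p in predictors]
        names = list(predictors)
        if interaction:
            cols.append(_zscore(cols[0] * cols[1]))
            names.append(f"{predictors[0]}:{predictors[1]}")
        X = np.column_stack([np.ones(len(g))] + cols)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(f"singular design in cell {keys}")
        beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
        for name, b in zip(["intercept"] + names, beta):
            row = {participant_col: keys[0], "term": name, "coef": float(b)}
            if condition_col:
                row[condition_col] = keys[1]
            rows.append(row)
    return pd.DataFrame(rows)


def group_ttest(values, popmean: float = 0.0, paired_with=None) -> dict:
    """One-sample (or paired) t-test with Cohen's d.

    Returns dict(t, df, p, d, mean, n). Zero-variance input is flagged with
    NaN statistics rather than raising.
    """
    x = np.asarray(values, dtype=float)
    if paired_with is not None:
        x = x - np.asarray(paired_with, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 participants")
    sd = x.std(ddof=1)
    if sd == 0:
        return dict(t=np.nan, df=len(x) - 1, p=np.nan, d=np.nan, mean=float(x.mean()),
                    n=len(x), degenerate=True)
    t, p = sps.ttest_1samp(x, popmean)
    return dict(t=float(t), df=len(x) - 1, p=float(p), d=float((x.mean() - popmean) / sd),
                mean=float(x.mean()), n=len(x), degenerate=False)


@dataclass
class ClusterStat:
    """Result of a cluster-based sign-flip permutation test."""

    t_obs: np.ndarray
    cluster_labels: np.ndarray           # 0 = background; signed clusters share |id|
    clusters: list = field(default_factory=list)  # dicts: mass, p, sign, n_cells, id
    n_permutations: int = 0
    threshold_t: float = np.nan
    null_max_mass: np.ndarray | None = None

    def significant_masks(self, alpha: float = 0.05) -> list[np.ndarray]:
        return [np.abs(self.cluster_labels) == c["id"] for c in self.clusters if c["p"] <= alpha]


def _cluster_masses(tmap: np.ndarray, thr: float, structure: np.ndarray):
    """Signed suprathreshold clusters of a t-map; returns (labels, list of (id, sign, mass, n))."""
    labels = np.zeros(tmap.shape, dtype=int)
    out = []
    next_id = 1
    for sign in (1, -1):
        supra = (sign * tmap > thr) & np.isfinite(tmap)
        lab, n = ndimage.label(supra, structure=structure)
        for k in range(1, n + 1):
            m = lab == k
            labels[m] = next_id
            out.append((next_id, sign, float(tmap[m].sum()), int(m.sum())))
            next_id += 1
    return labels, out


def cluster_permutation(
    maps: np.ndarray,
    n_perm: int = 10000,
    threshold_p: float = 0.05,
    adjacency: str = "4",
    seed: int | None = None,
) -> ClusterStat:
    """Cluster-corrected one-sample test of per-participant effect maps.

    ``maps`` is participants x grid (1-D or 2-D grid). Cells that are NaN for
    any participant are excluded. The null distribution is the maximum
    absolute cluster mass over random per-participant sign flips; corrected
    p = (1 + #{null >= observed}) / (1 + n_perm). An empty result (no
    suprathreshold cells) is valid, not an error.
    """
    maps = np.asarray(maps, dtype=float)
    n_sub = maps.shape[0]
    if n_sub < 2:
        raise ValueError("need at least 2 participants")
    grid_shape = maps.shape[1:]
    if len(grid_shape) not in (1, 2):
        raise ValueError("grid must be 1-D or 2-D")
    if adjacency == "4":
        structure = ndimage.generate_binary_structure(len(grid_shape), 1)
    elif adjacency == "8":
        structure = ndimage.generate_binary_structure(len(grid_shape), len(grid_shape))
    else:
        raise ValueError("adjacency must be '4' or '8'")

    flat = maps.reshape(n_sub, -1)
    valid = np.isfinite(flat).all(axis=0)
    df = n_sub - 1
    thr = float(sps.t.ppf(1 - threshold_p / 2, df))

    def tmap_from(signed: np.ndarray) -> np.ndarray:
        mean = signed.mean(axis=0)
        sd = signed.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean / (sd / np.sqrt(n_sub))
        t[~valid] = np.nan
        return t

    t_obs = tmap_from(flat).reshape(grid_shape)
    labels, obs = _cluster_masses(t_obs, thr, structure)

    rng = np.random.default_rng(seed)
    # Sign-flipping leaves per-cell sum of squares unchanged, so the permuted
    # t-maps only need the flipped means.
    ssq = (flat**2).sum(axis=0)
    null = np.zeros(n_perm)
    for i in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=n_sub)
        mean = signs @ flat / n_sub
        var = (ssq - n_sub * mean**2) / df
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean / np.sqrt(var / n_sub)
        t[~valid] = np.nan
        t = t.reshape(grid_shape)
        _, perm_clusters = _cluster_masses(t, thr, structure)
        null[i] = max((abs(m) for _, _, m, _ in perm_clusters), default=0.0)

    clusters = []
    for cid, sign, mass, n_cells in obs:
        p = (1.0 + np.sum(null >= abs(mass))) / (1.0 + n_perm)
        clusters.append(dict(id=cid, sign=sign, mass=mass, n_cells=n_cells, p=float(p)))
    clusters.sort(key=lambda c: abs(c["mass"]), reverse=True)
    return ClusterStat(t_obs=t_obs, cluster_labels=labels, clusters=clusters,
                       n_permutations=n_perm, threshold_t=thr, null_max_mass=null)


def bin_analysis(
    df: pd.DataFrame,
    power: str,
    score: str,
    n_bins: int = 8,
    participant_col: str = "participant",
    condition_col: str | None = None,
) -> dict:
    """Bin trials by power into equal-count bins; slope of mean score across bins.

    Per participant (x condition): trials are ranked by ``power`` and split
    into ``n_bins`` nonoverlapping bins of (as close as possible) equal count,
    with remainder trials spread across the lowest bins. Returns per-bin mean
    scores, per-participant OLS slopes across bin index, and group one-sample
    t-tests on the slopes.
    """
    group_cols = [participant_col] + ([condition_col] if condition_col else [])
    bin_rows, slope_rows = [], []
    for keys, g in df.groupby(group_cols, observed=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        g = g.dropna(subset=[power, score])
        if len(g) < n_bins:
            raise ValueError(f"cell {keys}: {len(g)} trials < {n_bins} bins")
        order = np.argsort(g[power].to_numpy(dtype=float), kind="stable")
        chunks = np.array_split(order, n_bins)
        means = np.array([g[score].to_numpy(dtype=float)[c].mean() for c in chunks])
        slope = np.polyfit(np.arange(n_bins), means, 1)[0]
        base = {participant_col: keys[0]}
        if condition_col:
            base[condition_col] = keys[1]
        slope_rows.append({**base, "slope": float(slope)})
        for b, mval in enumerate(means):
            bin_rows.append({**base, "bin": b, "mean_score": float(mval)})
    bins = pd.DataFrame(bin_rows)
    slopes = pd.DataFrame(slope_rows)
    tests = {}
    if condition_col:
        for cond, g in slopes.groupby(condition_col, observed=True):
            if len(g) >= 3:
                tests[str(cond)] = group_ttest(g["slope"].to_numpy())
    elif len(slopes) >= 3:
        tests["all"] = group_ttest(slopes["slope"].to_numpy())
    return {"bins": bins, "slopes": slopes, "tests": tests}


def rm_anova_1way(values: np.ndarray, gg_correction: bool = False) -> dict:
    """One-way repeated-measures ANOVA on a participants x levels table.

    Returns F, dfs (optionally Greenhouse-Geisser corrected), p and partial
    eta squared. Missing cells are not allowed.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("values must be participants x levels with at least 2 of each")
    if not np.isfinite(x).all():
        raise ValueError("missing cells in repeated-measures table")
    n, k = x.shape
    grand = x.mean()
    subj_means = x.mean(axis=1)
    lvl_means = x.mean(axis=0)
    ss_cond = n * np.sum((lvl_means - grand) ** 2)
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_tot = np.sum((x - grand) ** 2)
    ss_err = ss_tot - ss_cond - ss_subj
    df1, df2 = k - 1, (n - 1) * (k - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    F = ms_cond / ms_err if ms_err > 0 else np.inf
    eps = 1.0
    if gg_correction:
        # Greenhouse-Geisser epsilon from the double-centered covariance.
        S = np.cov(x, rowvar=False, ddof=1)
        Sc = S - S.mean(axis=0, keepdims=True) - S.mean(axis=1, keepdims=True) + S.mean()
        eps = float(np.trace(Sc) ** 2 / ((k - 1) * np.sum(Sc**2)))
        eps = min(1.0, max(eps, 1.0 / (k - 1)))
    d1, d2 = df1 * eps, df2 * eps
    p = float(sps.f.sf(F, d1, d2))
    return dict(F=float(F), df1=float(d1), df2=float(d2), p=p,
                partial_eta_sq=float(ss_cond / (ss_cond + ss_err)),
                gg_epsilon=float(eps))
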