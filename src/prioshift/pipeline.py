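"""End-to-end orchestration: simulate N participants, run the behavioral,
spectral, decoding and statistical analyses, and write a reproducible report
bundle (tidy TSVs + one JSON summary).

The analysis sequence mirrors the study: behavioral switch costs and
psychometric fits; surface-Laplacian + Hanning-taper TFR with a cluster-
corrected switch-vs-repeat contrast at central and frontal channel sets;
item-distance regressions on band power (with a distance-level repeated-
measures ANOVA for beta); and trial-wise power-vs-decoding regressions plus
the 8-bin analysis for cued, uncued and cross-decoded orientation scores.

Everything is keyed off a single master seed (per-participant seeds are
spawned from it), and the written bundle contains no wall-clock information,
so identical configurations and seeds give byte-identical bundles.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior, decoding, spectral, stats, synth
from .containers import EpochSet
from .io import read_epochs, read_trial_table, write_trial_table
from .montage import CENTRAL_CHANNELS, FRONTAL_CHANNELS, POSTERIOR_ALPHA_CHANNELS

__all__ = ["RunConfig", "run_synthetic_study", "run_import_study"]

PROFILES = {
    "full": dict(n_participants=43, n_blocks=128, n_perm=10000,
                 decode_timepoints=tuple(np.round(np.arange(0.8, 1.4001, 0.05), 10))),
    "ci": dict(n_participants=8, n_blocks=16, n_perm=1000,
               decode_timepoints=(1.0, 1.05, 1.1, 1.15, 1.2)),
}


@dataclass
class RunConfig:
    """Serializable configuration of a full synthetic-study run."""

    profile: str = "ci"
    n_participants: int | None = None
    n_blocks: int | None = None
    n_perm: int | None = None
    decode_timepoints: tuple | None = None
    decode_targets: tuple = ("cued", "uncued", "cross")
    score_window: tuple[float, float] = (1.0, 1.2)
    master_seed: int = 0
    cluster_threshold_p: float = 0.05
    task: dict = field(default_factory=dict)       # TaskConfig overrides
    signal: dict = field(default_factory=dict)     # SignalSpec overrides
    behavior_params: dict | None = None            # condition -> psychometric params

    def resolved(self) -> "RunConfig":
        if self.profile not in PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}")
        prof = PROFILES[self.profile]
        out = RunConfig(**{**asdict(self)})
        for key in ("n_participants", "n_blocks", "n_perm", "decode_timepoints"):
            if getattr(out, key) is None:
                setattr(out, key, prof[key])
        return out

    def to_dict(self) -> dict:
        d = asdict(self)
        d["decode_timepoints"] = None if self.decode_timepoints is None else [float(t) for t in self.decode_timepoints]
        d["decode_targets"] = list(self.decode_targets)
        d["score_window"] = [float(v) for v in self.score_window]
        return d

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("decode_timepoints", "decode_targets", "score_window"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)


def _log(stage: str, **kv) -> None:
    print(json.dumps({"stage": stage, **kv}), file=sys.stderr, flush=True)


def _participant_seeds(master_seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(master_seed).spawn(n)]


TFR_CHANNELS = tuple(CENTRAL_CHANNELS) + tuple(FRONTAL_CHANNELS) + tuple(POSTERIOR_ALPHA_CHANNELS)


def _analyze_participant(pid: int, trials: pd.DataFrame, epochs: EpochSet, config: RunConfig) -> dict:
    """All per-participant computations; returns tables and effect maps."""
    out: dict = {"pid": pid}

    # --- spectral: CSD -> TFR -> baseline -> per-trial band power
    csd = spectral.surface_laplacian(epochs)
    tfr = spectral.tfr_hanning(csd, channels=TFR_CHANNELS)
    tfr = spectral.baseline_db(tfr)
    trials = trials.copy()
    trials["participant"] = pid
    for preset in ("beta", "theta", "alpha"):
        trials[f"{preset}_power"] = spectral.band_power(tfr, preset=preset)

    # switch-vs-repeat dB contrast maps (freq x time) at the central and
    # frontal sets, used for the group cluster tests
    is_sw = (trials["condition"] == "switch").to_numpy()
    is_rep = trials["condition"].isin(["repeat1", "repeat2plus"]).to_numpy()
    from .montage import channel_indices

    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", "Mean of empty slice")
        for name, chans in (("central", CENTRAL_CHANNELS), ("frontal", FRONTAL_CHANNELS)):
            ci = channel_indices(tfr.channels, chans)
            chan_mean = np.nanmean(tfr.power[:, ci], axis=1)  # trials x freqs x times
            out[f"contrast_{name}"] = (np.nanmean(chan_mean[is_sw], axis=0)
                                       - np.nanmean(chan_mean[is_rep], axis=0))
    out["tfr_freqs"] = tfr.freqs
    out["tfr_times"] = tfr.times

    # --- decoding: per-trial scores averaged over the post-probe score window
    lo, hi = config.score_window
    res = decoding.crossval_decode(epochs, trials, target=list(config.decode_targets),
                                   timepoints=config.decode_timepoints)
    win = res[(res["timepoint"] >= lo - 1e-9) & (res["timepoint"] <= hi + 1e-9)]
    for target in config.decode_targets:
        per_trial = win[win["target"] == target].groupby("trial")["score"].mean()
        trials[f"decoding_{target}"] = per_trial.reindex(np.arange(len(trials))).to_numpy()

    out["trials"] = trials
    return out


def _group_stage(results: list[dict], config: RunConfig, out_dir: Path) -> dict:
    """Group-level statistics over per-participant results; writes the bundle."""
    summary: dict = {"config": config.to_dict(), "config_hash": config.config_hash,
                     "n_participants": len(results)}
    trials = pd.concat([r["trials"] for r in results], ignore_index=True)
    write_trial_table(trials, out_dir / "trials.tsv")

    # --- behavior
    sc = behavior.switch_cost_summary(trials)
    sc["summary"].to_csv(out_dir / "switch_costs.tsv", sep="\t", index=False, float_format="%.10g")
    sc["tests"].to_csv(out_dir / "switch_cost_tests.tsv", sep="\t", index=False, float_format="%.10g")

    fits = []
    for pid, g in trials.groupby("participant"):
        for cond in ("switch", "repeat"):
            params = behavior.fit_psychometric(g, include_swap=False, condition_filter=cond,
                                               min_trials=20)
            fits.append(dict(participant=pid, condition=cond, lapse=params.lapse,
                             sigma=params.sigma, p_swap=params.p_swap,
                             neg_log_lik=params.neg_log_lik, n_trials=params.n_trials))
    pd.DataFrame(fits).to_csv(out_dir / "psychometric_fits.tsv", sep="\t", index=False,
                              float_format="%.10g")

    dist_tables = []
    for outcome in ("accuracy", "rt"):
        de = behavior.distance_effect(trials, outcome=outcome)
        de["slopes"]["outcome"] = outcome
        de["tests"]["outcome"] = outcome
        dist_tables.append(de)
    pd.concat([d["slopes"] for d in dist_tables]).to_csv(
        out_dir / "distance_slopes.tsv", sep="\t", index=False, float_format="%.10g")
    pd.concat([d["tests"] for d in dist_tables]).to_csv(
        out_dir / "distance_slope_tests.tsv", sep="\t", index=False, float_format="%.10g")

    # --- cluster-corrected switch-vs-repeat TFR contrasts
    cluster_out = {}
    for name in ("central", "frontal"):
        maps = np.stack([r[f"contrast_{name}"] for r in results])
        cs = stats.cluster_permutation(maps, n_perm=config.n_perm,
                                       threshold_p=config.cluster_threshold_p,
                                       seed=config.master_seed + 7919)
        cluster_out[name] = dict(clusters=cs.clusters, threshold_t=cs.threshold_t,
                                 n_permutations=cs.n_permutations)
    summary["tfr_cluster_tests"] = cluster_out

    # --- band power vs item distance (regression + ANOVA over distance levels)
    df2 = trials[trials["condition"] != "block_start"].copy()
    df2["cond2"] = np.where(df2["condition"] == "switch", "switch", "repeat")
    band_tests = {}
    for preset in ("beta", "theta"):
        coefs = stats.ztrial_regress(df2, y=f"{preset}_power", predictors=["item_distance"],
                                     condition_col="cond2")
        coefs.to_csv(out_dir / f"{preset}_distance_coefs.tsv", sep="\t", index=False,
                     float_format="%.10g")
        slopes = coefs[coefs["term"] == "item_distance"].pivot(
            index="participant", columns="cond2", values="coef")
        band_tests[preset] = {
            "switch": stats.group_ttest(slopes["switch"].to_numpy()),
            "repeat": stats.group_ttest(slopes["repeat"].to_numpy()),
            "switch_vs_repeat": stats.group_ttest(slopes["switch"].to_numpy(),
                                                  paired_with=slopes["repeat"].to_numpy()),
        }
        # distance-level repeated-measures ANOVA (7 levels), main + interaction
        lvl = df2.pivot_table(index="participant", columns="item_distance",
                              values=f"{preset}_power", aggfunc="mean")
        if lvl.notna().all().all() and lvl.shape[1] >= 2:
            band_tests[preset]["anova_main"] = stats.rm_anova_1way(lvl.to_numpy())
            diff = (df2[df2["cond2"] == "switch"].pivot_table(
                        index="participant", columns="item_distance",
                        values=f"{preset}_power", aggfunc="mean")
                    - df2[df2["cond2"] == "repeat"].pivot_table(
                        index="participant", columns="item_distance",
                        values=f"{preset}_power", aggfunc="mean"))
            if diff.notna().all().all():
                band_tests[preset]["anova_interaction"] = stats.rm_anova_1way(diff.to_numpy())
    summary["band_distance_tests"] = band_tests

    # --- power -> decoding regressions and 8-bin analysis
    decode_tests = {}
    for target in config.decode_targets:
        col = f"decoding_{target}"
        tcol = {}
        for power in ("beta_power", "theta_power"):
            coefs = stats.ztrial_regress(df2.dropna(subset=[col]), y=col,
                                         predictors=[power, "item_distance"],
                                         condition_col="cond2", interaction=True)
            wide = coefs[coefs["term"] == power].pivot(index="participant",
                                                       columns="cond2", values="coef")
            tcol[power] = {
                "switch": stats.group_ttest(wide["switch"].to_numpy()),
                "repeat": stats.group_ttest(wide["repeat"].to_numpy()),
                "switch_vs_repeat": stats.group_ttest(wide["switch"].to_numpy(),
                                                      paired_with=wide["repeat"].to_numpy()),
            }
        ba = stats.bin_analysis(df2.dropna(subset=[col]), power="beta_power", score=col,
                                condition_col="cond2")
        ba["bins"].to_csv(out_dir / f"bins_{target}.tsv", sep="\t", index=False,
                          float_format="%.10g")
        ba["slopes"].to_csv(out_dir / f"bin_slopes_{target}.tsv", sep="\t", index=False,
                            float_format="%.10g")
        tcol["bin_slope_tests"] = ba["tests"]
        decode_tests[target] = tcol
    summary["power_decoding_tests"] = decode_tests

    (out_dir / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True, default=float) + "\n")
    return summary


def run_synthetic_study(config: RunConfig, out_dir) -> dict:
    """Simulate N independent participants and run the full analysis chain."""
    config = config.resolved()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))

    seeds = _participant_seeds(config.master_seed, config.n_participants)
    results = []
    for pid, seed in enumerate(seeds):
        _log("simulate", participant=pid, seed=seed)
        task_cfg = synth.TaskConfig(n_blocks=config.n_blocks, **config.task)
        signal = synth.SignalSpec(**config.signal)
        trials, epochs = synth.simulate_dataset(task_cfg, signal,
                                                params_by_condition=config.behavior_params,
                                                seed=seed)
        _log("analyze", participant=pid)
        results.append(_analyze_participant(pid, trials, epochs, config))
        del epochs
    _log("group")
    return _group_stage(results, config, out_dir)


def run_import_study(datasets, config: RunConfig, out_dir) -> dict:
    """Run the analysis chain on imported (trial-table TSV, epoch HDF5) pairs.

    ``datasets`` is a sequence of (trials_path, epochs_path). Schema
    violations are collected and reported per file before aborting.
    """
    config = config.resolved()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))

    loaded, errors = [], []
    for trials_path, epochs_path in datasets:
        try:
            trials = read_trial_table(trials_path)
        except Exception as e:  # noqa: BLE001 - report all schema problems at once
            errors.append(f"{trials_path}: {e}")
            continue
        try:
            epochs = read_epochs(epochs_path)
        except Exception as e:  # noqa: BLE001
            errors.append(f"{epochs_path}: {e}")
            continue
        if len(trials) != epochs.n_trials:
            errors.append(f"{epochs_path}: {epochs.n_trials} epochs vs {len(trials)} trials")
            continue
        loaded.append((trials, epochs))
    if errors:
        raise ValueError("import failed:\n" + "\n".join(errors))

    results = []
    for pid, (trials, epochs) in enumerate(loaded):
        _log("analyze", participant=pid)
        results.append(_analyze_participant(pid, trials, epochs, config))
    _log("group")
    return _group_stage(results, config, out_dir)
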