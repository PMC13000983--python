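"""Reading and writing of trial tables (TSV) and epoch containers (HDF5 + JSON sidecar)."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import EpochSet, TRIAL_COLUMNS, validate_trial_table


def write_trial_table(trials: pd.DataFrame, path) -> None:
    validate_trial_table(trials)
    cols = [c for c in TRIAL_COLUMNS if c in trials.columns]
    extra = [c for c in trials.columns if c not in cols]
    trials[cols + extra].to_csv(path, sep="\t", index=False, float_format="%.10g", na_rep="NA")


def read_trial_table(path) -> pd.DataFrame:
    trials = pd.read_csv(path, sep="\t", na_values=["NA"])
    validate_trial_table(trials)
    return trials


def write_epochs(epochs: EpochSet, path) -> None:
    """One 3-D dataset plus attributes; axis metadata duplicated in a JSON sidecar."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        d = f.create_dataset("data", data=epochs.data)
        d.attrs["sfreq"] = epochs.sfreq
        d.attrs["csd_applied"] = epochs.csd_applied
        f.create_dataset("times", data=epochs.times)
        f.create_dataset("channels", data=np.array(epochs.channels, dtype="S"))
        if epochs.positions is not None:
            f.create_dataset("positions", data=epochs.positions)
    sidecar = dict(
        sfreq=epochs.sfreq,
        n_trials=int(epochs.n_trials),
        n_channels=len(epochs.channels),
        n_samples=int(epochs.times.size),
        tmin=float(epochs.times[0]),
        tmax=float(epochs.times[-1]),
        channels=list(epochs.channels),
        csd_applied=bool(epochs.csd_applied),
    )
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1) + "\n")


def read_epochs(path) -> EpochSet:
    path = Path(path)
    with h5py.File(path, "r") as f:
        for key in ("data", "times", "channels"):
            if key not in f:
                raise ValueError(f"epoch file {path} is missing dataset '{key}'")
        data = f["data"][...]
        if data.ndim != 3:
            raise ValueError("epoch file 'data' must be trials x channels x samples")
        times = f["times"][...]
        channels = tuple(c.decode() for c in f["channels"][...])
        positions = f["positions"][...] if "positions" in f else None
        sfreq = float(f["data"].attrs["sfreq"])
        csd = bool(f["data"].attrs.get("csd_applied", False))
    return EpochSet(data=data, times=times, sfreq=sfreq, channels=channels,
                    positions=positions, csd_applied=csd)
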