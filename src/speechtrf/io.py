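"""Container I/O: EEG recordings, stimulus matrices and TRF sets in HDF5,
scores and feature tables as TSV."""

from __future__ import annotations

import h5py
import numpy as np
import pandas as pd

from .preprocess import EEGRecording
from .stimulus import StimulusMatrix
from .trf import LagAxis, TRFSet

__all__ = [
    "save_recording", "load_recording",
    "save_stimulus", "load_stimulus",
    "save_trfset", "load_trfset",
    "write_scores_tsv", "read_scores_tsv",
]


def _str_attr(value) -> list[str]:
    return [s.decode() if isinstance(s, bytes) else str(s) for s in value]


def save_recording(rec: EEGRecording, path, group: str = "eeg") -> None:
    with h5py.File(path, "a") as f:
        if group in f:
            del f[group]
        g = f.create_group(group)
        g.create_dataset("values", data=rec.values)
        g.attrs["fs"] = rec.fs
        g.attrs["channel_names"] = list(rec.channel_names)
        g.create_dataset("trials", data=np.asarray(rec.trials, dtype=int)
                         .reshape(-1, 2))


def load_recording(path, group: str = "eeg") -> EEGRecording:
    with h5py.File(path, "r") as f:
        g = f[group]
        return EEGRecording(
            values=g["values"][()], fs=float(g.attrs["fs"]),
            channel_names=tuple(_str_attr(g.attrs["channel_names"])),
            trials=[tuple(t) for t in g["trials"][()]])


def save_stimulus(stim: StimulusMatrix, path, group: str | None = None) -> None:
    group = group or f"stim/{stim.trial_id}/{stim.scheme}"
    with h5py.File(path, "a") as f:
        if group in f:
            del f[group]
        g = f.create_group(group)
        g.create_dataset("values", data=stim.values)
        g.attrs["fs"] = stim.fs
        g.attrs["scheme"] = stim.scheme
        g.attrs["trial_id"] = stim.trial_id
        g.attrs["feature_names"] = list(stim.feature_names)


def load_stimulus(path, group: str) -> StimulusMatrix:
    with h5py.File(path, "r") as f:
        g = f[group]
        return StimulusMatrix(
            scheme=str(g.attrs["scheme"]),
            feature_names=_str_attr(g.attrs["feature_names"]),
            values=g["values"][()], fs=float(g.attrs["fs"]),
            trial_id=str(g.attrs["trial_id"]))


def save_trfset(trf: TRFSet, path, group: str | None = None) -> None:
    group = group or f"trf/{trf.participant_id or 'p'}/{trf.scheme}"
    with h5py.File(path, "a") as f:
        if group in f:
            del f[group]
        g = f.create_group(group)
        g.create_dataset("weights", data=trf.weights)
        g.create_dataset("intercept", data=trf.intercept)
        if trf.residual_variance is not None:
            g.create_dataset("residual_variance", data=trf.residual_variance)
        g.attrs["scheme"] = trf.scheme
        g.attrs["participant_id"] = trf.participant_id
        g.attrs["feature_names"] = list(trf.feature_names)
        g.attrs["channel_names"] = list(trf.channel_names)
        g.attrs["lag_min_ms"] = trf.lag_axis.lag_min_ms
        g.attrs["lag_max_ms"] = trf.lag_axis.lag_max_ms
        g.attrs["fs"] = trf.lag_axis.fs


def load_trfset(path, group: str) -> TRFSet:
    with h5py.File(path, "r") as f:
        g = f[group]
        lag_axis = LagAxis(float(g.attrs["lag_min_ms"]),
                           float(g.attrs["lag_max_ms"]), float(g.attrs["fs"]))
        rv = g["residual_variance"][()] if "residual_variance" in g else None
        return TRFSet(
            scheme=str(g.attrs["scheme"]),
            feature_names=_str_attr(g.attrs["feature_names"]),
            lag_axis=lag_axis, weights=g["weights"][()],
            intercept=g["intercept"][()],
            channel_names=tuple(_str_attr(g.attrs["channel_names"])),
            participant_id=str(g.attrs["participant_id"]),
            residual_variance=rv)


def write_scores_tsv(scores, path, participant_ids=None) -> None:
    ids = participant_ids or [f"p{i:03d}" for i in range(len(scores))]
    pd.DataFrame({"participant_id": ids, "score": np.asarray(scores)}) \
        .to_csv(path, sep="\t", index=False)


def read_scores_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
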