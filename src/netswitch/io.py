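"""File interfaces: EDF export, TSV tables, HDF5 trial tensors, JSON summaries.

EDF quantizes to 16 bits, so a lossless ``.npz`` sidecar accompanies each
exported recording for bit-exact round trips; the EDF itself is readable by
any standard EEG toolchain (validated against the MNE reader in the tests).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .preprocess import Recording, TrialTensor

__all__ = [
    "write_edf",
    "write_events_tsv",
    "read_events_tsv",
    "write_electrodes_tsv",
    "read_electrodes_tsv",
    "save_trials",
    "load_trials",
    "write_json",
]


def _pad(text: str, n: int) -> bytes:
    b = text.encode("ascii", "replace")[:n]
    return b + b" " * (n - len(b))


def write_edf(recording: Recording, path, sidecar: bool = True) -> Path:
    """Write a continuous recording as EDF (plus a lossless .npz sidecar).

    One-second data records; the signal is zero-padded to a whole number of
    seconds.  Per-channel physical scaling maps the data range onto the full
    16-bit digital range.
    """
    path = Path(path)
    x = recording.signal
    fs = int(round(recording.fs))
    if not np.isclose(recording.fs, fs):
        raise ValueError("EDF export requires an integer sampling rate")
    n_ch = x.shape[1]
    n_rec = int(np.ceil(x.shape[0] / fs))
    padded = np.zeros((n_rec * fs, n_ch))
    padded[: x.shape[0]] = x
    pmin = padded.min(axis=0)
    pmax = padded.max(axis=0)
    same = pmax <= pmin
    pmax = np.where(same, pmin + 1.0, pmax)
    dmin, dmax = -32768, 32767
    gain = (dmax - dmin) / (pmax - pmin)
    digital = np.round((padded - pmin) * gain + dmin).astype("<i2")

    header = bytearray()
    header += _pad("0", 8)
    header += _pad("X X X X", 80)
    header += _pad("Startdate X X X X", 80)
    header += _pad("01.01.00", 8) + _pad("00.00.00", 8)
    header += _pad(str(256 * (1 + n_ch)), 8)
    header += _pad("", 44)
    header += _pad(str(n_rec), 8)
    header += _pad("1", 8)
    header += _pad(str(n_ch), 4)
    names = [str(n) for n in recording.contacts["name"]]
    for field, width in (
        (names, 16),
        (["" for _ in names], 80),
        (["uV" for _ in names], 8),
        ([f"{v:.6g}" for v in pmin], 8),
        ([f"{v:.6g}" for v in pmax], 8),
        ([str(dmin) for _ in names], 8),
        ([str(dmax) for _ in names], 8),
        (["" for _ in names], 80),
        ([str(fs) for _ in names], 8),
        (["" for _ in names], 32),
    ):
        for val in field:
            header += _pad(val, width)
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        for r in range(n_rec):
            fh.write(digital[r * fs:(r + 1) * fs].T.tobytes())
    if sidecar:
        np.savez_compressed(
            path.with_suffix(".npz"), signal=recording.signal,
            fs=recording.fs)
    return path


def write_events_tsv(recording: Recording, path) -> Path:
    path = Path(path)
    df = pd.DataFrame({
        "onset_s": recording.events["onset_sample"] / recording.fs,
        "condition": recording.events["condition"],
    })
    df.to_csv(path, sep="\t", index=False)
    return path


def read_events_tsv(path, fs: float) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return pd.DataFrame({
        "onset_sample": np.round(df["onset_s"] * fs).astype(int),
        "condition": df["condition"],
    })


def write_electrodes_tsv(contacts: pd.DataFrame, path) -> Path:
    path = Path(path)
    cols = [c for c in ("name", "shank", "pos", "x", "y", "z", "network")
            if c in contacts.columns]
    contacts[cols].to_csv(path, sep="\t", index=False)
    return path


def read_electrodes_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_trials(trials: TrialTensor, path) -> Path:
    """Persist a trial tensor (data, mask, axes, channel table) to HDF5."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["fs"] = trials.fs
        f.create_dataset("times", data=trials.times)
        for cond, d in trials.data.items():
            g = f.create_group(f"condition/{cond}")
            g.create_dataset("data", data=d, compression="gzip",
                             compression_opts=1)
            g.create_dataset("onsets", data=trials.onsets[cond])
            if trials.mask is not None:
                g.create_dataset("mask", data=trials.mask[cond],
                                 compression="gzip", compression_opts=1)
        ch = f.create_group("channels")
        for col in trials.channels.columns:
            vals = trials.channels[col].to_numpy()
            if vals.dtype == object:
                vals = vals.astype("S")
            ch.create_dataset(col, data=vals)
    return path


def load_trials(path) -> TrialTensor:
    with h5py.File(path, "r") as f:
        fs = float(f.attrs["fs"])
        times = f["times"][()]
        data, onsets, mask = {}, {}, {}
        for cond in f["condition"]:
            g = f[f"condition/{cond}"]
            data[cond] = g["data"][()]
            onsets[cond] = g["onsets"][()]
            if "mask" in g:
                mask[cond] = g["mask"][()]
        cols = {}
        for col in f["channels"]:
            v = f["channels"][col][()]
            if v.dtype.kind == "S":
                v = v.astype(str)
            cols[col] = v
    return TrialTensor(data=data, times=times, fs=fs,
                       channels=pd.DataFrame(cols), onsets=onsets,
                       mask=mask or None)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_json(obj, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=1, sort_keys=True)
    return path
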