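"""Continuous-recording preprocessing: referencing, filtering, epoching, rejection.

The stages mirror standard depth-electrode (stereo-EEG) practice: contacts on a
shank are re-referenced to their nearest neighbour (bipolar derivation, deepest
contact first), slow drifts and line noise are removed with zero-phase
Butterworth filters, recordings sampled above 512 Hz are decimated, and trials
are cut around each attention-switch event into a ``time x channels x trials``
tensor per condition.  Amplitude-based artifact rejection marks supra-threshold
epochs (plus safety margins) in a boolean mask; whole trials are never dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .bands import CONDITIONS

__all__ = [
    "Recording",
    "TrialTensor",
    "bipolar_reference",
    "filter_chain",
    "downsample",
    "extract_trials",
    "reject_epochs",
]


@dataclass
class Recording:
    """One continuous multichannel session.

    Parameters
    ----------
    signal : ndarray, shape (n_samples, n_contacts)
        Voltage traces in microvolts.
    fs : float
        Sampling rate in Hz.
    contacts : DataFrame
        One row per contact/channel with at least ``name``, ``shank``, ``pos``
        (position index on the shank, 1 = deepest) and ``x, y, z`` (MNI mm).
        An optional boolean ``excluded`` column flags broken or clinically
        excluded contacts.
    events : DataFrame
        Trial markers with ``onset_sample`` (int) and ``condition`` columns.
    """

    signal: np.ndarray
    fs: float
    contacts: pd.DataFrame
    events: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["onset_sample", "condition"]))

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (samples x contacts)")
        if self.signal.shape[1] != len(self.contacts):
            raise ValueError("contact table length does not match signal columns")
        if "excluded" not in self.contacts.columns:
            self.contacts = self.contacts.assign(excluded=False)

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class TrialTensor:
    """Epoched trials ``D(t, ch, tr)`` per attention-switching condition.

    ``times`` is the shared time axis in seconds relative to the switch
    (``t = 0`` at the event onset); epochs are half-open ``[start, end)`` in
    samples.  ``mask`` (same shape as ``data``) is True where a sample is
    excluded from averages.
    """

    data: dict[str, np.ndarray]
    times: np.ndarray
    fs: float
    channels: pd.DataFrame
    onsets: dict[str, np.ndarray]
    mask: dict[str, np.ndarray] | None = None

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(self.data)

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def n_trials(self, condition: str) -> int:
        return self.data[condition].shape[2]


def bipolar_reference(recording: Recording) -> Recording:
    """Derive bipolar channels from adjacent contact pairs on each shank.

    Starting from the deepest contact, each usable contact is referenced to its
    nearest shallower neighbour: ``channel = deeper - shallower``.  A broken or
    excluded contact breaks the adjacency chain (no skip-pairing), and a shank
    with fewer than two usable contacts contributes no channels.  The channel
    coordinate is the arithmetic midpoint of the pair.
    """
    contacts = recording.contacts
    out_sig: list[np.ndarray] = []
    rows: list[dict] = []
    extra_cols = [c for c in contacts.columns
                  if c not in ("name", "shank", "pos", "x", "y", "z", "excluded")]
    n_pairs = 0
    for shank, grp in contacts.groupby("shank", sort=False):
        grp = grp.sort_values("pos")
        idx = grp.index.to_numpy()
        usable = ~grp["excluded"].to_numpy(dtype=bool)
        pairs = [(idx[i], idx[i + 1]) for i in range(len(idx) - 1)
                 if usable[i] and usable[i + 1]]
        if not pairs:
            warnings.warn(f"shank {shank!r} has <2 adjacent usable contacts; skipped")
            continue
        for deep, shallow in pairs:
            ci = contacts.index.get_loc(deep)
            cj = contacts.index.get_loc(shallow)
            out_sig.append(recording.signal[:, ci] - recording.signal[:, cj])
            row = {
                "name": f"{contacts.at[deep, 'name']}-{contacts.at[shallow, 'name']}",
                "shank": shank,
                "pos": n_pairs + 1,
                "x": (contacts.at[deep, "x"] + contacts.at[shallow, "x"]) / 2.0,
                "y": (contacts.at[deep, "y"] + contacts.at[shallow, "y"]) / 2.0,
                "z": (contacts.at[deep, "z"] + contacts.at[shallow, "z"]) / 2.0,
                "excluded": False,
            }
            for c in extra_cols:
                vi, vj = contacts.at[deep, c], contacts.at[shallow, c]
                row[c] = vi if vi == vj or pd.isna(vj) else None
            rows.append(row)
            n_pairs += 1
    if not out_sig:
        raise ValueError("no shank with >=2 usable contacts; cannot re-reference")
    return Recording(
        signal=np.column_stack(out_sig),
        fs=recording.fs,
        contacts=pd.DataFrame(rows),
        events=recording.events.copy(),
    )


def _check_band(fs: float, hz: float, what: str) -> None:
    if hz >= fs / 2:
        raise ValueError(f"{what} at {hz} Hz is at/above Nyquist ({fs / 2} Hz)")


def filter_chain(
    recording: Recording,
    highpass_hz: float | None = 0.1,
    notches: tuple[tuple[float, float], ...] = ((48.0, 52.0), (98.0, 102.0)),
    order: int = 6,
) -> Recording:
    """Zero-phase Butterworth high-pass followed by band-stop (notch) filters.

    Filters are applied forward-backward (``sosfiltfilt``) so the chain has
    zero phase shift.  Notch bands at or above Nyquist raise an error naming
    the offending band.
    """
    fs = recording.fs
    x = recording.signal
    if highpass_hz is not None:
        _check_band(fs, highpass_hz, "high-pass cutoff")
        sos = sps.butter(order, highpass_hz, btype="highpass", fs=fs,
                         output="sos")
        # a deep-subsonic cutoff has second-scale zero-phase transients;
        # pad well beyond them (scipy's default padlen is far too short)
        padlen = min(x.shape[0] - 1, int(5 * fs / highpass_hz))
        x = sps.sosfiltfilt(sos, x, axis=0, padlen=padlen)
    for lo, hi in notches:
        _check_band(fs, hi, f"band-stop {lo}-{hi} Hz")
        sos = sps.butter(order, [lo, hi], btype="bandstop", fs=fs, output="sos")
        if not np.all(np.abs(np.linalg.eigvals(_sos_companion(sos))) < 1.0 + 1e-9):
            raise ValueError(f"unstable band-stop design for {lo}-{hi} Hz at fs={fs}")
        x = sps.sosfiltfilt(sos, x, axis=0)
    return replace(recording, signal=x, contacts=recording.contacts.copy(),
                   events=recording.events.copy())


def _sos_companion(sos: np.ndarray) -> np.ndarray:
    # Companion matrix of the cascaded denominator, for a stability check.
    a = np.array([1.0])
    for sec in sos:
        a = np.convolve(a, sec[3:])
    n = len(a) - 1
    comp = np.zeros((n, n))
    comp[0] = -a[1:] / a[0]
    comp[1:, :-1] = np.eye(n - 1)
    return comp


def downsample(recording: Recording, target_fs: float = 512.0) -> Recording:
    """Anti-alias filter and decimate to ``target_fs`` (integer ratio only)."""
    fs = recording.fs
    if np.isclose(fs, target_fs):
        return recording
    ratio = fs / target_fs
    q = int(round(ratio))
    if not np.isclose(ratio, q):
        raise ValueError(f"fs {fs} is not an integer multiple of target {target_fs}")
    x = sps.resample_poly(recording.signal, 1, q, axis=0)
    events = recording.events.copy()
    events["onset_sample"] = (events["onset_sample"] // q).astype(int)
    return Recording(signal=x, fs=target_fs, contacts=recording.contacts.copy(),
                     events=events)


def extract_trials(
    recording: Recording,
    span: tuple[float, float] = (-4.0, 4.0),
    max_trials_per_condition: int = 60,
    conditions: tuple[str, ...] = CONDITIONS,
) -> TrialTensor:
    """Cut epochs around each event into ``D(t, ch, tr)`` per condition.

    Epochs whose span falls outside the session are dropped with a warning;
    a condition with zero extractable trials raises.
    """
    fs = recording.fs
    n_pre = int(round(span[0] * fs))
    n_post = int(round(span[1] * fs))
    times = np.arange(n_pre, n_post) / fs
    n_len = n_post - n_pre
    data: dict[str, np.ndarray] = {}
    onsets: dict[str, np.ndarray] = {}
    events = recording.events.sort_values("onset_sample")
    for cond in conditions:
        evs = events.loc[events["condition"] == cond, "onset_sample"].to_numpy(int)
        kept, dropped = [], 0
        for s in evs:
            if s + n_pre < 0 or s + n_post > recording.n_samples:
                dropped += 1
                continue
            kept.append(s)
            if len(kept) >= max_trials_per_condition:
                break
        if dropped:
            warnings.warn(f"{dropped} {cond} trial(s) dropped: epoch outside session")
        if not kept:
            raise ValueError(f"no extractable trials for condition {cond!r}")
        epochs = np.stack(
            [recording.signal[s + n_pre:s + n_post] for s in kept], axis=2)
        assert epochs.shape[0] == n_len
        data[cond] = epochs
        onsets[cond] = np.asarray(kept, dtype=int)
    return TrialTensor(data=data, times=times, fs=fs,
                       channels=recording.contacts.copy(), onsets=onsets)


def reject_epochs(
    trials: TrialTensor,
    recording: Recording,
    sd_threshold: float = 6.0,
    margin_ms: float = 100.0,
) -> dict[str, np.ndarray]:
    """Mask samples whose continuous amplitude strays beyond ``sd_threshold`` SDs.

    Mean and SD are computed per channel on the *continuous* session signal
    (before epoching).  Contiguous supra-threshold runs are extended by
    ``margin_ms`` on each side and mapped into the trial tensor; the mask is
    stored on ``trials.mask`` and returned.  Whole trials are never dropped.
    """
    x = recording.signal
    if x.shape[1] != trials.n_channels:
        raise ValueError("recording/trials channel mismatch")
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    margin = int(round(margin_ms / 1000.0 * recording.fs))
    cont_mask = np.zeros_like(x, dtype=bool)
    for ch in range(x.shape[1]):
        if sd[ch] == 0:
            warnings.warn(f"channel {ch} has zero variance; rejection skipped")
            continue
        bad = np.abs(x[:, ch] - mu[ch]) > sd_threshold * sd[ch]
        if not bad.any():
            continue
        # dilate each run by the margin
        edges = np.flatnonzero(np.diff(np.r_[0, bad.view(np.int8), 0]))
        for start, stop in zip(edges[::2], edges[1::2]):
            cont_mask[max(0, start - margin):min(x.shape[0], stop + margin), ch] = True
    n_pre = int(round(trials.times[0] * trials.fs))
    n_len = len(trials.times)
    mask: dict[str, np.ndarray] = {}
    for cond, ons in trials.onsets.items():
        m = np.stack([cont_mask[s + n_pre:s + n_pre + n_len] for s in ons], axis=2)
        mask[cond] = m
    trials.mask = mask
    return mask
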