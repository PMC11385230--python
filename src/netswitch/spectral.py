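"""Normalized relative band power (RBP) via STFT, with a Morlet-wavelet check.

The time-resolved power spectral density is estimated with Hann-windowed
periodograms slid in 31.25 ms steps; the window length depends on the band
group (2 s for delta, 1 s for theta, 0.5 s for everything faster) so slow
oscillations get adequate spectral resolution.  Power is converted to dB and
z-scored per frequency bin and channel against the statistics of the whole
recording session -- this removes the 1/f background and puts every frequency
on a comparable scale.  Band averages of the z-scored bins yield
``RBP(t, fb, ch, tr)``; bins inside the line-noise notches never enter the
high-gamma average.

A Morlet-wavelet path (:func:`wavelet_rbp`) provides an independent PSD
estimate on the same time grid for validating the STFT pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.fft import rfft, rfftfreq

from .bands import BANDS, BAND_NAMES, STEP_S, WINDOW_GROUPS, band_bins
from .preprocess import Recording, TrialTensor

__all__ = [
    "NormFactors",
    "RbpResult",
    "stft_psd",
    "session_norm_factors",
    "normalize_psd",
    "band_average",
    "rbp_from_recording",
    "rbp_from_trials",
    "wavelet_rbp",
    "condition_means",
]

_FLOOR_MIN = 1e-30


@dataclass
class NormFactors:
    """Per-bin z-score factors: session-wide mean/SD of dB power."""

    mu: np.ndarray        # (n_freqs, n_channels)
    sigma: np.ndarray     # (n_freqs, n_channels)
    freqs: np.ndarray
    floor: float


@dataclass
class RbpResult:
    """Relative band power ``RBP(t, fb, ch, tr)`` per condition."""

    times: np.ndarray
    band_names: tuple[str, ...]
    data: dict[str, np.ndarray]
    step_mask: dict[str, np.ndarray] | None = None  # True = step excluded


def _auto_floor(power: np.ndarray) -> float:
    pos = power[power > 0]
    if pos.size == 0:
        return _FLOOR_MIN
    return max(float(np.median(pos)) * 1e-12, _FLOOR_MIN)


def _centers(n_samples: int, nperseg: int, step: int, offset: int = 0):
    """Valid window-center sample indices, aligned to multiples of ``step``.

    ``offset`` shifts the alignment origin (e.g. the sample of trial time 0).
    """
    half = nperseg // 2
    lo = half
    hi = n_samples - (nperseg - half)
    if hi < lo:
        raise ValueError("signal shorter than the analysis window")
    k_lo = int(np.ceil((lo - offset) / step))
    k_hi = int(np.floor((hi - offset) / step))
    return offset + np.arange(k_lo, k_hi + 1) * step


def _psd_segments(x: np.ndarray, centers: np.ndarray, nperseg: int, fs: float):
    """Hann periodogram at each window center.

    ``x`` has time on axis 0; output is (n_centers, n_freqs, ...).
    """
    win = sps.get_window("hann", nperseg, fftbins=True)
    scale = 1.0 / (fs * (win ** 2).sum())
    half = nperseg // 2
    idx = centers[:, None] - half + np.arange(nperseg)[None, :]
    segs = x[idx]  # (n_centers, nperseg, ...)
    wshape = (1, nperseg) + (1,) * (segs.ndim - 2)
    spec = rfft(segs * win.reshape(wshape), axis=1)
    p = (np.abs(spec) ** 2) * scale
    p[:, 1:] *= 2.0
    if nperseg % 2 == 0:
        p[:, -1] /= 2.0
    return p


def stft_psd(
    x: np.ndarray,
    fs: float,
    window_s: float,
    step_s: float = STEP_S,
    t0_sample: int = 0,
    floor: float | str = "auto",
):
    """Sliding Hann-windowed PSD in dB.

    Parameters
    ----------
    x : ndarray
        Either a continuous ``(n_samples, n_channels)`` session or epoched
        trials ``(n_times, n_channels, n_trials)``.
    window_s : float
        Window length in seconds (band-group dependent).
    t0_sample : int
        Sample index of time zero; window centers are placed at multiples of
        ``step_s`` relative to it, so tensors from different window lengths
        share one grid.
    floor : float or "auto"
        Additive power floor before the log; "auto" uses 1e-12 of the median
        positive power (with an absolute minimum) so silent input stays finite.

    Returns
    -------
    times, freqs, psd_db, floor_used
        ``psd_db`` has shape ``(n_steps, n_freqs) + x.shape[1:]``.
    """
    x = np.asarray(x, dtype=float)
    nperseg = int(round(window_s * fs))
    step = int(round(step_s * fs))
    if not np.isclose(step_s * fs, step):
        raise ValueError("step_s must be an integer number of samples")
    centers = _centers(x.shape[0], nperseg, step, offset=t0_sample)
    p = _psd_segments(x, centers, nperseg, fs)
    if floor == "auto":
        floor = _auto_floor(p)
    psd_db = 10.0 * np.log10(p + floor)
    freqs = rfftfreq(nperseg, 1.0 / fs)
    times = (centers - t0_sample) / fs
    return times, freqs, psd_db, floor


def session_norm_factors(
    signal: np.ndarray,
    fs: float,
    window_s: float,
    step_s: float = STEP_S,
    floor: float | str = "auto",
    chunk: int = 4096,
) -> NormFactors:
    """Mean/SD of dB power per (frequency bin, channel) over a whole session.

    Windows are streamed in chunks so arbitrarily long sessions fit in memory.
    """
    x = np.asarray(signal, dtype=float)
    nperseg = int(round(window_s * fs))
    step = int(round(step_s * fs))
    centers = _centers(x.shape[0], nperseg, step)
    freqs = rfftfreq(nperseg, 1.0 / fs)
    if floor == "auto":
        probe = _psd_segments(x, centers[: min(len(centers), 256)], nperseg, fs)
        floor = _auto_floor(probe)
    n = 0
    s1 = np.zeros((len(freqs), x.shape[1]))
    s2 = np.zeros_like(s1)
    for start in range(0, len(centers), chunk):
        p = _psd_segments(x, centers[start:start + chunk], nperseg, fs)
        db = 10.0 * np.log10(p + floor)
        n += db.shape[0]
        s1 += db.sum(axis=0)
        s2 += (db ** 2).sum(axis=0)
    mu = s1 / n
    var = np.maximum(s2 / n - mu ** 2, 0.0)
    return NormFactors(mu=mu, sigma=np.sqrt(var), freqs=freqs, floor=float(floor))


def normalize_psd(psd_db: np.ndarray, factors: NormFactors) -> np.ndarray:
    """z-score dB power per (frequency bin, channel); zero-SD bins become NaN."""
    sigma = factors.sigma
    bad = sigma <= 0
    if bad.any():
        warnings.warn(f"{int(bad.sum())} zero-variance bin(s) dropped from z-scoring")
    extra = psd_db.ndim - 3
    shape = (1,) + sigma.shape + (1,) * extra
    safe = np.where(bad, 1.0, sigma).reshape(shape)
    z = (psd_db - factors.mu.reshape(shape)) / safe
    if bad.any():
        z = np.where(bad.reshape(shape), np.nan, z)
    return z


def band_average(
    psd_z: np.ndarray,
    freqs: np.ndarray,
    bands: dict[str, tuple[float, float]],
) -> dict[str, np.ndarray]:
    """Arithmetic mean of z-scored bins inside each band (frequency axis 1)."""
    out = {}
    for name in bands:
        mask = band_bins(freqs, name, bands)
        if not mask.any():
            raise ValueError(f"band {name!r} contains no frequency bin")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out[name] = np.nanmean(psd_z[:, mask], axis=1)
    return out


def _group_floor(factors: NormFactors | None) -> float | str:
    return factors.floor if factors is not None else "auto"


def _trial_rbp_one_group(
    trials: TrialTensor,
    window_s: float,
    group_bands: tuple[str, ...],
    factors: NormFactors | None,
    t_range: tuple[float, float],
    step_s: float,
):
    """Band-averaged z-scored trial PSD for one window-length group.

    Channels are processed one at a time to bound memory.  When ``factors`` is
    None (trials-only mode) the z-score statistics are pooled per channel over
    all steps and trials of *both* conditions, so the normalization applies
    one common monotone map to the two conditions -- condition crossings are
    preserved exactly as with session-wide factors.
    """
    fs = trials.fs
    conds = list(trials.data)
    n_ch = trials.n_channels
    t0_sample = int(round(-trials.times[0] * fs))
    out: dict[str, np.ndarray] = {}
    t_out = None
    for ch in range(n_ch):
        psd_c = {}
        floor = _group_floor(factors)
        for cond in conds:
            t, f, psd_db, floor = stft_psd(
                trials.data[cond][:, ch, :][:, None, :], fs, window_s,
                step_s=step_s, t0_sample=t0_sample, floor=floor)
            keep = (t >= t_range[0] - 1e-9) & (t <= t_range[1] + 1e-9)
            psd_c[cond] = psd_db[keep]
            t_out = t[keep]
        if factors is None:
            pooled = np.concatenate(list(psd_c.values()), axis=3)
            fac = NormFactors(mu=pooled.mean(axis=(0, 3)),
                              sigma=pooled.std(axis=(0, 3)),
                              freqs=f, floor=floor)
        else:
            fac = NormFactors(mu=factors.mu[:, ch:ch + 1],
                              sigma=factors.sigma[:, ch:ch + 1],
                              freqs=factors.freqs, floor=factors.floor)
        for cond in conds:
            z = normalize_psd(psd_c[cond], fac)
            ba = band_average(z, f, {b: BANDS[b] for b in group_bands})
            if cond not in out:
                out[cond] = np.empty((len(t_out), len(group_bands), n_ch,
                                      trials.n_trials(cond)))
            for bi, b in enumerate(group_bands):
                out[cond][:, bi, ch, :] = ba[b][:, 0, :]
    return t_out, out


def _select_groups(bands: tuple[str, ...] | None):
    """Window groups restricted to the requested analysis bands."""
    if bands is None:
        return WINDOW_GROUPS, BAND_NAMES
    groups = []
    for window_s, group_bands in WINDOW_GROUPS:
        kept = tuple(b for b in group_bands if b in bands)
        if kept:
            groups.append((window_s, kept))
    names = tuple(b for b in BAND_NAMES if b in bands)
    return tuple(groups), names


def _assemble_groups(
    trials: TrialTensor,
    group_factors: dict[float, NormFactors | None],
    t_range: tuple[float, float],
    step_s: float,
    bands: tuple[str, ...] | None = None,
) -> RbpResult:
    groups, names = _select_groups(bands)
    per_band: dict[str, dict[str, np.ndarray]] = {c: {} for c in trials.data}
    times_out = None
    for window_s, group_bands in groups:
        t, arrs = _trial_rbp_one_group(
            trials, window_s, group_bands, group_factors[window_s],
            t_range, step_s)
        if times_out is None:
            times_out = t
        elif len(t) != len(times_out) or not np.allclose(t, times_out):
            raise RuntimeError("band-group time grids failed to align")
        for cond, arr in arrs.items():
            for bi, b in enumerate(group_bands):
                per_band[cond][b] = arr[:, bi]
    data_out = {cond: np.stack([per_band[cond][b] for b in names], axis=1)
                for cond in trials.data}
    res = RbpResult(times=times_out, band_names=names, data=data_out)
    if trials.mask is not None:
        res.step_mask = _mask_to_steps(trials, times_out)
    return res


def rbp_from_recording(
    recording: Recording,
    trials: TrialTensor,
    t_range: tuple[float, float] = (-2.5, 2.5),
    step_s: float = STEP_S,
    bands: tuple[str, ...] | None = None,
) -> RbpResult:
    """Full RBP pipeline: session z-score factors, trial PSD, band averages.

    The normalization factors are computed over the entire continuous session
    (task periods included), separately per window-length group, then applied
    to the epoched trials.  ``bands`` optionally restricts the computation to
    a subset of the analysis bands.
    """
    groups, _ = _select_groups(bands)
    factors: dict[float, NormFactors | None] = {}
    for window_s, _gb in groups:
        factors[window_s] = session_norm_factors(
            recording.signal, recording.fs, window_s, step_s=step_s)
    return _assemble_groups(trials, factors, t_range, step_s, bands=bands)


def rbp_from_trials(
    trials: TrialTensor,
    t_range: tuple[float, float] = (-2.5, 2.5),
    step_s: float = STEP_S,
    bands: tuple[str, ...] | None = None,
) -> RbpResult:
    """RBP with z-score factors pooled over the trials themselves.

    Used when no continuous session is available (e.g. simulated trial sets).
    """
    groups, _ = _select_groups(bands)
    factors = {window_s: None for window_s, _gb in groups}
    return _assemble_groups(trials, factors, t_range, step_s, bands=bands)


def _mask_to_steps(trials: TrialTensor, step_times: np.ndarray,
                   window_s: float = 0.5) -> dict[str, np.ndarray]:
    """Map the sample-level rejection mask onto the RBP step grid.

    A step is flagged if any raw sample inside its (0.5 s) analysis window is
    masked; this single mapping is shared across band groups.
    """
    fs = trials.fs
    half = int(round(window_s * fs)) // 2
    out: dict[str, np.ndarray] = {}
    for cond, m in trials.mask.items():
        n = m.shape[0]
        centers = np.round((step_times - trials.times[0]) * fs).astype(int)
        step_m = np.zeros((len(centers),) + m.shape[1:], dtype=bool)
        cum = np.concatenate([np.zeros((1,) + m.shape[1:], dtype=int),
                              np.cumsum(m, axis=0)])
        for i, c in enumerate(centers):
            lo, hi = max(0, c - half), min(n, c + half)
            step_m[i] = (cum[hi] - cum[lo]) > 0
        out[cond] = step_m
    return out


def condition_means(rbp: RbpResult) -> dict[str, np.ndarray]:
    """Trial means per condition, honouring the rejection mask when present."""
    out = {}
    for cond, d in rbp.data.items():
        if rbp.step_mask is not None:
            m = rbp.step_mask[cond][:, None]  # broadcast over bands
            dm = np.where(m, np.nan, d)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                out[cond] = np.nanmean(dm, axis=-1)
        else:
            out[cond] = d.mean(axis=-1)
    return out


def wavelet_rbp(
    trials: TrialTensor,
    t_range: tuple[float, float] = (-2.5, 2.5),
    step_s: float = STEP_S,
    n_cycles_max: float = 6.0,
) -> RbpResult:
    """Morlet-wavelet alternative to the STFT band-power estimate.

    Constant-Q Morlet wavelets (6 cycles, tapering down to 3 cycles below 6 Hz
    so the wavelet support stays inside the epoch) are evaluated on the same
    31.25 ms step grid, dB-transformed, z-scored per frequency bin over all
    steps and trials, and band-averaged exactly like the STFT path.
    """
    from mne.time_frequency import tfr_array_morlet

    fs = trials.fs
    step = int(round(step_s * fs))
    # frequency grid mirroring the STFT bin grids of the three window groups
    freqs = np.concatenate([
        np.arange(1.0, 3.0 + 1e-9, 0.5),
        np.arange(4.0, 7.0 + 1e-9, 1.0),
        np.arange(8.0, 120.0 + 1e-9, 2.0),
    ])
    n_cycles = np.clip(freqs, 3.0, n_cycles_max)
    db_c: dict[str, np.ndarray] = {}
    times_out = None
    floor = None
    for cond, d in trials.data.items():
        epochs = np.ascontiguousarray(np.moveaxis(d, 2, 0).swapaxes(1, 2))
        power = tfr_array_morlet(
            epochs, sfreq=fs, freqs=freqs, n_cycles=n_cycles,
            output="power", decim=step, zero_mean=True)
        # (n_epochs, n_ch, n_f, n_steps) -> (n_steps, n_f, n_ch, n_tr)
        power = np.moveaxis(power, (0, 1, 2, 3), (3, 2, 1, 0))
        t = trials.times[::step][: power.shape[0]]
        keep = (t >= t_range[0] - 1e-9) & (t <= t_range[1] + 1e-9)
        t, power = t[keep], power[keep]
        if floor is None:
            floor = _auto_floor(power)
        db_c[cond] = 10.0 * np.log10(power + floor)
        times_out = t
    # z-score factors pooled over both conditions: one common map per bin
    pooled = np.concatenate(list(db_c.values()), axis=3)
    fac = NormFactors(mu=pooled.mean(axis=(0, 3)),
                      sigma=pooled.std(axis=(0, 3)), freqs=freqs, floor=floor)
    data_out: dict[str, np.ndarray] = {}
    for cond, db in db_c.items():
        z = normalize_psd(db, fac)
        ba = band_average(z, freqs, BANDS)
        data_out[cond] = np.stack([ba[b] for b in BAND_NAMES], axis=1)
    return RbpResult(times=times_out, band_names=BAND_NAMES, data=data_out)
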