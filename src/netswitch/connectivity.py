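"""Time-resolved directed connectivity (DTF/PDC/GGC) and phase locking (PLV).

Directed measures derive from a multivariate autoregressive (MVAR) model
``X(t) = sum_l A(l) X(t-l) + E(t)`` fitted by ordinary least squares over a
short sliding window, pooling all trials of a condition as independent
realizations (lagged predictors never cross trial boundaries).  To increase
frequency specificity the model is fitted separately in four bands (below
30 Hz, 31-48, 52-98, 102-120 Hz, leaving out 50 Hz line noise and its first
harmonic) with the model order fixed to the integer bandwidth.

From the transfer function ``H(f) = [I - sum_l A(l) e^(-i 2 pi f l / fs)]^-1``:

* DTF_mn(f) = |H_mn| / sqrt(sum_j |H_mj|^2)  -- inflow into m from n,
  normalized by the total inflow to m (rows of DTF^2 sum to 1);
* PDC_mn(f) = |Abar_mn| / sqrt(sum_j |Abar_jn|^2) -- outflow from n to m,
  normalized by the total outflow of n (columns of PDC^2 sum to 1);
* GGC_mn(f) = (Z_nn - Z_mn^2 / Z_mm) |H_mn|^2 / |S_mm|, the spectral
  Granger-Geweke causality with S = H Z H* the model spectrum.

Connectivity is z-scored along the window axis, averaged over frequencies into
the six analysis bands, and over all channel pairs spanning two networks,
yielding one directional time series per (source network -> target network).

The phase-locking value is computed from Hilbert phases of 2 Hz-wide
zero-phase band-passed signals: across-trial consistency of the phase
difference of a channel pair at each time point, then averaged into the six
analysis bands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .bands import BANDS, BAND_NAMES, CROP, FIT_BANDS, STEP_S, band_bins
from .preprocess import TrialTensor

__all__ = [
    "MvarModel",
    "ConnectivityResult",
    "PlvResult",
    "band_split",
    "fit_mvar",
    "transfer_function",
    "dtf",
    "pdc",
    "ggc",
    "sliding_connectivity",
    "mvar_band_power",
    "plv",
    "connectivity_group_stats",
]


@dataclass
class MvarModel:
    """Fitted MVAR model: lag coefficients, residual covariance, order."""

    A: np.ndarray        # (p, k, k)
    Z: np.ndarray        # (k, k) residual noise covariance
    p: int
    fs: float
    band: tuple[float, float] | None = None

    @property
    def k(self) -> int:
        return self.A.shape[1]

    def is_stable(self) -> bool:
        """Spectral radius of the companion matrix < 1."""
        p, k = self.p, self.k
        comp = np.zeros((k * p, k * p))
        comp[:k] = np.concatenate(list(self.A), axis=1)
        comp[k:, :-k] = np.eye(k * (p - 1))
        return bool(np.max(np.abs(np.linalg.eigvals(comp))) < 1.0)


@dataclass
class ConnectivityResult:
    """Network-averaged directional series per measure/condition/direction."""

    times: np.ndarray
    band_names: tuple[str, ...]
    series: dict[str, dict[str, dict[tuple[str, str], np.ndarray]]]
    pair_band: dict[str, dict[str, np.ndarray]] | None = None


@dataclass
class PlvResult:
    """Phase-locking value ``PLV(t, fb, m, n)`` per condition."""

    times: np.ndarray
    band_names: tuple[str, ...]
    plv: dict[str, np.ndarray]


def band_split(
    data: np.ndarray,
    fs: float,
    fit_bands=FIT_BANDS,
    order: int = 6,
    zscore: bool = True,
) -> dict[tuple[float, float], np.ndarray]:
    """z-score each trial in time, then band-filter into the MVAR fitting bands.

    The first band is realized as a low-pass at its upper edge; the others as
    band-passes.  All filters are zero-phase 6th-order Butterworth.
    """
    x = np.asarray(data, dtype=float)
    if zscore:
        mu = x.mean(axis=0, keepdims=True)
        sd = x.std(axis=0, keepdims=True)
        x = (x - mu) / np.where(sd > 0, sd, 1.0)
    out = {}
    for (lo, hi), _p in fit_bands:
        if hi >= fs / 2:
            raise ValueError(f"band {lo}-{hi} Hz exceeds Nyquist at fs={fs}")
        if lo <= 0.5:
            sos = sps.butter(order, hi, btype="lowpass", fs=fs, output="sos")
        else:
            sos = sps.butter(order, [lo, hi], btype="bandpass", fs=fs,
                             output="sos")
        out[(lo, hi)] = sps.sosfiltfilt(sos, x, axis=0)
    return out


def _lag_matrix(data: np.ndarray, start: int, stop: int, p: int):
    """Design matrices pooling trials: Y (N, k), X (N, k*p).

    Targets are samples ``start..stop-1`` of every trial; lagged predictors
    reach back before ``start`` but stay inside the trial array.
    """
    if start < p:
        raise ValueError("window start leaves no room for the model lags")
    L = stop - start
    k = data.shape[1]
    n_tr = data.shape[2]
    Y = np.moveaxis(data[start:stop], 2, 1).reshape(L * n_tr, k)
    X = np.empty((L * n_tr, k * p))
    for l in range(1, p + 1):
        X[:, (l - 1) * k:l * k] = np.moveaxis(
            data[start - l:stop - l], 2, 1).reshape(L * n_tr, k)
    return Y, X


def fit_mvar(
    data: np.ndarray,
    p: int,
    window: tuple[int, int] | None = None,
    fs: float = 512.0,
    band: tuple[float, float] | None = None,
) -> MvarModel:
    """Least-squares MVAR fit on ``(time, channels, trials)`` data.

    All trials of a condition are pooled as independent realizations; the
    residual covariance is estimated from the pooled residuals with a
    degrees-of-freedom correction.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        data = data[:, :, None]
    if p < 1:
        raise ValueError("model order p must be >= 1")
    k = data.shape[1]
    if window is None:
        window = (p, data.shape[0])
    Y, X = _lag_matrix(data, window[0], window[1], p)
    n_obs = Y.shape[0]
    if n_obs < k * p:
        raise np.linalg.LinAlgError(
            f"under-determined MVAR design ({n_obs} observations for "
            f"{k * p} parameters per equation); use a lower order p or "
            "fewer channels")
    if n_obs < 10 * k * p:
        warnings.warn(f"only {n_obs} observations for {k * p} parameters "
                      "per equation; MVAR fit may be poorly conditioned")
    # SVD-based least squares with a relative singular-value cutoff: heavily
    # band-limited (oversampled) signals make the lag design numerically
    # rank-deficient, and the minimum-norm solution is the stable estimator.
    B, _, _, _ = np.linalg.lstsq(X, Y, rcond=1e-10)
    resid = Y - X @ B
    dof = max(n_obs - k * p, 1)
    Z = resid.T @ resid / dof
    A = np.stack([B[(l - 1) * k:l * k].T for l in range(1, p + 1)])
    return MvarModel(A=A, Z=Z, p=p, fs=fs, band=band)


def _abar(model: MvarModel, freqs: np.ndarray) -> np.ndarray:
    """Abar(f) = I - sum_l A(l) exp(-i 2 pi f l / fs), shape (n_f, k, k)."""
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    lags = np.arange(1, model.p + 1)
    phase = np.exp(-2j * np.pi * freqs[:, None] * lags[None, :] / model.fs)
    acc = np.einsum("fl,lmn->fmn", phase, model.A.astype(complex))
    return np.eye(model.k)[None] - acc


def transfer_function(model: MvarModel, freqs: np.ndarray) -> np.ndarray:
    """H(f) = Abar(f)^-1 for each requested frequency; (n_f, k, k) complex."""
    ab = _abar(model, freqs)
    try:
        return np.linalg.inv(ab)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular Abar(f); the MVAR model has a root on the unit circle "
            "at a requested frequency") from err


def dtf(H: np.ndarray) -> np.ndarray:
    """Directed transfer function: inflow-normalized |H| (rows of DTF^2 sum to 1)."""
    mag2 = np.abs(H) ** 2
    denom = mag2.sum(axis=-1, keepdims=True)
    if np.any(denom == 0):
        warnings.warn("zero row in H; DTF undefined there (NaN)")
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.sqrt(mag2 / denom)


def pdc(model: MvarModel, freqs: np.ndarray) -> np.ndarray:
    """Partial directed coherence: outflow-normalized |Abar| (columns of PDC^2 sum to 1)."""
    ab = _abar(model, freqs)
    mag2 = np.abs(ab) ** 2
    denom = mag2.sum(axis=-2, keepdims=True)
    if np.any(denom == 0):
        warnings.warn("zero column in Abar; PDC undefined there (NaN)")
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.sqrt(mag2 / denom)


def ggc(model: MvarModel, H: np.ndarray) -> np.ndarray:
    """Granger-Geweke causality from the full multivariate model.

    GGC_mn(f) = (Z_nn - Z_mn^2/Z_mm) |H_mn(f)|^2 / |S_mm(f)|.
    """
    Z = model.Z
    try:
        np.linalg.cholesky(Z)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "residual covariance Z is not positive definite") from err
    S = H @ Z @ np.conj(np.swapaxes(H, -1, -2))
    s_diag = np.abs(np.einsum("fmm->fm", S))
    zd = np.diag(Z)
    num_z = zd[None, :] - (Z ** 2) / zd[:, None]   # (m, n): Z_nn - Z_mn^2/Z_mm
    out = num_z[None] * np.abs(H) ** 2 / s_diag[:, :, None]
    return np.maximum(out, 0.0)


_MEASURES = ("dtf", "pdc", "ggc")


def _band_freqs(lo: float, hi: float, step: float = 1.0) -> np.ndarray:
    return np.arange(np.ceil(max(lo, step)), np.floor(hi) + 1e-9, step)


def _window_starts(times: np.ndarray, fs: float, window_s: float,
                   step_s: float, crop: tuple[float, float]):
    """Start indices (samples) tiling the crop with the sliding window."""
    n_win = int(round(window_s * fs))
    starts_t = np.arange(crop[0], crop[1] - window_s + 1e-9, step_s)
    starts = np.round((starts_t - times[0]) * fs).astype(int)
    centers = starts_t + window_s / 2.0
    ok = starts >= 0
    return starts[ok], centers[ok], n_win


def _zscore_axis0(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0, keepdims=True)
    sd = x.std(axis=0, keepdims=True)
    return (x - mu) / np.where(sd > 0, sd, 1.0)


def sliding_connectivity(
    trials: TrialTensor,
    labels: np.ndarray,
    measures: tuple[str, ...] = ("dtf",),
    window_s: float = 0.5,
    step_s: float = 0.125,
    crop: tuple[float, float] = CROP,
    fit_bands=FIT_BANDS,
    freq_step: float = 1.0,
    keep_pairs: bool = False,
) -> ConnectivityResult:
    """Sliding-window directed connectivity, network-averaged.

    For each condition and fitting band an MVAR model is estimated in every
    window, the requested measures are evaluated on a 1 Hz grid, z-scored
    along the window axis per (pair, frequency), averaged into the six
    analysis bands and finally over all (target in A, source in B) channel
    pairs, giving ``measure_{B->A}(t, fb)`` for each ordered network pair.
    """
    for m in measures:
        if m not in _MEASURES:
            raise ValueError(f"unknown measure {m!r}")
    labels = np.asarray(labels)
    networks = [n for n in pd_unique(labels) if n is not None and n == n]
    if len(networks) < 2:
        raise ValueError("need channels from at least two labeled networks")
    fs = trials.fs
    starts, centers, n_win = _window_starts(trials.times, fs, window_s,
                                            step_s, crop)
    all_freqs = np.concatenate([_band_freqs(lo, hi, freq_step)
                                for (lo, hi), _ in fit_bands])
    band_masks = {b: band_bins(all_freqs, b) for b in BAND_NAMES}
    series: dict[str, dict[str, dict[tuple[str, str], np.ndarray]]] = {
        m: {} for m in measures}
    pair_band: dict[str, dict[str, np.ndarray]] = {m: {} for m in measures}
    k = trials.n_channels
    for cond, data in trials.data.items():
        split = band_split(data, fs, fit_bands=fit_bands)
        raw = {m: np.empty((len(starts), len(all_freqs), k, k))
               for m in measures}
        col = 0
        for (lo, hi), p in fit_bands:
            freqs = _band_freqs(lo, hi, freq_step)
            x = split[(lo, hi)]
            for wi, s0 in enumerate(starts):
                model = fit_mvar(x, p, window=(s0, s0 + n_win), fs=fs,
                                 band=(lo, hi))
                H = transfer_function(model, freqs) if (
                    "dtf" in measures or "ggc" in measures) else None
                if "dtf" in measures:
                    raw["dtf"][wi, col:col + len(freqs)] = dtf(H)
                if "pdc" in measures:
                    raw["pdc"][wi, col:col + len(freqs)] = pdc(model, freqs)
                if "ggc" in measures:
                    raw["ggc"][wi, col:col + len(freqs)] = ggc(model, H)
            col += len(freqs)
        for m in measures:
            z = _zscore_axis0(raw[m])
            pb = np.stack([z[:, band_masks[b]].mean(axis=1)
                           for b in BAND_NAMES], axis=1)  # (n_w, n_fb, k, k)
            if keep_pairs:
                pair_band[m][cond] = pb
            for dst in networks:
                for src in networks:
                    if src == dst:
                        continue
                    mi = np.flatnonzero(labels == dst)
                    ni = np.flatnonzero(labels == src)
                    sl = pb[:, :, mi][:, :, :, ni].mean(axis=(2, 3))
                    series[m].setdefault(cond, {})[(src, dst)] = sl
    return ConnectivityResult(times=centers, band_names=BAND_NAMES,
                              series=series,
                              pair_band=pair_band if keep_pairs else None)


def mvar_band_power(
    data: np.ndarray,
    times: np.ndarray,
    fs: float,
    window_s: float = 0.5,
    step_s: float = 0.125,
    crop: tuple[float, float] = CROP,
    fit_bands=FIT_BANDS,
    freq_step: float = 1.0,
):
    """Band power implied by the sliding MVAR model spectrum.

    The diagonal of ``S(f) = H Z H*`` gives each channel's model spectrum per
    window; it is dB-transformed, z-scored along the window axis per
    (frequency, channel), and averaged into the six analysis bands.

    Returns ``(window_centers, band_power)`` with band power shaped
    ``(n_windows, n_bands, n_channels)``.
    """
    data = np.asarray(data, dtype=float)
    starts, centers, n_win = _window_starts(times, fs, window_s, step_s, crop)
    split = band_split(data, fs, fit_bands=fit_bands)
    all_freqs = np.concatenate([_band_freqs(lo, hi, freq_step)
                                for (lo, hi), _ in fit_bands])
    k = data.shape[1]
    P = np.empty((len(starts), len(all_freqs), k))
    col = 0
    for (lo, hi), p in fit_bands:
        freqs = _band_freqs(lo, hi, freq_step)
        x = split[(lo, hi)]
        for wi, s0 in enumerate(starts):
            model = fit_mvar(x, p, window=(s0, s0 + n_win), fs=fs)
            H = transfer_function(model, freqs)
            S = H @ model.Z @ np.conj(np.swapaxes(H, -1, -2))
            P[wi, col:col + len(freqs)] = np.abs(np.einsum("fmm->fm", S))
        col += len(freqs)
    db = 10.0 * np.log10(P + 1e-30)
    z = _zscore_axis0(db)
    bp = np.stack([z[:, band_bins(all_freqs, b)].mean(axis=1)
                   for b in BAND_NAMES], axis=1)
    return centers, bp


def plv(
    trials: TrialTensor,
    bin_hz: float = 2.0,
    fmax: float = 120.0,
    crop: tuple[float, float] = CROP,
    step_s: float = STEP_S,
    order: int = 6,
) -> PlvResult:
    """Across-trial phase locking from narrow-band Hilbert phases.

    The signal is decomposed into non-overlapping 2 Hz bands (zero-phase
    Butterworth), the instantaneous phase extracted on the full epoch (edges
    discarded by the crop), and the PLV computed across trials for every
    channel pair and time step (decimated to the common 31.25 ms grid); bins
    are averaged into the six analysis bands by their center frequency.
    """
    fs = trials.fs
    if fmax >= fs / 2:
        raise ValueError(f"fmax {fmax} Hz is at/above Nyquist ({fs / 2} Hz)")
    step = int(round(step_s * fs))
    edges = np.arange(0.0, fmax + 1e-9, bin_hz)
    bins = list(zip(edges[:-1], edges[1:]))
    mids = np.array([(lo + hi) / 2.0 for lo, hi in bins])
    t_dec = trials.times[::step]
    keep = (t_dec >= crop[0] - 1e-9) & (t_dec <= crop[1] + 1e-9)
    t_out = t_dec[keep]
    band_of = {}
    for b in BAND_NAMES:
        for i in np.flatnonzero(band_bins(mids, b)):
            band_of[i] = b
    k = trials.n_channels
    out: dict[str, np.ndarray] = {}
    for cond, data in trials.data.items():
        n_tr = data.shape[2]
        if n_tr < 2:
            raise ValueError("need >=2 trials per condition for PLV")
        acc = np.zeros((len(t_out), len(BAND_NAMES), k, k))
        cnt = np.zeros(len(BAND_NAMES))
        for bi, (lo, hi) in enumerate(bins):
            if bi not in band_of:
                continue
            lo_eff = max(lo, 0.1)
            sos = sps.butter(order, [lo_eff, hi], btype="bandpass", fs=fs,
                             output="sos")
            xf = sps.sosfiltfilt(sos, data, axis=0)
            analytic = sps.hilbert(xf, axis=0)
            ph = analytic[::step][keep]
            u = ph / np.maximum(np.abs(ph), 1e-300)
            pl = np.abs(np.einsum("tmr,tnr->tmn", u, np.conj(u))) / n_tr
            fb = BAND_NAMES.index(band_of[bi])
            acc[:, fb] += pl
            cnt[fb] += 1
        out[cond] = acc / np.maximum(cnt[None, :, None, None], 1)
    return PlvResult(times=t_out, band_names=BAND_NAMES, plv=out)


def connectivity_group_stats(
    subject_series: list[dict[str, np.ndarray]],
    alpha: float = 0.001,
) -> np.ndarray:
    """Across-subject condition test on network-averaged connectivity series.

    Each subject contributes ``{condition: (n_t, n_fb)}``.  Per time step and
    band a two-sided rank-sum test compares the two conditions across
    subjects; FDR at ``alpha`` runs across time steps and bands.  Returns a
    boolean ``(n_t, n_fb)`` mask.
    """
    from .stats import fdr_adjust, wilcoxon_ranksum

    n_s = len(subject_series)
    if n_s < 2:
        raise ValueError("need at least 2 subjects per condition")
    if n_s < 5:
        warnings.warn(f"only {n_s} subjects; across-subject test is weak")
    conds = list(subject_series[0])
    a = np.stack([s[conds[0]] for s in subject_series])
    b = np.stack([s[conds[1]] for s in subject_series])
    pv = wilcoxon_ranksum(a, b, axis=0)
    reject, _ = fdr_adjust(pv.ravel(), q=alpha)
    return reject.reshape(pv.shape)


def pd_unique(values) -> list:
    """Order-preserving unique."""
    seen: list = []
    for v in values:
        if v not in seen:
            seen.append(v)
    return seen
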