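"""Condition-difference statistics, significance screening and crossover timing.

The strength of the band-power difference between the two switching conditions
is summarized per channel and band as a signal-to-noise ratio: the variance of
the two condition means divided by the mean trial-by-trial variance, averaged
over the analysis window and expressed in dB.

Significance screening is two-level.  At the channel level a two-sided
Wilcoxon rank-sum test compares the two trial distributions at every time
step; p-values are Benjamini-Hochberg corrected jointly across subjects, time
steps, bands and channels, and only runs of consecutive significant steps
longer than 100 ms survive (a temporal-continuity screen against isolated
false positives).  At the network level the trial-averaged values of the
significant channels are compared between conditions per time step with a
stricter FDR level.

Crossover timing removes the condition-common response, low-pass filters both
residuals at 1 Hz (zero phase) and reports the first sign change of their
difference inside the allowed window, linearly interpolated between steps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

from .bands import BAND_NAMES, CROP, CROSSOVER_WINDOW, STEP_S

__all__ = [
    "SnrTable",
    "SignificanceResult",
    "rbp_snr",
    "fdr_adjust",
    "wilcoxon_ranksum",
    "channel_significance",
    "network_significance",
    "subtract_common",
    "crossover_time",
    "compare_crossovers",
]

SNR_FLOOR_DB = -120.0


@dataclass
class SnrTable:
    """Strength of the condition difference, per channel and band."""

    snr_t: np.ndarray      # (n_steps, n_bands, n_channels), power ratio
    snr_db: np.ndarray     # (n_bands, n_channels), 10*log10 of time-mean ratio
    times: np.ndarray
    band_names: tuple[str, ...]


@dataclass
class SignificanceResult:
    """Channel- or network-level significance masks and summary ratios."""

    channel_sig: list[np.ndarray]          # per subject: (n_bands, n_ch) bool
    sig_mask: list[np.ndarray]             # per subject: (n_steps, n_bands, n_ch)
    pvals: list[np.ndarray] = field(default_factory=list)
    times: np.ndarray | None = None
    band_names: tuple[str, ...] = BAND_NAMES

    def r_c(self) -> np.ndarray:
        """Ratio of significant channels per band, pooled over subjects."""
        sig = np.concatenate(self.channel_sig, axis=1)
        return sig.mean(axis=1)

    def r_s(self) -> np.ndarray:
        """Ratio of subjects with at least one significant channel, per band."""
        per = np.stack([s.any(axis=1) for s in self.channel_sig])
        return per.mean(axis=0)

    def any_band(self, subject: int) -> np.ndarray:
        """Channels significant in any band for one subject."""
        return self.channel_sig[subject].any(axis=0)


def rbp_snr(
    rbp_a: np.ndarray,
    rbp_b: np.ndarray,
    times: np.ndarray,
    crop: tuple[float, float] = CROP,
    band_names: tuple[str, ...] = BAND_NAMES,
    floor_db: float = SNR_FLOOR_DB,
) -> SnrTable:
    """SNR of the condition difference from two ``(t, fb, ch, tr)`` tensors.

    Sample-variance convention (denominator n-1) is used both for the
    numerator over the two condition means and for the trial variances.  Time
    steps where both conditions have zero trial variance are undefined (NaN);
    the dB summary floors zero numerators at ``floor_db``.
    """
    means = np.stack([rbp_a.mean(axis=-1), rbp_b.mean(axis=-1)], axis=-1)
    num = means.var(axis=-1, ddof=1)  # sample variance of the 2 condition means
    den = 0.5 * (rbp_a.var(axis=-1, ddof=1) + rbp_b.var(axis=-1, ddof=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        snr_t = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    sel = (times >= crop[0] - 1e-9) & (times <= crop[1] + 1e-9)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_ratio = np.nanmean(snr_t[sel], axis=0)
    with np.errstate(divide="ignore"):
        snr_db = 10.0 * np.log10(mean_ratio)
    snr_db = np.where(np.isfinite(snr_db), snr_db, floor_db)
    snr_db = np.where(np.isnan(mean_ratio), np.nan, snr_db)
    return SnrTable(snr_t=snr_t, snr_db=snr_db, times=times,
                    band_names=band_names)


def fdr_adjust(pvals, q: float = 0.05):
    """Benjamini-Hochberg step-up: (reject mask, adjusted p-values)."""
    p = np.asarray(pvals, dtype=float).ravel()
    if p.size == 0:
        return np.zeros(0, dtype=bool), p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def wilcoxon_ranksum(x: np.ndarray, y: np.ndarray, axis: int = 0) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p-value (Mann-Whitney form).

    Exact enumeration for small tie-free samples (< 10 per group), otherwise
    the normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    small = x.shape[axis] < 10 and y.shape[axis] < 10
    method = "exact" if small else "asymptotic"
    try:
        res = sstats.mannwhitneyu(x, y, axis=axis, alternative="two-sided",
                                  method=method)
    except ValueError:
        res = sstats.mannwhitneyu(x, y, axis=axis, alternative="two-sided",
                                  method="asymptotic")
    return np.asarray(res.pvalue)


def _runs_longer_than(mask_1d: np.ndarray, min_steps: int) -> np.ndarray:
    """Keep only True-runs of at least ``min_steps`` consecutive steps."""
    out = np.zeros_like(mask_1d)
    edges = np.flatnonzero(np.diff(np.r_[0, mask_1d.view(np.int8), 0]))
    for start, stop in zip(edges[::2], edges[1::2]):
        if stop - start >= min_steps:
            out[start:stop] = True
    return out


def min_run_steps(min_run_ms: float, step_s: float = STEP_S) -> int:
    """Smallest number of consecutive steps spanning strictly more than
    ``min_run_ms`` (e.g. 100 ms at 31.25 ms steps -> 4)."""
    return int(np.floor(min_run_ms / 1000.0 / step_s)) + 1


def channel_significance(
    rbp_by_subject: list[dict[str, np.ndarray]],
    times: np.ndarray,
    alpha: float = 0.05,
    min_run_ms: float = 100.0,
    step_s: float = STEP_S,
    crop: tuple[float, float] = CROP,
    band_names: tuple[str, ...] = BAND_NAMES,
) -> SignificanceResult:
    """Channel-level condition-difference screening for a whole cohort.

    Each subject contributes tensors ``{condition: RBP(t, fb, ch, tr)}``.
    Rank-sum p-values at every (t, fb, ch) are FDR-corrected *jointly* across
    subjects, time steps, bands and channels; surviving steps are then pruned
    by the >``min_run_ms`` continuity rule.  A channel is significant in a
    band iff at least one run survives.
    """
    sel = (times >= crop[0] - 1e-9) & (times <= crop[1] + 1e-9)
    t_sel = times[sel]
    pv_list = []
    for rbp in rbp_by_subject:
        conds = list(rbp)
        if len(conds) != 2:
            raise ValueError("exactly two conditions required")
        a, b = rbp[conds[0]][sel], rbp[conds[1]][sel]
        if a.shape[-1] < 2 or b.shape[-1] < 2:
            raise ValueError("need >=2 trials per condition")
        pv = wilcoxon_ranksum(np.moveaxis(a, -1, 0), np.moveaxis(b, -1, 0),
                              axis=0)
        pv_list.append(pv)
    flat = np.concatenate([p.ravel() for p in pv_list])
    reject, _ = fdr_adjust(flat, q=alpha)
    need = min_run_steps(min_run_ms, step_s)
    res = SignificanceResult(channel_sig=[], sig_mask=[], pvals=pv_list,
                             times=t_sel, band_names=band_names)
    pos = 0
    for pv in pv_list:
        rej = reject[pos:pos + pv.size].reshape(pv.shape)
        pos += pv.size
        mask = np.zeros_like(rej)
        for fb in range(rej.shape[1]):
            for ch in range(rej.shape[2]):
                mask[:, fb, ch] = _runs_longer_than(rej[:, fb, ch], need)
        res.sig_mask.append(mask)
        res.channel_sig.append(mask.any(axis=0))
    return res


def network_significance(
    network_values: dict[str, dict[str, np.ndarray]],
    alpha: float = 0.001,
) -> dict[str, np.ndarray]:
    """Network-level condition difference over significant channels.

    ``network_values[network][condition]`` is a ``(t, fb, n_chan)`` array of
    trial-averaged RBP for the channels comprising the network (pooled over
    subjects).  Per time step and band a rank-sum test across channels
    compares the conditions; FDR at ``alpha`` runs jointly across networks,
    bands and time steps.  Networks/bands with fewer than two channels are
    undefined (all-False mask, warning).
    """
    pv = {}
    for net, vals in network_values.items():
        conds = list(vals)
        a, b = vals[conds[0]], vals[conds[1]]
        if a.shape[-1] < 2:
            warnings.warn(f"network {net!r}: <2 significant channels; skipped")
            pv[net] = np.full(a.shape[:2], np.nan)
            continue
        pv[net] = wilcoxon_ranksum(np.moveaxis(a, -1, 0),
                                   np.moveaxis(b, -1, 0), axis=0)
    flat = np.concatenate([p.ravel() for p in pv.values()])
    ok = np.isfinite(flat)
    reject_ok, _ = fdr_adjust(flat[ok], q=alpha) if ok.any() else (flat[ok] > 1, None)
    reject = np.zeros(flat.size, dtype=bool)
    reject[ok] = reject_ok
    out = {}
    pos = 0
    for net, p in pv.items():
        out[net] = reject[pos:pos + p.size].reshape(p.shape)
        pos += p.size
    return out


def subtract_common(mean_a: np.ndarray, mean_b: np.ndarray):
    """Remove the condition-common response: residuals are exact mirror images."""
    common = 0.5 * (mean_a + mean_b)
    return mean_a - common, mean_b - common


def crossover_time(
    mean_a: np.ndarray,
    mean_b: np.ndarray,
    times: np.ndarray,
    window: tuple[float, float] = CROSSOVER_WINDOW,
    lowpass_hz: float = 1.0,
    order: int = 6,
) -> float | None:
    """First crossing time of the two condition curves, or None.

    The condition-common mean is removed, both residuals are low-pass filtered
    (zero phase) and the first sign change of their difference whose
    interpolated crossing lies inside ``window`` is returned.
    """
    res_a, _ = subtract_common(np.asarray(mean_a, float), np.asarray(mean_b, float))
    d = 2.0 * res_a  # res_a - res_b with res_b = -res_a
    fs_steps = 1.0 / float(np.mean(np.diff(times)))
    sos = sps.butter(order, lowpass_hz, btype="lowpass", fs=fs_steps,
                     output="sos")
    d = sps.sosfiltfilt(sos, d)
    for i in range(len(times) - 1):
        if times[i + 1] < window[0] or times[i] > window[1]:
            continue
        if d[i] == 0.0:
            tc = float(times[i])
        elif d[i] * d[i + 1] < 0:
            tc = float(times[i] - d[i] * (times[i + 1] - times[i])
                       / (d[i + 1] - d[i]))
        else:
            continue
        if window[0] - 1e-12 <= tc <= window[1] + 1e-12:
            return tc
    return None


def compare_crossovers(
    times_net_a: dict[str, np.ndarray],
    times_net_b: dict[str, np.ndarray],
    q: float = 0.05,
) -> pd.DataFrame:
    """Compare per-channel crossover-time distributions of two networks.

    Two-sided rank-sum per band, FDR across bands; the mean difference
    (network A minus network B) is reported in milliseconds.
    """
    rows = []
    for band in times_net_a:
        a = np.asarray(times_net_a[band], dtype=float)
        b = np.asarray(times_net_b.get(band, []), dtype=float)
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        if len(a) < 2 or len(b) < 2:
            continue
        p = float(wilcoxon_ranksum(a, b))
        rows.append({"band": band, "p": p,
                     "mean_diff_ms": float((a.mean() - b.mean()) * 1000.0),
                     "n_a": len(a), "n_b": len(b)})
    df = pd.DataFrame(rows)
    if len(df):
        reject, p_adj = fdr_adjust(df["p"].to_numpy(), q=q)
        df["p_fdr"] = p_adj
        df["significant"] = reject
    return df
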