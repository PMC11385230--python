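"""Frequency-band definitions and grid conventions shared across the pipeline.

The analysis divides the iEEG spectrum into six non-overlapping bands.  Power
in the two line-noise notch ranges (around 50 Hz and its first harmonic) is
never counted towards the high-gamma band (HGB).  All time-resolved power
estimates share a common 31.25 ms step so that tensors from different window
lengths concatenate on one time axis.
"""

from __future__ import annotations

#: Six analysis bands, low edge / high edge in Hz.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.1, 3.0),
    "theta": (4.0, 7.0),
    "alpha": (8.0, 12.0),
    "beta": (13.0, 30.0),
    "lowgamma": (31.0, 48.0),
    "hgb": (52.0, 120.0),
}

BAND_NAMES: tuple[str, ...] = tuple(BANDS)

#: Line-noise stop bands; bins inside these are excluded from the HGB average.
NOTCHES: tuple[tuple[float, float], ...] = ((48.0, 52.0), (98.0, 102.0))

#: Sliding-step of all time-resolved power estimates, seconds (16 samples at 512 Hz).
STEP_S: float = 0.03125

#: STFT window length (s) per group of bands: slow oscillations need longer windows.
WINDOW_GROUPS: tuple[tuple[float, tuple[str, ...]], ...] = (
    (2.0, ("delta",)),
    (1.0, ("theta",)),
    (0.5, ("alpha", "beta", "lowgamma", "hgb")),
)

#: MVAR fitting bands (Hz) with their fixed model orders (integer bandwidth).
FIT_BANDS: tuple[tuple[tuple[float, float], int], ...] = (
    ((0.1, 30.0), 29),
    ((31.0, 48.0), 17),
    ((52.0, 98.0), 46),
    ((102.0, 120.0), 18),
)

#: Analysis crop around the attention switch, seconds.
CROP: tuple[float, float] = (-2.3, 2.3)

#: Search window for band-power crossover times, seconds.
CROSSOVER_WINDOW: tuple[float, float] = (-0.5, 2.0)

#: The two attention-switching conditions.
CONDITIONS: tuple[str, str] = ("ext2int", "int2ext")


def in_notch(f: float) -> bool:
    """True if frequency ``f`` falls inside a line-noise notch range (inclusive)."""
    return any(lo <= f <= hi for lo, hi in NOTCHES)


def band_bins(freqs, band: str, bands: dict[str, tuple[float, float]] | None = None):
    """Boolean mask of frequency bins belonging to an analysis band.

    For the HGB the notched-out ranges are excluded from the average.
    """
    import numpy as np

    bands = BANDS if bands is None else bands
    lo, hi = bands[band]
    freqs = np.asarray(freqs, dtype=float)
    mask = (freqs >= lo) & (freqs <= hi)
    if band == "hgb":
        for nlo, nhi in NOTCHES:
            mask &= ~((freqs >= nlo) & (freqs <= nhi))
    return mask
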