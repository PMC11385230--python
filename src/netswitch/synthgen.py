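"""Synthetic iEEG cohort generator with planted, recoverable structure.

The generator emulates the statistical features the analysis pipeline assumes:
512 Hz sampling, 60 switch trials per condition, a 1/f-decaying background
spectrum, band-limited oscillatory power whose envelope crosses over between
the two switching conditions near t = 0 s (with a configurable per-group lag),
directional lagged coupling between two channel groups that reverses at the
switch, and rare high-amplitude artifact events.  Oscillations are realized as
narrow-band-filtered Gaussian noise rather than sinusoids so autoregressive
model fitting downstream stays well-posed.

Contacts come in pairs on two-contact shanks: the deep contact carries the
planted channel signal plus a per-shank common-mode trace, the shallow contact
the common mode alone, so nearest-neighbour bipolar referencing recovers the
planted channel exactly.  Every planted quantity is reproducible from
(config, seed) and returned as ground truth for recovery scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.special import expit

from .bands import CONDITIONS
from .preprocess import Recording, TrialTensor

__all__ = [
    "BandModulation",
    "CouplingConfig",
    "GenConfig",
    "GroundTruth",
    "generate_cohort",
    "inject_artifacts",
    "make_atlas",
    "generate_ar_trials",
]

NETWORKS = ("NetA", "NetB")


@dataclass
class BandModulation:
    """One planted band-limited power modulation.

    ``condition_contrast`` is the peak-to-peak fractional amplitude difference
    between the two conditions far from the crossover; its sign flips between
    the two channel groups when ``antagonistic`` (the hallmark of the
    phenomenon being emulated).  The envelope follows a logistic transition of
    width ``transition_width`` centered on ``crossover_time`` (group B lags by
    ``crossover_lag_per_group``).
    """

    band: tuple[float, float] = (8.0, 12.0)
    base_amplitude: float = 1.0
    condition_contrast: float = 1.0
    crossover_time: float = 0.5
    crossover_lag_per_group: float = 0.0
    transition_width: float = 0.3
    antagonistic: bool = True


@dataclass
class CouplingConfig:
    """Lagged linear mixing between the two channel groups.

    ``direction_by_condition[c]`` names (driver, driven) *after* the switch in
    condition ``c``; the direction is reversed before the switch, emulating
    the activated network driving the deactivated one.
    """

    direction_by_condition: dict[str, tuple[str, str]] = field(
        default_factory=lambda: {"ext2int": ("NetA", "NetB"),
                                 "int2ext": ("NetB", "NetA")})
    lag: int = 8
    strength: float = 0.8
    band: tuple[float, float] = (4.0, 12.0)
    switch_width_s: float = 0.2


@dataclass
class GenConfig:
    """Cohort-level generator configuration (defaults = study conditions)."""

    n_subjects: int = 6
    n_channels_per_network: int = 10
    n_trials_per_condition: int = 60
    fs: float = 512.0
    trial_span: tuple[float, float] = (-4.0, 4.0)
    background_exponent: float = 1.0
    band_modulations: list[BandModulation] = field(default_factory=lambda: [
        BandModulation(band=(8.0, 12.0), base_amplitude=1.0,
                       condition_contrast=1.0, crossover_time=0.5),
        BandModulation(band=(52.0, 120.0), base_amplitude=0.5,
                       condition_contrast=-1.0, crossover_time=0.5),
    ])
    coupling: CouplingConfig = field(default_factory=CouplingConfig)
    artifact_rate: float = 0.5          # events per minute
    artifact_amplitude: float = 8.0     # in SD multiples
    artifact_duration_s: float = 0.05
    n_sessions: int = 1
    pad_s: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        top = max((m.band[1] for m in self.band_modulations), default=0.0)
        if self.fs <= 2 * top:
            raise ValueError(
                f"fs={self.fs} must exceed twice the highest band edge ({top})")
        if not (self.trial_span[0] <= -2.3 and self.trial_span[1] >= 2.3):
            raise ValueError("trial_span must contain the analysis window "
                             "[-2.3, 2.3] s")


@dataclass
class GroundTruth:
    """Everything planted, for parameter-recovery scoring."""

    crossovers: pd.DataFrame      # subject, channel, name, network, band, time
    coupling: dict
    artifacts: pd.DataFrame       # subject, session, onset_s, duration_s, channel
    seed: int


def make_atlas(shape=(40, 40, 40), voxel_mm: float = 2.0):
    """Small two-region labeled volume for localization at test scale.

    Returns ``(data, affine), labels`` with two cubic regions labeled 1
    ("NetA") and 2 ("NetB") in a world frame centered on the volume.
    """
    data = np.zeros(shape, dtype=np.int16)
    data[5:13, 5:13, 5:13] = 1
    data[26:34, 26:34, 26:34] = 2
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    affine[:3, 3] = -voxel_mm * np.asarray(shape) / 2.0
    return (data, affine), {1: "NetA", 2: "NetB"}


def _pink_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with power spectrum ~ 1/f**exponent, unit variance."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec *= f ** (-exponent / 2.0)
    x = np.fft.irfft(spec, n)
    return x / x.std()


def _narrowband_noise(n: int, band: tuple[float, float], fs: float,
                      rng: np.random.Generator, order: int = 4) -> np.ndarray:
    sos = sps.butter(order, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    return x / x.std()


def _logistic_profile(t: np.ndarray, t0: float, width: float) -> np.ndarray:
    """Smooth -1 -> +1 transition centered at t0 (logistic, 12-88% width)."""
    return 2.0 * expit((t - t0) / (width / 4.0)) - 1.0


def _delay(x: np.ndarray, lag: int) -> np.ndarray:
    out = np.zeros_like(x)
    if lag == 0:
        return x.copy()
    out[lag:] = x[:-lag]
    return out


def _group_sign(network: str, antagonistic: bool) -> float:
    return 1.0 if (network == "NetA" or not antagonistic) else -1.0


_COND_SIGN = {"ext2int": 1.0, "int2ext": -1.0}


def _session_events(config: GenConfig, n_per_cond: int,
                    rng: np.random.Generator) -> pd.DataFrame:
    span = config.trial_span[1] - config.trial_span[0]
    epoch = int(round(span * config.fs))
    pad = int(round(config.pad_s * config.fs))
    labels = np.array([CONDITIONS[0]] * n_per_cond + [CONDITIONS[1]] * n_per_cond)
    rng.shuffle(labels)
    onsets = pad + np.arange(len(labels)) * epoch + int(round(-config.trial_span[0]
                                                              * config.fs))
    return pd.DataFrame({"onset_sample": onsets, "condition": labels})


def _channel_coords(config: GenConfig, rng: np.random.Generator):
    (data, affine), labels = make_atlas()
    coords = {}
    for value, name in labels.items():
        ijk = np.argwhere(data == value)
        pick = rng.choice(len(ijk), size=config.n_channels_per_network,
                          replace=False)
        coords[name] = ijk[pick] @ affine[:3, :3].T + affine[:3, 3]
    return coords


def _build_session(config: GenConfig, n_per_cond: int,
                   rng: np.random.Generator, coords) -> tuple[Recording, list]:
    fs = config.fs
    events = _session_events(config, n_per_cond, rng)
    span = config.trial_span
    epoch = int(round((span[1] - span[0]) * fs))
    n_samples = 2 * int(round(config.pad_s * fs)) + len(events) * epoch
    n_pre = int(round(span[0] * fs))
    n_post = int(round(span[1] * fs))
    tt_epoch = np.arange(n_pre, n_post) / fs

    names, networks = [], []
    for net in NETWORKS:
        for i in range(config.n_channels_per_network):
            names.append(f"{net[-1]}{i + 1:02d}")
            networks.append(net)
    n_ch = len(names)

    # planted per-channel signals
    chan_sig = np.zeros((n_samples, n_ch))
    crossover_rows = []
    for ci, (name, net) in enumerate(zip(names, networks)):
        chan_sig[:, ci] = _pink_noise(n_samples, config.background_exponent, rng)
        for mod in config.band_modulations:
            carrier = _narrowband_noise(n_samples, mod.band, fs, rng)
            env = np.ones(n_samples)
            g = _group_sign(net, mod.antagonistic)
            t0 = mod.crossover_time + (mod.crossover_lag_per_group
                                       if net == "NetB" else 0.0)
            prof = _logistic_profile(tt_epoch, t0, mod.transition_width)
            for s, cond in zip(events["onset_sample"], events["condition"]):
                c = _COND_SIGN[cond]
                seg = slice(s + n_pre, s + n_post)
                env[seg] = 1.0 + g * c * (mod.condition_contrast / 2.0) * prof
            chan_sig[:, ci] += mod.base_amplitude * env * carrier
            crossover_rows.append({"channel": ci, "name": name, "network": net,
                                   "band_lo": mod.band[0], "band_hi": mod.band[1],
                                   "crossover_s": t0})

    # lagged directional coupling, reversing at the switch
    cp = config.coupling
    if cp is not None and cp.strength > 0:
        net_idx = {net: [i for i, n in enumerate(networks) if n == net]
                   for net in NETWORKS}
        sos = sps.butter(4, cp.band, btype="bandpass", fs=fs, output="sos")
        drive = {net: sps.sosfiltfilt(sos, chan_sig[:, net_idx[net]].mean(axis=1))
                 for net in NETWORKS}
        w = {("NetA", "NetB"): np.zeros(n_samples),
             ("NetB", "NetA"): np.zeros(n_samples)}
        post_profile = expit(tt_epoch / (cp.switch_width_s / 4.0))
        for s, cond in zip(events["onset_sample"], events["condition"]):
            post = tuple(cp.direction_by_condition[cond])
            pre = (post[1], post[0])
            seg = slice(s + n_pre, s + n_post)
            w[post][seg] = post_profile
            w[pre][seg] = 1.0 - post_profile
        for (src, dst), weight in w.items():
            mix = cp.strength * weight * _delay(drive[src], cp.lag)
            for ci in net_idx[dst]:
                chan_sig[:, ci] += mix

    # contacts: deep = channel + common mode, shallow = common mode
    contact_sig = np.empty((n_samples, 2 * n_ch))
    rows = []
    for ci, (name, net) in enumerate(zip(names, networks)):
        common = 0.5 * _pink_noise(n_samples, config.background_exponent, rng)
        contact_sig[:, 2 * ci] = chan_sig[:, ci] + common
        contact_sig[:, 2 * ci + 1] = common
        x, y, z = coords[net][ci % config.n_channels_per_network]
        for pos, dz in ((1, -0.75), (2, 0.75)):
            rows.append({"name": f"{name}c{pos}", "shank": name, "pos": pos,
                         "x": x, "y": y, "z": z + dz, "excluded": False,
                         "network": net})
    rec = Recording(signal=contact_sig, fs=fs, contacts=pd.DataFrame(rows),
                    events=events)
    return rec, crossover_rows


def generate_cohort(config: GenConfig):
    """Generate the synthetic cohort and its ground truth.

    Returns
    -------
    subjects : list of list of Recording
        One entry per subject; each subject holds ``config.n_sessions``
        continuous sessions whose trials sum to the configured counts.
    truth : GroundTruth
    """
    config.validate()
    master = np.random.SeedSequence(config.seed)
    subject_seeds = master.spawn(config.n_subjects)
    per_session = np.full(config.n_sessions,
                          config.n_trials_per_condition // config.n_sessions)
    per_session[:config.n_trials_per_condition % config.n_sessions] += 1
    subjects = []
    xo_rows = []
    art_rows: list[dict] = []
    for si, ss in enumerate(subject_seeds):
        rng = np.random.default_rng(ss)
        coords = _channel_coords(config, rng)
        sessions = []
        for sess_i in range(config.n_sessions):
            rec, xo = _build_session(config, int(per_session[sess_i]), rng,
                                     coords)
            if config.artifact_rate > 0:
                rec, log = inject_artifacts(
                    rec, config.artifact_rate, config.artifact_amplitude,
                    rng=rng, duration_s=config.artifact_duration_s)
                for row in log.to_dict("records"):
                    art_rows.append({"subject": si, "session": sess_i, **row})
            sessions.append(rec)
            if sess_i == 0:
                for row in xo:
                    xo_rows.append({"subject": si, **row})
        subjects.append(sessions)
    truth = GroundTruth(
        crossovers=pd.DataFrame(xo_rows),
        coupling={
            "direction_by_condition":
                {c: tuple(d) for c, d in
                 config.coupling.direction_by_condition.items()},
            "lag_samples": config.coupling.lag,
            "strength": config.coupling.strength,
            "band": tuple(config.coupling.band),
        },
        artifacts=pd.DataFrame(
            art_rows, columns=["subject", "session", "onset_s", "duration_s",
                               "channel"]),
        seed=config.seed,
    )
    return subjects, truth


def inject_artifacts(
    recording: Recording,
    rate: float,
    amplitude_sd: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    duration_s: float = 0.05,
):
    """Add transient high-amplitude deflections at Poisson-random times.

    Each artifact is a flat-top pulse of ``amplitude_sd`` times the SD of
    the affected contact, added to the *deep* contact of one shank so the
    deflection survives bipolar referencing.  Returns the modified recording
    and a log of (onset_s, duration_s, channel name).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    rec = replace(recording, signal=recording.signal.copy(),
                  contacts=recording.contacts.copy(),
                  events=recording.events.copy())
    log_rows: list[dict] = []
    if rate <= 0:
        return rec, pd.DataFrame(log_rows, columns=["onset_s", "duration_s",
                                                    "channel"])
    fs = rec.fs
    dur = int(round(duration_s * fs))
    n_events = rng.poisson(rate * rec.duration / 60.0)
    shanks = rec.contacts["shank"].unique()
    # flat-top pulse: every sample of the artifact sits at the full amplitude,
    # so the supra-threshold run matches the planted duration exactly
    pulse = np.ones(dur)
    for _ in range(n_events):
        onset = int(rng.integers(0, rec.n_samples - dur))
        shank = shanks[rng.integers(0, len(shanks))]
        grp = rec.contacts[rec.contacts["shank"] == shank].sort_values("pos")
        ci = rec.contacts.index.get_loc(grp.index[0])
        amp = amplitude_sd * rec.signal[:, ci].std()
        rec.signal[onset:onset + dur, ci] += amp * pulse
        log_rows.append({"onset_s": onset / fs, "duration_s": duration_s,
                         "channel": str(shank)})
    return rec, pd.DataFrame(log_rows, columns=["onset_s", "duration_s",
                                                "channel"])


# ---------------------------------------------------------------------------
# AR-mode trial generator (for validating MVAR spectral fidelity)

_AR_BANDS = (
    ("delta", 1.5, 1.0),
    ("theta", 5.5, 2.0),
    ("alpha", 10.0, 2.5),
    ("beta", 20.0, 6.0),
    ("lowgamma", 40.0, 8.0),
    ("hgb", 80.0, 20.0),
)


def _ar2_oscillator(n: int, f0: float, bw: float, fs: float,
                    rng: np.random.Generator) -> np.ndarray:
    """AR(2) resonator at f0 with ~bw Hz bandwidth, unit variance."""
    r = 1.0 - np.pi * bw / fs
    a1 = 2.0 * r * np.cos(2.0 * np.pi * f0 / fs)
    a2 = -r ** 2
    eps = rng.standard_normal(n + 200)
    x = sps.lfilter([1.0], [1.0, -a1, -a2], eps)[200:]
    return x / x.std()


def generate_ar_trials(
    n_channels_per_group: int = 3,
    n_trials: int = 60,
    fs: float = 512.0,
    span: tuple[float, float] = (-4.0, 4.0),
    mod_depth: float = 0.8,
    mod_period_s: float = 3.0,
    noise_std: float = 0.1,
    seed: int = 0,
) -> TrialTensor:
    """Trials from band-limited AR oscillators with slow envelope modulation.

    Each channel superimposes one AR(2) oscillator per analysis band; every
    (band, group, condition) gets a sinusoidal amplitude envelope with its own
    phase, shared across trials.  This produces strongly, smoothly modulated
    band power whose time course a well-specified MVAR model should track.
    """
    rng = np.random.default_rng(seed)
    n_pre = int(round(span[0] * fs))
    n_post = int(round(span[1] * fs))
    times = np.arange(n_pre, n_post) / fs
    n_t = len(times)
    names, nets = [], []
    for net in NETWORKS:
        for i in range(n_channels_per_group):
            names.append(f"{net[-1]}{i + 1:02d}")
            nets.append(net)
    n_ch = len(names)
    data = {}
    for cond in CONDITIONS:
        x = noise_std * rng.standard_normal((n_t, n_ch, n_trials))
        for _, f0, bw in _AR_BANDS:
            for gi, net in enumerate(NETWORKS):
                phase = rng.uniform(0, 2 * np.pi)
                env = 1.0 + mod_depth * np.sin(
                    2 * np.pi * times / mod_period_s + phase)
                for ci in range(n_ch):
                    if nets[ci] != net:
                        continue
                    for tr in range(n_trials):
                        osc = _ar2_oscillator(n_t, f0, bw, fs, rng)
                        x[:, ci, tr] += env * osc
        data[cond] = x
    channels = pd.DataFrame({"name": names, "network": nets,
                             "x": 0.0, "y": 0.0, "z": 0.0})
    onsets = {c: np.arange(d.shape[2]) for c, d in data.items()}
    return TrialTensor(data=data, times=times, fs=fs, channels=channels,
                       onsets=onsets)
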