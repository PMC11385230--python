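"""Shared fixtures: one small synthetic cohort, preprocessed once per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import netswitch as ns


@pytest.fixture(scope="session")
def cohort():
    """One-subject cohort with planted alpha/HGB crossovers and coupling."""
    cfg = ns.GenConfig(
        n_subjects=1, n_channels_per_network=3, n_trials_per_condition=60,
        band_modulations=[
            ns.BandModulation(band=(8.0, 12.0), base_amplitude=1.0,
                              condition_contrast=1.0, crossover_time=0.5),
            ns.BandModulation(band=(52.0, 120.0), base_amplitude=0.6,
                              condition_contrast=-1.0, crossover_time=0.5),
        ],
        coupling=ns.CouplingConfig(strength=1.0, lag=8, band=(4.0, 12.0)),
        artifact_rate=0.5, seed=11)
    subjects, truth = ns.generate_cohort(cfg)
    return cfg, subjects, truth


@pytest.fixture(scope="session")
def preprocessed(cohort):
    """Filtered, bipolar-referenced session with epoched, masked trials."""
    _, subjects, _ = cohort
    rec = subjects[0][0]
    bip = ns.bipolar_reference(ns.filter_chain(rec))
    trials = ns.extract_trials(bip)
    ns.reject_epochs(trials, bip)
    return bip, trials


@pytest.fixture(scope="session")
def rbp(preprocessed):
    """Session-normalized six-band RBP of the fixture cohort."""
    bip, trials = preprocessed
    return ns.rbp_from_recording(bip, trials)


@pytest.fixture()
def toy_recording():
    """Tiny deterministic recording: one 4-contact shank, white noise."""
    rng = np.random.default_rng(0)
    n = 512 * 20
    sig = rng.standard_normal((n, 4))
    contacts = pd.DataFrame({
        "name": ["a1", "a2", "a3", "a4"], "shank": "a",
        "pos": [1, 2, 3, 4], "x": [0.0, 0.0, 0.0, 0.0],
        "y": 0.0, "z": [0.0, 1.5, 3.0, 4.5]})
    events = pd.DataFrame({"onset_sample": [512 * 6, 512 * 14],
                           "condition": ["ext2int", "int2ext"]})
    return ns.Recording(signal=sig, fs=512.0, contacts=contacts,
                        events=events)
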