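"""Referencing, filtering, epoching and amplitude-rejection behaviour."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal as sps
from scipy.stats import norm

import netswitch as ns


def _shank_recording(signals, excluded=None, fs=512.0):
    n_contacts = signals.shape[1]
    contacts = pd.DataFrame({
        "name": [f"a{i + 1}" for i in range(n_contacts)], "shank": "a",
        "pos": np.arange(1, n_contacts + 1), "x": 0.0, "y": 0.0,
        "z": np.arange(n_contacts) * 1.5,
        "excluded": excluded if excluded is not None else False})
    return ns.Recording(signal=signals, fs=fs, contacts=contacts,
                        events=pd.DataFrame({"onset_sample": [],
                                             "condition": []}))


class TestBipolarReference:
    def test_adjacent_pairs_deepest_first(self):
        x = np.arange(12.0).reshape(4, 3)  # contacts a1..a3
        rec = _shank_recording(x)
        out = ns.bipolar_reference(rec)
        assert list(out.contacts["name"]) == ["a1-a2", "a2-a3"]
        np.testing.assert_allclose(out.signal[:, 0], x[:, 0] - x[:, 1])
        np.testing.assert_allclose(out.signal[:, 1], x[:, 1] - x[:, 2])

    def test_common_mode_cancellation(self):
        common = np.sin(np.linspace(0, 10, 100))
        x = np.tile(common[:, None], (1, 3))
        out = ns.bipolar_reference(_shank_recording(x))
        np.testing.assert_allclose(out.signal, 0.0, atol=1e-12)

    def test_broken_contact_breaks_adjacency(self):
        # shank a: [a1, broken a2, a3] -> no skip-pair a1-a3; shank b healthy
        x = np.random.default_rng(0).standard_normal((50, 5))
        contacts = pd.DataFrame({
            "name": ["a1", "a2", "a3", "b1", "b2"],
            "shank": ["a", "a", "a", "b", "b"],
            "pos": [1, 2, 3, 1, 2], "x": 0.0, "y": 0.0, "z": 0.0,
            "excluded": [False, True, False, False, False]})
        rec = ns.Recording(signal=x, fs=512.0, contacts=contacts,
                           events=pd.DataFrame({"onset_sample": [],
                                                "condition": []}))
        with pytest.warns(UserWarning, match="shank 'a'"):
            out = ns.bipolar_reference(rec)
        assert list(out.contacts["name"]) == ["b1-b2"]

    def test_common_signal_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((200, 4))
        add = rng.standard_normal(200)
        a = ns.bipolar_reference(_shank_recording(x))
        b = ns.bipolar_reference(_shank_recording(x + add[:, None]))
        np.testing.assert_allclose(a.signal, b.signal, atol=1e-12)

    def test_midpoint_coordinates(self):
        x = np.zeros((10, 2))
        out = ns.bipolar_reference(_shank_recording(x))
        assert out.contacts.loc[0, "z"] == pytest.approx(0.75)

    def test_single_contact_shank_warns_and_errors(self):
        x = np.zeros((10, 1))
        with pytest.raises(ValueError):
            with pytest.warns(UserWarning):
                ns.bipolar_reference(_shank_recording(x))


class TestFilterChain:
    def test_dc_removed(self):
        x = np.full((512 * 10, 1), 5.0)
        out = ns.filter_chain(_shank_recording(np.c_[x, x]))
        assert np.abs(out.signal[512 * 2:-512 * 2]).max() < 1e-6 * 5.0

    @pytest.mark.parametrize("freq,lo,hi", [(50.0, None, -40.0),
                                            (100.0, None, -40.0),
                                            (10.0, -0.5, 0.5)])
    def test_chain_frequency_response(self, freq, lo, hi):
        """Steady-state gain from the designed filters' frequency response.

        The chain is applied forward-backward, so the effective magnitude
        response is the squared product of the single-pass responses.
        """
        fs = 512.0
        gain = 1.0
        for sos in (
            sps.butter(6, 0.1, btype="highpass", fs=fs, output="sos"),
            sps.butter(6, [48, 52], btype="bandstop", fs=fs, output="sos"),
            sps.butter(6, [98, 102], btype="bandstop", fs=fs, output="sos"),
        ):
            _, h = sps.sosfreqz(sos, worN=[freq], fs=fs)
            gain *= np.abs(h[0]) ** 2
        gain_db = 20 * np.log10(gain)
        if lo is not None:
            assert gain_db > lo
        if hi is not None:
            assert gain_db < hi

    def test_notch_above_nyquist_errors(self):
        rec = _shank_recording(np.zeros((100, 2)), fs=128.0)
        with pytest.raises(ValueError, match="98.*102|Nyquist"):
            ns.filter_chain(rec)


class TestDownsample:
    def test_2048_to_512_divides_length_by_four(self):
        rng = np.random.default_rng(2)
        rec = _shank_recording(rng.standard_normal((2048 * 4, 2)), fs=2048.0)
        rec.events = pd.DataFrame({"onset_sample": [4096],
                                   "condition": ["ext2int"]})
        out = ns.downsample(rec, 512.0)
        assert out.signal.shape[0] == rec.signal.shape[0] // 4
        assert out.events["onset_sample"].iloc[0] == 1024

    def test_already_at_target_is_identity(self, toy_recording):
        out = ns.downsample(toy_recording, 512.0)
        assert out is toy_recording

    def test_inband_amplitude_preserved(self):
        fs = 2048.0
        t = np.arange(int(fs * 4)) / fs
        x = np.sin(2 * np.pi * 30.0 * t)[:, None]
        out = ns.downsample(_shank_recording(np.c_[x, x], fs=fs), 512.0)
        mid = out.signal[512:-512, 0]
        assert np.abs(mid.std() * np.sqrt(2) - 1.0) < 0.01

    def test_non_integer_ratio_errors(self):
        rec = _shank_recording(np.zeros((1000, 2)), fs=1000.0)
        with pytest.raises(ValueError, match="integer"):
            ns.downsample(rec, 512.0)


class TestExtractTrials:
    def test_epoch_sample_arithmetic(self, toy_recording):
        trials = ns.extract_trials(toy_recording, span=(-4.0, 4.0))
        s = toy_recording.events["onset_sample"].iloc[0]
        expected = toy_recording.signal[s - 2048:s + 2048, :3]
        bip = trials  # channels here are raw contacts
        assert trials.data["ext2int"].shape[0] == 4096
        assert trials.times[2048] == 0.0
        np.testing.assert_allclose(
            trials.data["ext2int"][:, :3, 0], expected)

    def test_boundary_trial_dropped(self):
        rng = np.random.default_rng(3)
        rec = _shank_recording(rng.standard_normal((512 * 12, 2)))
        rec.events = pd.DataFrame({
            "onset_sample": [512 * 6, 512 * 11],  # second is 1 s from end
            "condition": ["ext2int", "ext2int"]})
        with pytest.warns(UserWarning, match="dropped"):
            trials = ns.extract_trials(rec, conditions=("ext2int",))
        assert trials.n_trials("ext2int") == 1

    def test_no_trials_errors(self, toy_recording):
        rec = toy_recording
        rec2 = ns.Recording(signal=rec.signal, fs=rec.fs,
                            contacts=rec.contacts,
                            events=pd.DataFrame({"onset_sample": [100],
                                                 "condition": ["ext2int"]}))
        with pytest.raises(ValueError, match="no extractable"):
            with pytest.warns(UserWarning):
                ns.extract_trials(rec2, conditions=("ext2int",))

    def test_sixty_interior_events_give_sixty_trials(self, cohort):
        _, subjects, _ = cohort
        trials = ns.extract_trials(ns.bipolar_reference(subjects[0][0]))
        assert trials.n_trials("ext2int") == 60
        assert trials.n_trials("int2ext") == 60


class TestRejectEpochs:
    def test_planted_spike_mask_extent(self):
        rng = np.random.default_rng(4)
        n = 512 * 30
        # second contact silent so the bipolar channel equals the first
        sig = np.c_[rng.standard_normal(n), np.zeros(n)]
        dur = int(round(0.05 * 512))
        onset = 512 * 11
        sig[onset:onset + dur, 0] += 8.0 * sig[:, 0].std()
        rec = _shank_recording(sig)
        rec.events = pd.DataFrame({"onset_sample": [512 * 10],
                                   "condition": ["ext2int"]})
        bip = ns.bipolar_reference(rec)
        trials = ns.extract_trials(bip, conditions=("ext2int",))
        mask = ns.reject_epochs(trials, bip)
        m = mask["ext2int"][:, 0, 0]
        run = np.flatnonzero(m)
        expected = dur + 2 * int(round(0.1 * 512))
        assert abs((run.max() - run.min() + 1) - expected) <= 1
        in_artifact = (trials.times >= 1.0) & (trials.times < 1.0 + 0.05)
        assert m[in_artifact].all()

    def test_gaussian_noise_masked_fraction_small(self):
        # per-sample exceedance 2*Phi(-6) inflated by the margins stays tiny
        rng = np.random.default_rng(5)
        sig = rng.standard_normal((512 * 60, 2))
        rec = _shank_recording(sig)
        rec.events = pd.DataFrame({"onset_sample": [512 * 20],
                                   "condition": ["ext2int"]})
        bip = ns.bipolar_reference(rec)
        trials = ns.extract_trials(bip, conditions=("ext2int",))
        mask = ns.reject_epochs(trials, bip)
        assert mask["ext2int"].mean() < 0.005
        assert 2 * norm.cdf(-6) < 1e-8  # the margin inflation dominates

    def test_constant_channel_empty_mask(self):
        sig = np.c_[np.zeros(512 * 20), np.zeros(512 * 20)]
        rec = _shank_recording(sig)
        rec.events = pd.DataFrame({"onset_sample": [512 * 10],
                                   "condition": ["ext2int"]})
        bip = ns.bipolar_reference(rec)
        trials = ns.extract_trials(bip, conditions=("ext2int",))
        with pytest.warns(UserWarning, match="zero variance"):
            mask = ns.reject_epochs(trials, bip)
        assert not mask["ext2int"].any()

    def test_cohort_artifacts_covered(self, cohort, preprocessed):
        cfg, subjects, truth = cohort
        bip, trials = preprocessed
        fs = bip.fs
        log = truth.artifacts
        n_pre = int(round(trials.times[0] * fs))
        n_len = len(trials.times)
        covered = total = 0
        names = list(bip.contacts["shank"])
        for _, row in log.iterrows():
            ch = names.index(row.channel)
            a0 = int(round(row.onset_s * fs))
            a1 = a0 + int(round(row.duration_s * fs))
            for cond, ons in trials.onsets.items():
                for ti, s in enumerate(ons):
                    lo, hi = s + n_pre, s + n_pre + n_len
                    if a1 <= lo or a0 >= hi:
                        continue
                    seg = trials.mask[cond][max(a0 - lo, 0):min(a1 - lo, n_len),
                                            ch, ti]
                    covered += seg.sum()
                    total += seg.size
        if total:
            assert covered / total >= 0.99


def test_notch_filter_and_epoching_commute_on_interior(toy_recording):
    """Filtering the session then epoching equals filtering the epoch.

    Checked for the line-noise notches, whose zero-phase transients decay
    within tens of samples, on the epoch interior (1 s margins); the 0.1 Hz
    high-pass has second-scale transients and needs the session context.
    """
    rec = toy_recording
    hp_skipped = ns.filter_chain(rec, highpass_hz=None)  # notches only
    sos1 = sps.butter(6, [48, 52], btype="bandstop", fs=rec.fs, output="sos")
    sos2 = sps.butter(6, [98, 102], btype="bandstop", fs=rec.fs, output="sos")
    session_then_epoch = ns.extract_trials(hp_skipped, span=(-2.0, 2.0))
    epoch_first = ns.extract_trials(rec, span=(-4.0, 4.0))
    scale = np.abs(rec.signal).max()
    for cond in session_then_epoch.data:
        x = epoch_first.data[cond]
        y = sps.sosfiltfilt(sos1, x, axis=0, padlen=2000)
        y = sps.sosfiltfilt(sos2, y, axis=0, padlen=2000)
        # compare the common (-0.5, 0.5) s core: the narrow notches' zero-phase
        # transients decay with a ~0.3 s time constant, which sets the
        # agreement floor at ~1e-5 for 1.5 s margins
        core = y[2048 - 256:2048 + 256]
        ref = session_then_epoch.data[cond][1024 - 256:1024 + 256]
        assert np.max(np.abs(core - ref)) < 2e-5 * scale
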