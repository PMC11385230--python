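"""MVAR fitting, DTF/PDC/GGC measures, sliding windows and PLV."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal as sps

import netswitch as ns
from netswitch.connectivity import (_window_starts, band_split, dtf, fit_mvar,
                                    ggc, pdc, plv, transfer_function)
from netswitch.preprocess import TrialTensor

FS = 512.0


def simulate_var(A, n, n_tr, seed=0, burn=50):
    """Simulate a VAR process with coefficient stack A (p, k, k)."""
    rng = np.random.default_rng(seed)
    p, k, _ = A.shape
    x = np.zeros((n + burn, k, n_tr))
    eps = rng.standard_normal((n + burn, k, n_tr))
    for t in range(p, n + burn):
        lagged = np.stack([x[t - l] for l in range(1, p + 1)])
        x[t] = np.einsum("lij,ljr->ir", A, lagged) + eps[t]
    return x[burn:]


def unidirectional_var2(coupling=0.3):
    A = np.zeros((2, 2, 2))
    A[0, 0, 0] = 0.5
    A[0, 1, 1] = 0.5
    A[0, 1, 0] = coupling   # channel 1 drives channel 2 at lag 1
    return A


class TestBandSplit:
    def test_sinusoid_isolated_to_its_band(self):
        t = np.arange(int(FS * 4)) / FS
        x = np.sin(2 * np.pi * 40.0 * t)[:, None, None]
        out = band_split(x, FS, zscore=False)
        p_in = out[(31.0, 48.0)].std()
        assert p_in == pytest.approx(np.sqrt(0.5), rel=0.02)
        for (lo, hi), arr in out.items():
            if (lo, hi) == (31.0, 48.0):
                continue
            # oracle: squared magnitude of the designed zero-phase filter
            if lo <= 0.5:
                sos = sps.butter(6, hi, btype="lowpass", fs=FS, output="sos")
            else:
                sos = sps.butter(6, [lo, hi], btype="bandpass", fs=FS,
                                 output="sos")
            _, h = sps.sosfreqz(sos, worN=[40.0], fs=FS)
            expect_db = 40 * np.log10(np.abs(h[0]))  # forward-backward pass
            got_db = 20 * np.log10(arr[512:-512].std() / p_in)
            assert got_db < -25.0
            if expect_db > -80.0:  # below that, numerical floor dominates
                assert got_db == pytest.approx(expect_db, abs=2.0)

    def test_zero_trials_stay_zero(self):
        out = band_split(np.zeros((1024, 2, 3)), FS)
        for arr in out.values():
            np.testing.assert_allclose(arr, 0.0)

    def test_fixed_orders_equal_integer_bandwidth(self):
        orders = {band: p for band, p in ns.FIT_BANDS}
        assert orders[(31.0, 48.0)] == 17
        assert orders[(0.1, 30.0)] == 29
        assert orders[(52.0, 98.0)] == 46
        assert orders[(102.0, 120.0)] == 18


class TestFitMvar:
    def test_var2_coefficients_recovered(self):
        A = unidirectional_var2(0.4)
        x = simulate_var(A, 256, 60, seed=1)
        m = fit_mvar(x, p=2, fs=FS)
        assert np.sqrt(np.mean((m.A - A) ** 2)) < 0.05
        assert m.is_stable()

    def test_white_noise_null_coefficients_small(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((256, 2, 60))
        m = fit_mvar(x, p=2, fs=FS)
        n_eff = 256 * 60
        assert np.abs(m.A).max() < 3.0 / np.sqrt(n_eff) * 3

    def test_zero_order_errors(self):
        with pytest.raises(ValueError, match="p must be"):
            fit_mvar(np.zeros((100, 2, 3)), p=0)

    def test_underdetermined_design_errors(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((12, 4, 1))
        with pytest.raises(np.linalg.LinAlgError, match="under-determined"):
            fit_mvar(x, p=10, window=(10, 12))


class TestTransferFunction:
    freqs = np.arange(1.0, 100.0)

    def test_zero_coefficients_give_identity(self):
        m = ns.MvarModel(A=np.zeros((1, 3, 3)), Z=np.eye(3), p=1, fs=FS)
        H = transfer_function(m, self.freqs)
        np.testing.assert_allclose(H, np.broadcast_to(np.eye(3),
                                                      H.shape), atol=1e-12)

    def test_ar1_dc_gain_closed_form(self):
        m = ns.MvarModel(A=np.full((1, 1, 1), 0.5), Z=np.eye(1), p=1, fs=FS)
        H = transfer_function(m, np.array([0.0]))
        assert np.abs(H[0, 0, 0]) == pytest.approx(2.0)

    def test_block_diagonal_model_gives_block_diagonal_h(self):
        A = np.zeros((1, 4, 4))
        A[0, :2, :2] = [[0.3, 0.2], [0.1, 0.4]]
        A[0, 2:, 2:] = [[0.5, 0.0], [0.2, 0.1]]
        m = ns.MvarModel(A=A, Z=np.eye(4), p=1, fs=FS)
        H = transfer_function(m, self.freqs)
        np.testing.assert_allclose(H[:, :2, 2:], 0.0, atol=1e-12)
        np.testing.assert_allclose(H[:, 2:, :2], 0.0, atol=1e-12)


class TestMeasures:
    def _fitted(self, seed=4):
        x = simulate_var(unidirectional_var2(), 256, 60, seed=seed)
        m = fit_mvar(x, p=2, fs=FS)
        freqs = np.arange(1.0, 120.0)
        return m, transfer_function(m, freqs), freqs

    def test_dtf_rows_and_pdc_columns_normalized_exactly(self):
        m, H, freqs = self._fitted()
        D = dtf(H)
        P = pdc(m, freqs)
        np.testing.assert_allclose((D ** 2).sum(axis=-1), 1.0, atol=1e-12)
        np.testing.assert_allclose((P ** 2).sum(axis=-2), 1.0, atol=1e-12)

    def test_identity_patterns_for_independent_channels(self):
        m = ns.MvarModel(A=np.zeros((1, 3, 3)), Z=np.eye(3), p=1, fs=FS)
        freqs = np.arange(1.0, 100.0)
        H = transfer_function(m, freqs)
        eye = np.broadcast_to(np.eye(3), H.shape)
        np.testing.assert_allclose(dtf(H), eye, atol=1e-12)
        np.testing.assert_allclose(pdc(m, freqs), eye, atol=1e-12)
        np.testing.assert_allclose(ggc(m, H)[:, ~np.eye(3, dtype=bool)],
                                   0.0, atol=1e-12)

    def test_ggc_nonnegative(self):
        m, H, _ = self._fitted()
        assert (ggc(m, H) >= 0).all()

    def test_direction_recovered_by_all_three_measures(self):
        hits = 0
        for seed in range(10):
            m, H, freqs = self._fitted(seed=100 + seed)
            D, P, G = dtf(H), pdc(m, freqs), ggc(m, H)
            ok = (D[:, 1, 0].mean() > D[:, 0, 1].mean()
                  and P[:, 1, 0].mean() > P[:, 0, 1].mean()
                  and G[:, 1, 0].mean() > G[:, 0, 1].mean())
            hits += ok
        assert hits == 10

    def test_nonpositive_definite_z_errors(self):
        m = ns.MvarModel(A=np.zeros((1, 2, 2)),
                         Z=np.array([[1.0, 2.0], [2.0, 1.0]]), p=1, fs=FS)
        H = transfer_function(m, np.array([10.0]))
        with pytest.raises(np.linalg.LinAlgError, match="positive definite"):
            ggc(m, H)


class TestSlidingWindows:
    def test_window_count_over_crop(self):
        times = np.arange(-2048, 2048) / FS
        starts, centers, n_win = _window_starts(times, FS, 0.5, 0.125,
                                                (-2.3, 2.3))
        assert len(starts) == 33
        assert n_win == 256

    def test_stationary_coupling_zscored_series_flat(self):
        # z-scoring along time removes any stationary connectivity level
        rng = np.random.default_rng(5)
        x = rng.standard_normal((4096, 4, 40))
        trials = TrialTensor(
            data={"a": x, "b": x + 0.0}, times=np.arange(-2048, 2048) / FS,
            fs=FS, channels=pd.DataFrame({"name": list("wxyz")}),
            onsets={"a": np.arange(40), "b": np.arange(40)})
        res = ns.sliding_connectivity(
            trials, np.array(["NetA", "NetA", "NetB", "NetB"]),
            measures=("dtf",), fit_bands=(((0.1, 30.0), 10),))
        s = res.series["dtf"]["a"][("NetA", "NetB")][:, 0]
        slope = np.polyfit(res.times, s, 1)[0]
        assert abs(slope) < 0.5  # z-units per second, pure noise level


class TestPlv:
    def _trials(self, data):
        n = data.shape[0]
        return TrialTensor(
            data={"c": data}, times=(np.arange(n) - n // 2) / FS, fs=FS,
            channels=pd.DataFrame({"name": [f"c{i}" for i in
                                            range(data.shape[1])]}),
            onsets={"c": np.arange(data.shape[2])})

    def test_self_pair_is_one(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal((1024, 2, 20))
        x[:, 1] = x[:, 0]
        pr = plv(self._trials(x), crop=(-0.8, 0.8))
        np.testing.assert_allclose(pr.plv["c"][:, :, 0, 1], 1.0, atol=1e-9)
        np.testing.assert_allclose(pr.plv["c"][:, :, 0, 0], 1.0, atol=1e-9)

    def test_constant_lag_gives_plv_one(self):
        rng = np.random.default_rng(7)
        x = np.empty((4096, 2, 20))
        x[:, 0] = rng.standard_normal((4096, 20))
        x[8:, 1] = x[:-8, 0]
        x[:8, 1] = 0.0
        pr = plv(self._trials(x), crop=(-2.0, 2.0))
        # a pure sample lag is a fixed phase offset per frequency
        assert pr.plv["c"][:, 1:4, 0, 1].mean() > 0.95
        assert pr.plv["c"][:, 0, 0, 1].mean() > 0.7

    def test_band_above_nyquist_errors(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal((512, 2, 4))
        with pytest.raises(ValueError, match="Nyquist"):
            plv(self._trials(x), fmax=400.0)

    def test_plv_bounded_unit_interval(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal((1024, 3, 10))
        pr = plv(self._trials(x), crop=(-0.8, 0.8))
        assert (pr.plv["c"] >= 0).all() and (pr.plv["c"] <= 1 + 1e-12).all()


class TestGroupStats:
    def test_identical_series_no_significance(self):
        rng = np.random.default_rng(10)
        subj = [{"a": rng.standard_normal((20, 2)),
                 "b": rng.standard_normal((20, 2))} for _ in range(8)]
        mask = ns.connectivity_group_stats(subj, alpha=0.001)
        assert mask.mean() < 0.05

    def test_planted_band_difference_detected_in_band_only(self):
        rng = np.random.default_rng(11)
        subj = []
        for _ in range(10):
            a = rng.standard_normal((20, 2)) * 0.1
            b = rng.standard_normal((20, 2)) * 0.1
            a[:, 0] += 2.0  # strong condition difference in band 0 only
            subj.append({"a": a, "b": b})
        mask = ns.connectivity_group_stats(subj, alpha=0.001)
        assert mask[:, 0].mean() > 0.9
        assert mask[:, 1].mean() < 0.05

    def test_single_subject_errors(self):
        with pytest.raises(ValueError, match="2 subjects"):
            ns.connectivity_group_stats([{"a": np.zeros((5, 1)),
                                          "b": np.zeros((5, 1))}])
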