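"""EEG preprocessing primitives: reference, filters, GESD, epoching,
interpolation, smoothing, baseline, response-locking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from bcfskit import eeg
from bcfskit.eeg import (
    EpochSet,
    PreprocConfig,
    baseline_correct,
    downsample,
    epoch_continuous,
    filter_signal,
    gesd_outliers,
    interpolate_bad_channels,
    rereference_average,
    response_lock,
    smooth_moving_average,
)
from bcfskit.montage import chain_montage


def _epochs(data, sfreq=100.0, tmin=-0.1, adjacency=None, labels=None):
    data = np.asarray(data, dtype=float)
    n = data.shape[2]
    return EpochSet(
        data=data, sfreq=sfreq,
        times=tmin + np.arange(n) / sfreq,
        lock="stimulus",
        labels=labels or [f"E{i+1}" for i in range(data.shape[1])],
        adjacency=adjacency or [],
    )


class TestReference:
    def test_constant_offsets_become_zero_mean(self):
        data = np.stack([np.full((3, 50), v) for v in (1.0, 2.0, 5.0)], axis=1)
        out = rereference_average(_epochs(data))
        assert np.abs(out.data.mean(axis=1)).max() < 1e-12

    def test_random_data_zero_mean_per_sample(self):
        rng = np.random.default_rng(0)
        out = rereference_average(_epochs(rng.standard_normal((4, 6, 80))))
        assert np.abs(out.data.mean(axis=1)).max() < 1e-10

    def test_single_electrode_errors(self):
        with pytest.raises(ValueError):
            rereference_average(_epochs(np.zeros((2, 1, 30))))


class TestFilter:
    sfreq = 1000.0

    def _attenuation(self, freq):
        # Lock-in measurement of the target frequency so slow edge
        # transients of the 0.1 Hz high-pass do not contaminate the ratio.
        t = np.arange(int(20 * self.sfreq)) / self.sfreq
        x = np.sin(2 * np.pi * freq * t)[None, :]
        y = filter_signal(x, self.sfreq)
        mid = slice(int(5 * self.sfreq), int(15 * self.sfreq))
        s = np.sin(2 * np.pi * freq * t[mid])
        c = np.cos(2 * np.pi * freq * t[mid])
        amp = np.hypot(2 * (y[0, mid] * s).mean(), 2 * (y[0, mid] * c).mean())
        return amp  # input amplitude is 1

    def test_notch_kills_line_noise(self):
        assert self._attenuation(50.0) < 0.1  # >= 20 dB

    def test_passband_ripple_small_at_10hz(self):
        assert self._attenuation(10.0) == pytest.approx(1.0, abs=0.1)

    def test_dc_offset_removed(self):
        x = np.full((1, int(60 * self.sfreq)), 3.0)
        y = filter_signal(x, self.sfreq)
        assert abs(y[0, int(30 * self.sfreq)]) < 0.15

    def test_downsample_preserves_slow_signal(self):
        t = np.arange(int(4 * self.sfreq)) / self.sfreq
        x = np.sin(2 * np.pi * 5 * t)[None, :]
        y = downsample(x, self.sfreq, 100.0)
        assert y.shape[-1] == 400
        t100 = np.arange(400) / 100.0
        mid = slice(50, 350)
        assert np.allclose(y[0, mid], np.sin(2 * np.pi * 5 * t100)[mid], atol=0.02)


def _brute_gesd(x, alpha=0.05, max_outliers=None):
    x = np.asarray(x, dtype=float)
    n = x.size
    if max_outliers is None:
        max_outliers = max(1, int(0.2 * n))
    vals = x.copy()
    idx = np.arange(n)
    removed = []
    n_sig = 0
    for i in range(1, max_outliers + 1):
        mu = vals.mean()
        sd = vals.std(ddof=1)
        if sd == 0:
            break
        j = int(np.argmax(np.abs(vals - mu)))
        r = abs(vals[j] - mu) / sd
        p = 1 - alpha / (2 * (n - i + 1))
        tcrit = stats.t.ppf(p, n - i - 1)
        lam = (n - i) * tcrit / np.sqrt((n - i - 1 + tcrit**2) * (n - i + 1))
        removed.append(int(idx[j]))
        if r > lam:
            n_sig = i
        vals = np.delete(vals, j)
        idx = np.delete(idx, j)
    return sorted(removed[:n_sig])


class TestGESD:
    def test_injected_outlier_flagged(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal(100)
            x[17] = 10.0
            out = gesd_outliers(x)
            hits += (out.tolist() == [17])
        assert hits >= 48

    def test_null_rarely_flags(self):
        flagged = 0
        for seed in range(200):
            rng = np.random.default_rng(10_000 + seed)
            flagged += gesd_outliers(rng.standard_normal(60)).size > 0
        # about alpha of seeds flag anything under the null
        assert flagged / 200 < 0.15

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(10, 25), st.integers(0, 3))
    def test_oracle_equivalence_small_n(self, seed, n, n_out):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(n)
        x[:n_out] += rng.choice([-8, 8], size=n_out)
        mo = max(1, min(int(0.2 * n) + n_out, (n - 1) // 2 - 1))
        if n < 3 + mo or mo < 1:
            return
        assert gesd_outliers(x, max_outliers=mo).tolist() == _brute_gesd(
            x, max_outliers=mo)

    def test_config_errors(self):
        with pytest.raises(ValueError):
            gesd_outliers(np.arange(10.0), max_outliers=5)


class TestEpoching:
    def test_sample_conventions(self):
        cont = np.arange(2000.0)[None, :]
        out = epoch_continuous(cont, 100.0, [1000], window=(-0.1, 3.0))
        assert out.data.shape == (1, 1, 310)
        assert out.data[0, 0, 0] == 990 and out.data[0, 0, -1] == 1299
        assert out.times[0] == pytest.approx(-0.1)
        assert out.times[-1] == pytest.approx(2.99)

    def test_response_lock_alignment(self):
        cont = np.arange(3000.0)[None, :]
        ep = epoch_continuous(cont, 100.0, [1000], window=(-0.1, 3.0))
        locked, kept = response_lock(ep, [1.0], window=(-0.5, 0.0))
        assert kept.tolist() == [0]
        # stimulus-locked sample at t = 1.0 s is continuous sample 1100
        i0 = np.argmin(np.abs(locked.times - 0.0))
        # window is [-0.5, 0): time zero is one sample past the last sample
        assert locked.data[0, 0, -1] == 1099
        assert locked.lock == "response"

    def test_response_lock_drops_missing_rt(self):
        cont = np.zeros((1, 3000))
        ep = epoch_continuous(cont, 100.0, [500, 1000], window=(-0.1, 3.0))
        locked, kept = response_lock(ep, [np.nan, 1.2])
        assert kept.tolist() == [1]
        assert locked.n_trials == 1
        assert any("no_response" in line for line in locked.log)


class TestInterpolation:
    def test_uniform_neighbour_mean_exact(self):
        mont = chain_montage(3)
        rng = np.random.default_rng(1)
        data = rng.standard_normal((2, 3, 40))
        data[:, 1, :] = 0.0
        ep = _epochs(data, adjacency=mont["edges"], labels=mont["labels"])
        out = interpolate_bad_channels(ep, ["E2"])
        assert np.allclose(out.data[:, 1, :], 0.5 * (data[:, 0, :] + data[:, 2, :]))

    def test_all_neighbours_bad_errors(self):
        mont = chain_montage(3)
        ep = _epochs(np.zeros((1, 3, 10)), adjacency=mont["edges"],
                     labels=mont["labels"])
        with pytest.raises(ValueError):
            interpolate_bad_channels(ep, ["E1", "E2"])


class TestSmoothing:
    def test_constant_unchanged(self):
        ep = _epochs(np.full((2, 2, 100), 3.3))
        out = smooth_moving_average(ep)
        assert np.allclose(out.data, 3.3)

    def test_boxcar_nulls_10hz(self):
        """A 200-ms boxcar at 100 Hz suppresses a 10 Hz sinusoid < 1%."""
        t = np.arange(400) / 100.0
        ep = _epochs(np.sin(2 * np.pi * 10 * t)[None, None, :], tmin=0.0)
        out = smooth_moving_average(ep, window=0.2)
        mid = slice(30, 370)
        assert np.abs(out.data[0, 0, mid]).max() < 0.01

    def test_impulse_plateau(self):
        x = np.zeros((1, 1, 100))
        x[0, 0, 50] = 1.0
        out = smooth_moving_average(_epochs(x), window=0.2)
        inner = out.data[0, 0, 40:60]
        assert np.allclose(inner, 1 / 20)
        assert out.data[0, 0, 20] == 0.0

    def test_length_preserved(self):
        out = smooth_moving_average(_epochs(np.random.default_rng(0)
                                            .standard_normal((3, 2, 77))))
        assert out.data.shape == (3, 2, 77)


class TestBaseline:
    def test_baseline_mean_zero(self):
        rng = np.random.default_rng(2)
        ep = _epochs(rng.standard_normal((4, 3, 310)) + 5.0)
        out = baseline_correct(ep, window=(-0.05, 0.0))
        mask = (out.times >= -0.05) & (out.times <= 0.0)
        assert np.abs(out.data[:, :, mask].mean(axis=2)).max() < 1e-12

    def test_constant_trial_all_zero(self):
        ep = _epochs(np.full((1, 2, 310), 7.0))
        out = baseline_correct(ep)
        assert np.allclose(out.data, 0.0)

    def test_window_outside_epoch_errors(self):
        ep = _epochs(np.zeros((1, 2, 100)), tmin=0.0)
        with pytest.raises(ValueError):
            baseline_correct(ep, window=(-0.5, -0.4))


def test_channel_screen_flags_noisy_electrode():
    rng = np.random.default_rng(12)
    data = rng.standard_normal((20, 10, 100))
    data[:, 4, :] *= 25.0
    ep = _epochs(data)
    assert eeg.screen_bad_channels(ep) == ["E5"]


class TestPipeline:
    def test_shape_conservation_and_log(self, small_epochs):
        ep = small_epochs["epochs"]
        out = eeg.preprocess_epochs(ep)
        assert out.data.shape[1:] == ep.data.shape[1:]
        assert out.n_trials <= ep.n_trials
        assert any("rereference" in s for s in out.log)
        assert any("smooth" in s for s in out.log)
        assert any("baseline" in s for s in out.log)

    def test_h5_round_trip(self, tmp_path, small_epochs):
        ep = small_epochs["epochs"]
        path = tmp_path / "epochs.h5"
        ep.save_h5(path)
        back = EpochSet.load_h5(path)
        assert back.labels == ep.labels
        assert back.lock == ep.lock
        assert np.allclose(back.data, ep.data, atol=1e-4)
        assert np.allclose(back.times, ep.times)
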