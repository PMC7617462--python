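"""Filtering, Morlet decomposition, z-scoring, band averaging and trial
rejection."""

import numpy as np
import pytest

from burstsync import preprocess as pp
from burstsync.synth import CHANNEL_ROLES, Recording

from conftest import make_recording


def sinusoid(freq: float, fs: float = 512.0, dur: float = 10.0, amp: float = 1.0) -> np.ndarray:
    return amp * np.sin(2 * np.pi * freq * np.arange(int(dur * fs)) / fs)


class TestFilter:
    def test_dc_removed(self):
        rec = make_recording(np.full(int(10 * 512), 3.0))
        out = pp.preprocess_filter(rec)
        core = out.data[0][512:-512]
        assert np.max(np.abs(core)) < 1e-6 * 3.0

    def test_passband_gain(self):
        out = pp.preprocess_filter(make_recording(sinusoid(20.0)))
        gain = out.data[0][512:-512].std() * np.sqrt(2)
        assert 0.95 <= gain <= 1.05

    def test_notch_attenuation(self):
        out = pp.preprocess_filter(make_recording(sinusoid(50.0)))
        gain = out.data[0][512:-512].std() * np.sqrt(2)
        assert -20 * np.log10(gain) >= 20.0

    def test_idempotent_on_band_limited(self):
        """Refiltering an already band-limited signal changes gain < 5%."""
        rng = np.random.default_rng(0)
        from scipy.signal import butter, sosfiltfilt

        sos = butter(4, [2, 40], btype="bandpass", fs=512, output="sos")
        x = sosfiltfilt(sos, rng.standard_normal(512 * 20))
        once = pp.preprocess_filter(make_recording(x))
        twice = pp.preprocess_filter(once)
        a = once.data[0][1024:-1024]
        b = twice.data[0][1024:-1024]
        assert abs(b.std() / a.std() - 1) < 0.05

    def test_invalid_corner_rejected(self):
        with pytest.raises(ValueError):
            pp.preprocess_filter(make_recording(sinusoid(20.0)), high=300.0)


class TestCWT:
    def test_zero_signal_zero_map(self):
        rec = make_recording(np.zeros(512 * 4))
        m = pp.cwt_amplitude(rec, "CTX", np.arange(5.0, 40.0, 5.0))
        assert np.allclose(m.values, 0.0)

    def test_ridge_location_and_linearity(self):
        freqs = pp.default_freq_grid(1, 100, 1)
        m1 = pp.cwt_amplitude(make_recording(sinusoid(20.0, amp=1.0, dur=20.0)), "CTX", freqs)
        m2 = pp.cwt_amplitude(make_recording(sinusoid(20.0, amp=2.0, dur=20.0)), "CTX", freqs)
        prof1 = m1.values[:, 512:-512].mean(axis=1)
        assert freqs[np.argmax(prof1)] == 20.0
        ridge1 = m1.values[freqs == 20.0, 512:-512].mean()
        ridge2 = m2.values[freqs == 20.0, 512:-512].mean()
        assert abs(ridge2 / ridge1 - 2.0) < 0.01

    def test_two_component_ridges(self):
        freqs = pp.default_freq_grid(1, 100, 1)
        x = sinusoid(10.0, dur=20.0) + sinusoid(70.0, dur=20.0)
        m = pp.cwt_amplitude(make_recording(x), "CTX", freqs)
        prof = m.values[:, 512:-512].mean(axis=1)
        lo = freqs[(freqs >= 2) & (freqs <= 40)]
        hi = freqs[(freqs >= 40) & (freqs <= 100)]
        peak_lo = lo[np.argmax(prof[(freqs >= 2) & (freqs <= 40)])]
        peak_hi = hi[np.argmax(prof[(freqs >= 40) & (freqs <= 100)])]
        assert abs(peak_lo - 10.0) <= 1.0
        assert abs(peak_hi - 70.0) <= 1.0

    def test_sign_invariance(self):
        x = sinusoid(15.0)
        a = pp.cwt_amplitude(make_recording(x), "CTX", np.array([15.0]))
        b = pp.cwt_amplitude(make_recording(-x), "CTX", np.array([15.0]))
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            pp.cwt_amplitude(make_recording(sinusoid(10.0)), "CTX", np.array([]))

    def test_matches_independent_wavelet_implementation(self):
        """Frequency response agrees with a PyWavelets complex-Morlet CWT
        parameterised to the same 10-cycle width (sigma_t = n/(2 pi f))."""
        pywt = pytest.importorskip("pywt")
        fs = 512.0
        t = np.arange(int(20 * fs)) / fs
        x = np.sin(2 * np.pi * 21 * t) + 0.5 * np.sin(2 * np.pi * 60 * t)
        freqs = np.arange(10.0, 81.0, 1.0)
        mine = pp.cwt_amplitude(make_recording(x), "CTX", freqs).values[:, 1024:-1024].mean(axis=1)
        bandwidth = 2 * (10 / (2 * np.pi)) ** 2
        coef, _ = pywt.cwt(x, fs / freqs, f"cmor{bandwidth}-1.0", sampling_period=1 / fs)
        ref = np.abs(coef)[:, 1024:-1024].mean(axis=1)
        np.testing.assert_allclose(mine / mine.max(), ref / ref.max(), atol=0.02)


def random_map(seed=0, nf=12, nt=400, fs=32.0):
    rng = np.random.default_rng(seed)
    return pp.TimeFrequencyMap(
        values=np.abs(rng.standard_normal((nf, nt))) + 0.5,
        freqs=np.arange(10.0, 10.0 + nf),
        times=np.arange(nt) / fs,
        fs=fs,
        channel="CTX",
    )


class TestZScore:
    def test_own_stats_standardise(self):
        m = random_map()
        st = pp.block_stats(m, edge_exclude_s=0.0)
        z = pp.zscore_block(m, st)
        assert z.z_scored
        np.testing.assert_allclose(z.values.mean(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(z.values.std(axis=1), 1.0, atol=1e-10)

    def test_per_frequency_independence(self):
        m = random_map()
        st = pp.block_stats(m, edge_exclude_s=0.0)
        shifted = random_map()
        shifted.values = shifted.values.copy()
        shifted.values[3] += 5.0
        z0 = pp.zscore_block(m, st)
        z1 = pp.zscore_block(shifted, st)
        assert np.allclose(z1.values[3] - z0.values[3], 5.0 / st.sigma[3])
        others = np.arange(len(m.freqs)) != 3
        np.testing.assert_allclose(z1.values[others], z0.values[others])

    def test_round_trip_identity(self):
        m = random_map(1)
        st = pp.block_stats(m, edge_exclude_s=0.0)
        back = pp.unzscore_block(pp.zscore_block(m, st), st)
        np.testing.assert_allclose(back.values, m.values, atol=1e-12)

    def test_percentile_occupancy(self):
        """About 25% of a white-noise z map exceeds its own 75th percentile."""
        m = random_map(2, nt=5000)
        z = pp.zscore_block(m, pp.block_stats(m, edge_exclude_s=0.0))
        thr = np.percentile(z.values, 75)
        frac = (z.values > thr).mean()
        assert abs(frac - 0.25) < 0.01


class TestBandSeries:
    def test_constant_map(self):
        m = random_map()
        m.values = np.full_like(m.values, 2.5)
        band = pp.BandDefinition("b", 11.0, 15.0)
        np.testing.assert_allclose(pp.band_series(m, band), 2.5)

    def test_single_frequency_band_is_row(self):
        m = random_map()
        band = pp.BandDefinition("one", 12.5, 13.5)
        np.testing.assert_allclose(pp.band_series(m, band), m.values[3])

    def test_band_outside_grid_rejected(self):
        with pytest.raises(ValueError):
            pp.band_series(random_map(), pp.BandDefinition("x", 200.0, 300.0))

    def test_beta_exceeds_gamma_for_beta_input(self):
        rec = make_recording(sinusoid(20.0, dur=20.0) + 0.01 * np.random.default_rng(0).standard_normal(512 * 20))
        m = pp.cwt_amplitude(rec, "CTX", pp.default_freq_grid())
        beta = pp.band_series(m, pp.BANDS["beta"])[512:-512].mean()
        gamma = pp.band_series(m, pp.BANDS["gamma"])[512:-512].mean()
        assert beta > 10 * gamma


def _rec_with_trials(x, fs=512.0):
    import pandas as pd

    n_trials = 4
    dur = len(x) / fs / n_trials
    events = pd.DataFrame(
        dict(
            trial=np.arange(n_trials),
            condition=["F0", "F1", "F2", "F0"],
            t_ready=np.arange(n_trials) * dur,
            t_steady=np.arange(n_trials) * dur + 0.2 * dur,
            t_go=np.arange(n_trials) * dur + 0.7 * dur,
            t_target=np.arange(n_trials) * dur + 0.8 * dur,
            t_relax=np.arange(n_trials) * dur + 0.9 * dur,
            t_end=(np.arange(n_trials) + 1) * dur,
        )
    )
    return Recording(data=np.vstack([x] * 5), fs=fs, roles=CHANNEL_ROLES, events=events, block=0)


class TestRejectTrials:
    def test_gaussian_block_low_rejection(self):
        rng = np.random.default_rng(3)
        flags = pp.reject_trials(_rec_with_trials(rng.standard_normal(512 * 40)))
        assert flags["keep"].mean() >= 0.75

    def test_spike_rejected_under_rule1(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(512 * 40)
        x[int(1.5 * 512 * 10)] = 30.0  # 30 SD spike inside trial 1
        flags = pp.reject_trials(_rec_with_trials(x))
        assert not flags.loc[1, "keep"]
        assert "raw_amplitude" in flags.loc[1, "reason"]

    def test_beta_burst_rejected_under_rule2_only(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(512 * 40)
        t = np.arange(512 * 40) / 512
        burst = (np.abs(t - 25.0) < 0.5) * 4.0 * np.sin(2 * np.pi * 25 * t)
        x = x + burst  # trial 2 spans seconds 20-30
        flags = pp.reject_trials(_rec_with_trials(x))
        assert not flags.loc[2, "keep"]
        assert flags.loc[2, "reason"] == "beta_amplitude"

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(512 * 40) * (1 + 0.5 * np.sin(np.arange(512 * 40) / 512))
        rec = _rec_with_trials(x)
        strict = pp.reject_trials(rec, raw_sd=2.0, band_sd=1.5)
        loose = pp.reject_trials(rec, raw_sd=6.0, band_sd=4.0)
        # raising thresholds never rejects more trials
        assert (loose["keep"] | ~strict["keep"]).all() or loose["keep"].sum() >= strict["keep"].sum()
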