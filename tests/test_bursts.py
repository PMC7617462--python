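"""Burst / no-burst detection and the control resamplings."""

import numpy as np
import pandas as pd
import pytest

from burstsync import bursts as bu


def times_for(n, fs=32.0):
    return np.arange(n) / fs


class TestThreshold:
    def test_uniform_order_statistic(self):
        rng = np.random.default_rng(0)
        s = rng.uniform(0, 1, 10**6)
        thr = bu.compute_threshold(s, 75.0)
        assert 0.748 <= thr.value <= 0.752

    def test_constant_series(self):
        thr = bu.compute_threshold(np.full(100, 2.0), 75.0)
        assert thr.value == 2.0

    def test_percentile_monotonicity(self):
        rng = np.random.default_rng(1)
        s = rng.standard_normal(1000)
        assert bu.compute_threshold(s, 50.0).value <= bu.compute_threshold(s, 75.0).value

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            bu.compute_threshold(np.array([]), 75.0)


class TestDetectBursts:
    def test_constant_series_no_bursts(self):
        s = np.full(1000, 1.0)
        thr = bu.compute_threshold(s, 75.0)
        assert len(bu.detect_bursts(s, times_for(1000), thr)) == 0

    @pytest.mark.parametrize("dur_ms,expected", [(150, 1), (80, 0)])
    def test_injected_epoch_duration_rule(self, dur_ms, expected):
        """A 150 ms supra-threshold epoch is one burst; an 80 ms epoch fails
        the 100 ms minimum."""
        fs = 32.0
        rng = np.random.default_rng(2)
        s = rng.uniform(0, 0.5, 2000)
        i0 = 640
        n = int(round(dur_ms / 1000 * fs))
        s[i0 : i0 + n] = 2.0
        thr = bu.BurstThreshold(level=75.0, value=1.0)
        df = bu.detect_bursts(s, times_for(2000, fs), thr, min_duration=0.1)
        assert len(df) == expected
        if expected:
            assert abs(df.iloc[0]["onset_s"] - i0 / fs) <= 1.0 / fs

    def test_min_duration_config_error(self):
        s = np.ones(100)
        thr = bu.BurstThreshold(75.0, 0.5)
        with pytest.raises(ValueError):
            bu.detect_bursts(s, times_for(100, fs=8.0), thr, min_duration=0.1)

    def test_monotone_rescale_invariance(self):
        """Detection depends only on ranks: a strictly monotone transform of
        the series yields identical burst intervals."""
        rng = np.random.default_rng(3)
        s = np.abs(np.convolve(rng.standard_normal(3000), np.hanning(20), "same"))
        t = times_for(3000)
        a = bu.detect_bursts(s, t, bu.compute_threshold(s, 75.0))
        s2 = np.exp(3 * s)
        b = bu.detect_bursts(s2, t, bu.compute_threshold(s2, 75.0))
        pd.testing.assert_frame_equal(a[["onset_s", "offset_s"]], b[["onset_s", "offset_s"]])

    def test_bursts_disjoint_sorted(self):
        rng = np.random.default_rng(4)
        s = np.abs(np.convolve(rng.standard_normal(5000), np.hanning(15), "same"))
        t = times_for(5000)
        df = bu.detect_bursts(s, t, bu.compute_threshold(s, 75.0))
        on = df["onset_s"].to_numpy()
        off = df["offset_s"].to_numpy()
        assert (np.diff(on) > 0).all()
        assert (on[1:] >= off[:-1]).all()


class TestDetectNoburst:
    def test_all_above_median_no_epochs(self):
        s = np.ones(1000) * 5
        thr = bu.BurstThreshold(50.0, 1.0)
        df = bu.detect_noburst(s, times_for(1000), thr, bursts=pd.DataFrame())
        assert len(df) == 0

    def test_guard_excludes_post_burst_quiet(self):
        """A 1 s sub-median run preceded by a burst ending 0.3 s earlier is
        excluded by the 0.5 s guard."""
        fs = 32.0
        s = np.ones(int(10 * fs))
        s[int(3 * fs) : int(4 * fs)] = 0.0  # quiet run at 3-4 s
        thr50 = bu.BurstThreshold(50.0, 0.5)
        bursts = pd.DataFrame([dict(onset_s=2.5, offset_s=2.7)])
        df = bu.detect_noburst(s, times_for(len(s), fs), thr50, bursts)
        assert len(df) == 0
        far = pd.DataFrame([dict(onset_s=1.0, offset_s=1.2)])
        df2 = bu.detect_noburst(s, times_for(len(s), fs), thr50, far)
        assert len(df2) == 1

    def test_matches_brute_force_scan(self):
        """Epoch set equals an independent O(n) reference scan."""
        fs = 32.0
        rng = np.random.default_rng(5)
        s = np.abs(np.convolve(rng.standard_normal(4000), np.hanning(25), "same"))
        t = times_for(4000, fs)
        thr75 = bu.compute_threshold(s, 75.0)
        thr50 = bu.compute_threshold(s, 50.0)
        bursts = bu.detect_bursts(s, t, thr75)
        got = bu.detect_noburst(s, t, thr50, bursts)

        # reference: explicit sample scan
        min_n = int(np.ceil(0.5 * fs))
        below = s < thr50.value
        runs = []
        i = 0
        while i < len(s):
            if below[i]:
                j = i
                while j < len(s) and below[j]:
                    j += 1
                if j - i >= min_n:
                    runs.append((t[i], t[j - 1] + 1 / fs))
                i = j
            else:
                i += 1
        kept = [
            (a, b)
            for a, b in runs
            if not ((bursts["offset_s"] > a - 0.5) & (bursts["onset_s"] < a)).any()
        ]
        assert len(got) == len(kept)
        np.testing.assert_allclose(got["onset_s"].to_numpy(), [a for a, _ in kept])

    def test_no_burst_overlaps_epoch(self, participant):
        """Pipeline-level invariant on generator output."""
        from burstsync import preprocess as pp

        _, recs, _ = participant
        rec = recs[0]
        filt = pp.preprocess_filter(rec, notch=None)
        m = pp.cwt_amplitude(filt, "CTX", np.arange(15.0, 36.0, 2.0), decim=16)
        z = pp.zscore_block(m, pp.block_stats(m))
        beta = pp.band_series(z, pp.BANDS["beta"])
        bursts = bu.detect_bursts(beta, z.times, bu.compute_threshold(beta, 75.0), events=rec.events)
        nob = bu.detect_noburst(beta, z.times, bu.compute_threshold(beta, 50.0), bursts,
                                events=rec.events)
        for e in nob.itertuples():
            overlap = (bursts["onset_s"] < e.offset_s) & (bursts["offset_s"] > e.onset_s)
            assert not overlap.any()


class TestMetricsAndControls:
    def _toy_bursts(self, durs_ms, conds=None, amps=None):
        n = len(durs_ms)
        return pd.DataFrame(
            dict(
                onset_s=np.arange(n, dtype=float),
                offset_s=np.arange(n) + np.array(durs_ms) / 1000.0,
                duration_s=np.array(durs_ms) / 1000.0,
                peak_amp=amps if amps is not None else np.linspace(1, 2, n),
                mean_amp=amps if amps is not None else np.linspace(1, 2, n),
                trial=np.arange(n),
                condition=conds if conds is not None else ["F0"] * n,
                phase=["steady"] * n,
                block=[0] * n,
                band=["beta"] * n,
                channel=["CTX"] * n,
            )
        )

    def test_metrics_empty(self):
        out = bu.burst_metrics(self._toy_bursts([])[0:0])
        assert len(out) == 0

    def test_metrics_recover_condition_ordering(self, participant):
        """Generator gains F0 > F1 ~ F2 appear in the detected mean amplitude."""
        from burstsync import preprocess as pp

        _, recs, _ = participant
        frames = []
        for rec in recs:
            filt = pp.preprocess_filter(rec, notch=None)
            m = pp.cwt_amplitude(filt, "CTX", np.arange(15.0, 36.0, 2.0), decim=16)
            z = pp.zscore_block(m, pp.block_stats(m))
            beta = pp.band_series(z, pp.BANDS["beta"])
            frames.append(bu.detect_bursts(beta, z.times, bu.compute_threshold(beta, 75.0),
                                           events=rec.events))
        met = bu.burst_metrics(pd.concat(frames, ignore_index=True))
        amp = met.set_index("condition")["mean_amp"]
        assert amp["F0"] > min(amp["F1"], amp["F2"]) - 0.15

    def test_median_split_example(self):
        low, high = bu.median_split(self._toy_bursts([100, 150, 200, 250]), "duration_s")
        assert sorted(low["duration_s"] * 1000) == [100, 150]
        assert sorted(high["duration_s"] * 1000) == [200, 250]

    def test_median_split_ties_and_sizes(self):
        df = self._toy_bursts([100] * 5, amps=np.ones(5))
        low, high = bu.median_split(df, "peak_amp")
        assert len(low) == 3 and len(high) == 2

    def test_median_split_order_property(self):
        rng = np.random.default_rng(6)
        df = self._toy_bursts((rng.uniform(100, 400, 21)).tolist())
        low, high = bu.median_split(df, "duration_s")
        assert low["duration_s"].max() <= high["duration_s"].min()
        assert len(low) + len(high) == len(df)

    def test_subsample_full_set(self):
        df = self._toy_bursts([150] * 10)
        sets = bu.subsample_bursts(df, n=10, reps=3, seed=0)
        assert all(len(s) == 10 for s in sets)

    def test_subsample_shapes_and_determinism(self):
        df = pd.concat(
            [self._toy_bursts([150] * 120, conds=[c] * 120) for c in ("F0", "F1", "F2")],
            ignore_index=True,
        )
        sets1 = bu.subsample_bursts(df, n=100, reps=5, seed=1)
        sets2 = bu.subsample_bursts(df, n=100, reps=5, seed=1)
        assert len(sets1) == 5
        for s1, s2 in zip(sets1, sets2):
            assert s1.groupby("condition").size().eq(100).all()
            pd.testing.assert_frame_equal(s1, s2)

    def test_subsample_insufficient_names_condition(self):
        df = self._toy_bursts([150] * 5, conds=["F1"] * 5)
        with pytest.raises(ValueError, match="F1"):
            bu.subsample_bursts(df, n=100)

    def test_subsample_coverage(self):
        """Over many repetitions, sampling 100 of 200 covers nearly the pool."""
        df = self._toy_bursts([150] * 200)
        sets = bu.subsample_bursts(df, n=100, reps=50, seed=2)
        seen = set()
        for s in sets:
            seen.update(s["onset_s"])
        assert len(seen) > 0.99 * 200
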