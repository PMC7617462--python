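"""Filtering, Morlet time-frequency decomposition, block z-scoring,
band averaging and automatic trial rejection.

The processing chain mirrors common sensorimotor-EEG practice: a 1 Hz
high-pass and 100 Hz low-pass (second-order, two-pass Butterworth each)
plus a 50 Hz notch; a 10-cycle complex Morlet CWT on a 1-100 Hz grid in
1 Hz steps; per-frequency z-scoring over each block; and a two-rule
amplitude-based trial rejection (6 SD on the raw source series, 4 SD on
its 15-35 Hz band-passed amplitude).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal as sps
from mne.time_frequency import tfr_array_morlet

from .synth import Recording

__all__ = [
    "BandDefinition",
    "BANDS",
    "TimeFrequencyMap",
    "BlockStats",
    "preprocess_filter",
    "cwt_amplitude",
    "block_stats",
    "zscore_block",
    "band_series",
    "reject_trials",
    "default_freq_grid",
]


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ValueError("band edges must satisfy 0 < low < high")


BANDS = {
    "alpha": BandDefinition("alpha", 8.0, 12.0),
    "beta": BandDefinition("beta", 15.0, 35.0),
    "gamma": BandDefinition("gamma", 55.0, 90.0),
}


def default_freq_grid(low: float = 1.0, high: float = 100.0, step: float = 1.0) -> np.ndarray:
    return np.arange(low, high + 0.5 * step, step)


@dataclass
class TimeFrequencyMap:
    """Amplitude (or z) values on a frequency x time grid for one channel."""

    values: np.ndarray  # (n_freqs, n_times)
    freqs: np.ndarray  # Hz, strictly increasing
    times: np.ndarray  # seconds, strictly increasing
    fs: float  # map sampling rate (after decimation)
    channel: str
    z_scored: bool = False
    block: int | None = None

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.freqs), len(self.times)):
            raise ValueError("values shape must be (n_freqs, n_times)")

    def band_rows(self, band: BandDefinition) -> np.ndarray:
        sel = (self.freqs >= band.low) & (self.freqs <= band.high)
        if not sel.any():
            raise ValueError(f"band {band.name} outside the frequency grid")
        return sel


@dataclass
class BlockStats:
    """Per-frequency mean and SD over one block (the z-score parameters)."""

    mu: np.ndarray
    sigma: np.ndarray
    freqs: np.ndarray
    block: int | None = None

    def __post_init__(self) -> None:
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be > 0 at every frequency")


def preprocess_filter(
    rec: Recording,
    low: float = 1.0,
    high: float = 100.0,
    notch: float | None = 50.0,
    notch_q: float = 35.0,
) -> Recording:
    """Zero-phase band limiting: two-pass 2nd-order Butterworth high- and
    low-pass plus an IIR notch. Returns a new Recording of the same shape."""
    nyq = rec.fs / 2
    if not (0 < low < high < nyq):
        raise ValueError("corner frequencies must satisfy 0 < low < high < Nyquist")
    sos_hp = sps.butter(2, low, btype="highpass", fs=rec.fs, output="sos")
    sos_lp = sps.butter(2, high, btype="lowpass", fs=rec.fs, output="sos")
    x = sps.sosfiltfilt(sos_hp, rec.data, axis=-1)
    x = sps.sosfiltfilt(sos_lp, x, axis=-1)
    if notch is not None:
        if notch >= nyq:
            raise ValueError("notch frequency must be below Nyquist")
        b, a = sps.iirnotch(notch, notch_q, fs=rec.fs)
        x = sps.filtfilt(b, a, x, axis=-1)
    return replace(rec, data=x)


def cwt_amplitude(
    rec: Recording,
    channel: str,
    freqs: np.ndarray | None = None,
    n_cycles: float = 10.0,
    decim: int = 1,
) -> TimeFrequencyMap:
    """10-cycle complex Morlet CWT amplitude of one channel.

    ``decim`` keeps every decim-th time sample; at 10 cycles the Morlet
    envelope bandwidth (f / n_cycles) is far below the decimated Nyquist
    for the decimations used here.
    """
    freqs = default_freq_grid() if freqs is None else np.asarray(freqs, dtype=float)
    if freqs.size == 0:
        raise ValueError("frequency grid is empty")
    if freqs.max() >= rec.fs / 2:
        raise ValueError("frequency grid exceeds Nyquist")
    x = rec.channel(channel)[np.newaxis, np.newaxis, :]
    out = tfr_array_morlet(
        x, sfreq=rec.fs, freqs=freqs, n_cycles=n_cycles, output="complex", decim=decim, verbose="error"
    )
    amp = np.abs(out[0, 0])
    times = np.arange(rec.n_samples)[::decim] / rec.fs
    return TimeFrequencyMap(
        values=amp, freqs=freqs, times=times, fs=rec.fs / decim, channel=channel, block=rec.block
    )


def block_stats(tfmap: TimeFrequencyMap, edge_exclude_s: float = 0.5) -> BlockStats:
    """Per-frequency mean/SD over the block, excluding the first and last
    ``edge_exclude_s`` seconds (filter and wavelet transients)."""
    n_edge = int(round(edge_exclude_s * tfmap.fs))
    core = tfmap.values[:, n_edge : tfmap.values.shape[1] - n_edge] if n_edge else tfmap.values
    if core.shape[1] < 2:
        raise ValueError("block too short for the requested edge exclusion")
    mu = core.mean(axis=1)
    sigma = core.std(axis=1)
    if np.any(sigma <= 0):
        raise ValueError("degenerate block: zero variance at some frequency")
    return BlockStats(mu=mu, sigma=sigma, freqs=tfmap.freqs, block=tfmap.block)


def zscore_block(tfmap: TimeFrequencyMap, stats: BlockStats) -> TimeFrequencyMap:
    """Z = (x - mu) / sigma per frequency row."""
    if not np.array_equal(stats.freqs, tfmap.freqs):
        raise ValueError("stats computed on a different frequency grid")
    z = (tfmap.values - stats.mu[:, None]) / stats.sigma[:, None]
    return replace(tfmap, values=z, z_scored=True)


def unzscore_block(tfmap: TimeFrequencyMap, stats: BlockStats) -> TimeFrequencyMap:
    """Inverse of :func:`zscore_block` (round-trip identity)."""
    x = tfmap.values * stats.sigma[:, None] + stats.mu[:, None]
    return replace(tfmap, values=x, z_scored=False)


def band_series(tfmap: TimeFrequencyMap, band: BandDefinition) -> np.ndarray:
    """Arithmetic mean over in-band frequency rows at each time point."""
    return tfmap.values[tfmap.band_rows(band)].mean(axis=0)


def reject_trials(
    rec: Recording,
    beta_band: BandDefinition = BANDS["beta"],
    raw_sd: float = 6.0,
    band_sd: float = 4.0,
) -> pd.DataFrame:
    """Two sequential amplitude criteria per trial.

    Rule 1: any sample of |source| above mean(|source|) + raw_sd * SD(source)
    (block statistics).  Rule 2: any sample of the 15-35 Hz band-passed
    amplitude above the block mean amplitude + band_sd * SD of the filtered
    signal.  The SD is that of the (zero-mean) signal itself, not of its
    rectified amplitude, so genuine oscillatory bursts -- which live in the
    upper quartile by construction -- do not trip an artifact rule meant
    for movement/muscle contamination.  Returns one row per trial with a
    keep flag and reasons.
    """
    if len(rec.events) == 0:
        raise ValueError("recording has no trials")
    x = rec.channel("CTX")
    a = np.abs(x)
    thr1 = a.mean() + raw_sd * x.std()
    sos = sps.butter(2, [beta_band.low, beta_band.high], btype="bandpass", fs=rec.fs, output="sos")
    bp = sps.sosfiltfilt(sos, x)
    e = np.abs(bp)
    thr2 = e.mean() + band_sd * bp.std()
    rows = []
    for row in rec.events.itertuples():
        i0, i1 = int(row.t_ready * rec.fs), int(row.t_end * rec.fs)
        if i1 <= i0:
            raise ValueError(f"trial {row.trial} is empty")
        r1 = bool(np.any(a[i0:i1] > thr1))
        r2 = bool(np.any(e[i0:i1] > thr2))
        reasons = [r for r, f in (("raw_amplitude", r1), ("beta_amplitude", r2)) if f]
        rows.append(dict(trial=row.trial, block=rec.block, keep=not (r1 or r2), reason=";".join(reasons)))
    return pd.DataFrame(rows)
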