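"""Sliding-window phase-locking value (PLV) between cortex and muscles
(CMC) and between muscle pairs (IMC).

Per analysis frequency, each signal is band-pass filtered (zero-phase
Butterworth, default +/-2 Hz around the centre) and Hilbert-transformed;
the PLV at time t is the resultant length of the phase difference over a
centred 250 ms window.  Maps are built on the continuous block and then
epoched around burst / no-burst onsets; the CMC null keeps the cortical
epochs fixed and shuffles the EMG epoch assignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .synth import Recording, EMG_ROLES

__all__ = [
    "PhaseSeries",
    "PLVMap",
    "instantaneous_phase",
    "plv_sliding",
    "plv_timefreq",
    "align_epochs",
    "epoch_phase",
    "plv_from_phase_epochs",
    "cmc_null_shuffle",
    "assemble_pairs",
    "cmc_pairs",
    "imc_pairs",
]


@dataclass
class PhaseSeries:
    phase: np.ndarray  # radians in (-pi, pi]
    fs: float
    centre: float
    bandwidth: float
    channel: str


@dataclass
class PLVMap:
    """PLV values on a frequency x time grid for one channel pair.

    Edge samples where the sliding window is incomplete are NaN.
    """

    values: np.ndarray  # (n_freqs, n_times), in [0, 1] or NaN
    freqs: np.ndarray
    times: np.ndarray
    fs: float
    pair: tuple[str, str]
    window_s: float


def instantaneous_phase(
    rec: Recording, channel: str, centre: float, bandwidth: float = 4.0, order: int = 2
) -> PhaseSeries:
    """Phase of the analytic signal of the band-passed channel."""
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    lo = max(centre - bandwidth / 2, 0.1)
    hi = min(centre + bandwidth / 2, 0.999 * rec.fs / 2)
    if hi <= lo:
        raise ValueError("band outside the valid range")
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=rec.fs, output="sos")
    x = sps.sosfiltfilt(sos, rec.channel(channel))
    from scipy.fft import next_fast_len

    phase = np.angle(sps.hilbert(x, N=next_fast_len(len(x)))[: len(x)])
    return PhaseSeries(phase=phase, fs=rec.fs, centre=centre, bandwidth=hi - lo, channel=channel)


def plv_sliding(a: PhaseSeries, b: PhaseSeries, window_s: float = 0.25) -> np.ndarray:
    """PLV(t) = | mean over a centred window of exp(i (phi_a - phi_b)) |.

    Incomplete edge windows are NaN.
    """
    if len(a.phase) != len(b.phase) or a.fs != b.fs:
        raise ValueError("phase series must share length and sampling rate")
    win = int(round(window_s * a.fs))
    if win < 2:
        raise ValueError("window must span at least 2 samples")
    z = np.exp(1j * (a.phase - b.phase))
    plv = np.abs(uniform_filter1d(z.real, win, mode="nearest")
                 + 1j * uniform_filter1d(z.imag, win, mode="nearest"))
    half = win // 2
    plv[:half] = np.nan
    plv[len(plv) - (win - 1 - half):] = np.nan
    return np.minimum(plv, 1.0)


def plv_timefreq(
    rec: Recording,
    pair: tuple[str, str],
    freqs: np.ndarray,
    bandwidth: float = 4.0,
    window_s: float = 0.25,
    decim: int = 1,
) -> PLVMap:
    """Stack sliding-window PLV series over a frequency grid."""
    freqs = np.asarray(freqs, dtype=float)
    rows = []
    for f in freqs:
        pa = instantaneous_phase(rec, pair[0], f, bandwidth)
        pb = instantaneous_phase(rec, pair[1], f, bandwidth)
        rows.append(plv_sliding(pa, pb, window_s)[::decim])
    values = np.vstack(rows)
    times = np.arange(rec.n_samples)[::decim] / rec.fs
    return PLVMap(values=values, freqs=freqs, times=times, fs=rec.fs / decim,
                  pair=tuple(pair), window_s=window_s)


def align_epochs(
    values: np.ndarray,
    times: np.ndarray,
    event_times: np.ndarray,
    window: tuple[float, float] = (-0.5, 1.0),
) -> tuple[np.ndarray, np.ndarray, int]:
    """Mean map across epochs around each event onset.

    Epochs that fall outside the valid (non-NaN) region of the map are
    dropped. Returns (mean_map, epoch_time_axis, n_epochs_used).
    """
    if window[1] <= window[0]:
        raise ValueError("epoch window must be ordered")
    fs = 1.0 / float(np.mean(np.diff(times)))
    i_lo = int(round(window[0] * fs))
    i_hi = int(round(window[1] * fs))
    n_t = i_hi - i_lo
    t0 = float(times[0])
    epochs = []
    for ev in np.atleast_1d(event_times):
        c = int(round((ev - t0) * fs))
        a, b = c + i_lo, c + i_lo + n_t
        if a < 0 or b > values.shape[-1]:
            continue
        seg = values[..., a:b]
        if np.isnan(seg).any():
            continue
        epochs.append(seg)
    if not epochs:
        raise ValueError("no usable epochs within the valid map region")
    rel_t = (np.arange(n_t) + i_lo) / fs
    return np.mean(epochs, axis=0), rel_t, len(epochs)


def epoch_phase(
    phase: np.ndarray, fs: float, event_times: np.ndarray, window: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Slice a phase series (n_freqs x n_samples) into epochs around events.

    Returns (epochs: n_events x n_freqs x n_times, relative time axis).
    Events whose window leaves the recording are dropped.
    """
    i_lo = int(round(window[0] * fs))
    n_t = int(round(window[1] * fs)) - i_lo
    segs = []
    for ev in np.atleast_1d(event_times):
        c = int(round(ev * fs))
        a = c + i_lo
        if a < 0 or a + n_t > phase.shape[-1]:
            continue
        segs.append(phase[..., a : a + n_t])
    if not segs:
        raise ValueError("no usable epochs")
    rel_t = (np.arange(n_t) + i_lo) / fs
    return np.stack(segs), rel_t


def plv_from_phase_epochs(
    ep_a: np.ndarray, ep_b: np.ndarray, fs: float, window_s: float = 0.25
) -> np.ndarray:
    """Sliding-window PLV within each epoch pair, then mean across epochs.

    ``ep_a``/``ep_b``: (n_epochs, n_freqs, n_times). Edge windows are NaN
    and excluded columnwise via the shared mask.
    """
    if ep_a.shape != ep_b.shape:
        raise ValueError("epoch arrays must share shape")
    win = int(round(window_s * fs))
    if win < 2:
        raise ValueError("window must span at least 2 samples")
    z = np.exp(1j * (ep_a - ep_b))
    sm = uniform_filter1d(z.real, win, axis=-1, mode="nearest") + 1j * uniform_filter1d(
        z.imag, win, axis=-1, mode="nearest"
    )
    plv = np.minimum(np.abs(sm), 1.0)
    half = win // 2
    plv[..., :half] = np.nan
    plv[..., plv.shape[-1] - (win - 1 - half):] = np.nan
    return plv.mean(axis=0)


def cmc_null_shuffle(
    ep_ctx: np.ndarray,
    ep_emg: np.ndarray,
    fs: float,
    seed: int,
    n_shuffles: int = 10,
    window_s: float = 0.25,
) -> np.ndarray:
    """Surrogate CMC: cortical epochs fixed, EMG epoch assignment permuted.

    Returns the mean surrogate map over ``n_shuffles`` derangement-style
    permutations (identity permutations are re-drawn when possible).
    """
    n_ep = ep_ctx.shape[0]
    if n_ep < 2:
        raise ValueError("need at least 2 epochs to shuffle")
    rng = np.random.default_rng(seed)
    maps = []
    for _ in range(n_shuffles):
        perm = rng.permutation(n_ep)
        if np.all(perm == np.arange(n_ep)):
            perm = np.roll(perm, 1)
        maps.append(plv_from_phase_epochs(ep_ctx, ep_emg[perm], fs, window_s))
    return np.mean(maps, axis=0)


def cmc_pairs(cortex: str = "CTX") -> list[tuple[str, str]]:
    return [(cortex, m) for m in EMG_ROLES]


def imc_pairs() -> list[tuple[str, str]]:
    return list(combinations(EMG_ROLES, 2))


def assemble_pairs(maps: dict) -> np.ndarray:
    """Arithmetic mean of per-pair maps (all on identical grids)."""
    vals = list(maps.values())
    shape = vals[0].shape
    if any(v.shape != shape for v in vals):
        raise ValueError("pair maps must share the grid")
    return np.mean(vals, axis=0)
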