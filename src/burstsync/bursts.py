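"""Beta/gamma burst and no-burst detection with condition annotation,
per-condition burst metrics, and the control resamplings (median split,
equal-count subsampling).

A burst is a maximal run of band-amplitude samples strictly above the
75th percentile of the whole block (one threshold pooled across all
force conditions) lasting at least 100 ms.  A no-burst epoch is a run
below the 50th percentile lasting at least 500 ms, with no burst ending
in the preceding 500 ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BurstThreshold",
    "compute_threshold",
    "detect_bursts",
    "detect_noburst",
    "annotate_events",
    "burst_metrics",
    "median_split",
    "subsample_bursts",
]

BURST_COLUMNS = [
    "onset_s", "offset_s", "duration_s", "peak_amp", "mean_amp",
    "trial", "condition", "phase", "block", "band", "channel",
]


@dataclass(frozen=True)
class BurstThreshold:
    """Percentile threshold of a band-amplitude series over one block."""

    level: float  # percentile level, e.g. 75
    value: float  # threshold in band-amplitude units
    block: int | None = None
    band: str = "beta"


def compute_threshold(
    series: np.ndarray, level: float = 75.0, block: int | None = None, band: str = "beta"
) -> BurstThreshold:
    """Empirical percentile of the pooled block series (all conditions)."""
    series = np.asarray(series)
    if series.size == 0:
        raise ValueError("empty series")
    return BurstThreshold(level=level, value=float(np.percentile(series, level)), block=block, band=band)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, stop) index pairs of maximal True runs."""
    if mask.size == 0:
        return []
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        stops = np.r_[stops, mask.size]
    return list(zip(starts, stops))


def detect_bursts(
    series: np.ndarray,
    times: np.ndarray,
    thr: BurstThreshold,
    min_duration: float = 0.1,
    events: pd.DataFrame | None = None,
    channel: str = "CTX",
) -> pd.DataFrame:
    """Maximal supra-threshold runs of at least ``min_duration`` seconds.

    ``times`` is the map time axis (uniform). Each burst is annotated with
    the trial/condition/phase at its onset sample when ``events`` is given.
    Duration is counted as n_samples * dt, so a run must span
    ceil(min_duration * fs_map) samples.
    """
    series = np.asarray(series)
    fs = 1.0 / float(np.mean(np.diff(times)))
    min_n = int(np.ceil(min_duration * fs - 1e-9))
    if min_n < 2:
        raise ValueError("min_duration shorter than 2 samples of the map grid")
    rows = []
    for a, b in _runs(series > thr.value):
        if b - a < min_n:
            continue
        seg = series[a:b]
        rows.append(
            dict(
                onset_s=float(times[a]),
                offset_s=float(times[b - 1] + 1.0 / fs),
                duration_s=(b - a) / fs,
                peak_amp=float(seg.max()),
                mean_amp=float(seg.mean()),
                block=thr.block,
                band=thr.band,
                channel=channel,
            )
        )
    df = pd.DataFrame(rows, columns=[c for c in BURST_COLUMNS if c not in ("trial", "condition", "phase")])
    df = annotate_events(df, events)
    return df[BURST_COLUMNS]


def detect_noburst(
    series: np.ndarray,
    times: np.ndarray,
    thr50: BurstThreshold,
    bursts: pd.DataFrame,
    min_duration: float = 0.5,
    guard: float = 0.5,
    events: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Sub-median runs >= min_duration with no burst ending within ``guard``
    seconds before the run onset. Restricted to Steady phases when events
    are given."""
    series = np.asarray(series)
    fs = 1.0 / float(np.mean(np.diff(times)))
    min_n = int(np.ceil(min_duration * fs - 1e-9))
    burst_offsets = bursts["offset_s"].to_numpy() if len(bursts) else np.empty(0)
    burst_onsets = bursts["onset_s"].to_numpy() if len(bursts) else np.empty(0)
    rows = []
    for a, b in _runs(series < thr50.value):
        if b - a < min_n:
            continue
        onset = float(times[a])
        # guard: no burst overlapping [onset - guard, onset)
        if len(burst_offsets) and np.any((burst_offsets > onset - guard) & (burst_onsets < onset)):
            continue
        rows.append(
            dict(onset_s=onset, offset_s=float(times[b - 1] + 1.0 / fs), duration_s=(b - a) / fs,
                 block=thr50.block)
        )
    df = pd.DataFrame(rows, columns=["onset_s", "offset_s", "duration_s", "block"])
    df = annotate_events(df, events)
    if events is not None and len(df):
        df = df[df["phase"] == "steady"].reset_index(drop=True)
    return df


def annotate_events(df: pd.DataFrame, events: pd.DataFrame | None) -> pd.DataFrame:
    """Attach trial, condition and phase labels by each row's onset time."""
    df = df.copy()
    if events is None or len(df) == 0:
        df["trial"] = pd.Series(dtype="Int64") if len(df) == 0 else pd.NA
        df["condition"] = pd.Series(dtype=object) if len(df) == 0 else None
        df["phase"] = pd.Series(dtype=object) if len(df) == 0 else None
        return df
    trials = np.full(len(df), -1)
    conds = np.full(len(df), None, dtype=object)
    phases = np.full(len(df), None, dtype=object)
    onsets = df["onset_s"].to_numpy()
    for row in events.itertuples():
        inside = (onsets >= row.t_ready) & (onsets < row.t_end)
        trials[inside] = row.trial
        conds[inside] = row.condition
        ph = np.full(int(inside.sum()), "ready", dtype=object)
        rel = onsets[inside]
        ph[rel >= row.t_steady] = "steady"
        ph[rel >= row.t_go] = "reach"
        ph[rel >= row.t_relax] = "relax"
        phases[inside] = ph
    df["trial"] = trials
    df["condition"] = conds
    df["phase"] = phases
    return df


def burst_metrics(bursts: pd.DataFrame, steady_only: bool = True) -> pd.DataFrame:
    """Per-condition burst count, mean amplitude, mean duration, and rate
    proxy (count; rate per second requires the steady time, supplied by the
    pipeline)."""
    df = bursts
    if steady_only and len(df):
        df = df[df["phase"] == "steady"]
    if len(df) == 0:
        return pd.DataFrame(columns=["condition", "count", "mean_amp", "mean_duration_s"])
    g = df.groupby("condition")
    out = g.agg(count=("onset_s", "size"), mean_amp=("mean_amp", "mean"),
                mean_duration_s=("duration_s", "mean")).reset_index()
    return out


def median_split(bursts: pd.DataFrame, key: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split at the median of ``key`` (stable order; low half gets
    ceil(n/2), so ties at the median go low first)."""
    if key not in ("peak_amp", "mean_amp", "duration_s"):
        raise ValueError("key must be an amplitude or duration column")
    n = len(bursts)
    if n < 2:
        raise ValueError("need at least 2 bursts for a median split")
    order = np.argsort(bursts[key].to_numpy(), kind="stable")
    k = (n + 1) // 2
    low = bursts.iloc[order[:k]]
    high = bursts.iloc[order[k:]]
    return low, high


def subsample_bursts(
    bursts: pd.DataFrame, n: int = 100, reps: int = 100, seed: int = 0
) -> list[pd.DataFrame]:
    """``reps`` random subsets of ``n`` bursts per condition, sampled
    without replacement within each repetition."""
    rng = np.random.default_rng(seed)
    counts = bursts.groupby("condition").size()
    short = counts[counts < n]
    if len(short):
        msg = ", ".join(f"{c}: {v} < {n}" for c, v in short.items())
        raise ValueError(f"insufficient bursts for subsampling ({msg})")
    out = []
    for _ in range(reps):
        parts = []
        for cond, grp in bursts.groupby("condition"):
            idx = rng.choice(len(grp), size=n, replace=False)
            parts.append(grp.iloc[np.sort(idx)])
        out.append(pd.concat(parts, ignore_index=True))
    return out
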