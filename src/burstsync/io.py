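"""File I/O: EDF signal files, delimited event / ground-truth / burst
tables, and an HDF5 container for time-frequency and PLV maps.

EDF writing is implemented here directly (the format is a small
fixed-layout 16-bit standard); reading goes through MNE, which also
serves as the round-trip check in the test suite.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .synth import Recording, CHANNEL_ROLES

__all__ = ["write_edf", "read_edf", "write_events", "read_events", "save_map", "load_map"]


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def write_edf(path: str | Path, rec: Recording, patient: str = "X", recording_id: str = "burstsync") -> None:
    """Write a Recording as 16-bit EDF with 1 s data records.

    Requires an integer sampling rate; the signal is trimmed to whole
    seconds (EDF stores fixed-size records).
    """
    fs = int(round(rec.fs))
    if abs(fs - rec.fs) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_ch = rec.data.shape[0]
    n_rec = rec.data.shape[1] // fs
    if n_rec == 0:
        raise ValueError("recording shorter than one EDF record (1 s)")
    data = rec.data[:, : n_rec * fs]

    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    span = phys_max - phys_min
    phys_min = phys_min - 0.01 * span - 1e-6
    phys_max = phys_max + 0.01 * span + 1e-6
    dig_min, dig_max = -32768, 32767

    now = _dt.datetime(2000, 1, 1)
    header = b"".join(
        [
            _pad("0", 8),
            _pad(patient, 80),
            _pad(recording_id, 80),
            _pad(now.strftime("%d.%m.%y"), 8),
            _pad(now.strftime("%H.%M.%S"), 8),
            _pad(str(256 * (n_ch + 1)), 8),
            _pad("", 44),
            _pad(str(n_rec), 8),
            _pad("1", 8),  # record duration, seconds
            _pad(str(n_ch), 4),
        ]
    )
    fields = [
        [(_pad(lbl, 16)) for lbl in rec.roles],  # label
        [(_pad("", 80)) for _ in range(n_ch)],  # transducer
        [(_pad("au", 8)) for _ in range(n_ch)],  # physical dimension
        [(_pad(f"{v:.6g}", 8)) for v in phys_min],
        [(_pad(f"{v:.6g}", 8)) for v in phys_max],
        [(_pad(str(dig_min), 8)) for _ in range(n_ch)],
        [(_pad(str(dig_max), 8)) for _ in range(n_ch)],
        [(_pad("", 80)) for _ in range(n_ch)],  # prefiltering
        [(_pad(str(fs), 8)) for _ in range(n_ch)],
        [(_pad("", 32)) for _ in range(n_ch)],  # reserved
    ]
    header += b"".join(b"".join(f) for f in fields)

    gain = (phys_max - phys_min) / (dig_max - dig_min)
    digital = np.empty((n_ch, n_rec * fs), dtype="<i2")
    for c in range(n_ch):
        digital[c] = np.round((data[c] - phys_min[c]) / gain[c] + dig_min).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            fh.write(digital[:, r * fs : (r + 1) * fs].tobytes())


def read_edf(path: str | Path, events: pd.DataFrame | None = None, block: int = 0) -> Recording:
    """Read an EDF file back into a Recording via MNE."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data()
    roles = tuple(raw.ch_names)
    return Recording(
        data=data, fs=float(raw.info["sfreq"]), roles=roles,
        events=events if events is not None else pd.DataFrame(), block=block,
    )


def write_events(path: str | Path, schedule_df: pd.DataFrame) -> None:
    """Long-format event table: trial, block, condition, phase, onset_s."""
    rows = []
    phase_cols = [("ready", "t_ready"), ("steady", "t_steady"), ("reach", "t_go"),
                  ("target", "t_target"), ("relax", "t_relax")]
    for row in schedule_df.itertuples():
        for phase, col in phase_cols:
            rows.append(dict(trial=row.trial, block=row.block, condition=row.condition,
                             phase=phase, onset_s=getattr(row, col)))
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    """Inverse of :func:`write_events`: back to one row per trial."""
    long = pd.read_csv(path, sep="\t")
    wide = long.pivot_table(index=["trial", "block", "condition"], columns="phase",
                            values="onset_s").reset_index()
    wide = wide.rename(columns={"ready": "t_ready", "steady": "t_steady", "reach": "t_go",
                                "target": "t_target", "relax": "t_relax"})
    return wide.sort_values("trial").reset_index(drop=True)


def save_map(path: str | Path, name: str, values: np.ndarray, freqs: np.ndarray,
             times: np.ndarray, attrs: dict | None = None) -> None:
    """Persist a frequency x time map with named axes into an HDF5 file."""
    with h5py.File(path, "a") as fh:
        if name in fh:
            del fh[name]
        g = fh.create_group(name)
        g.create_dataset("values", data=values)
        g.create_dataset("freqs_hz", data=freqs)
        g.create_dataset("times_s", data=times)
        for k, v in (attrs or {}).items():
            g.attrs[k] = v


def load_map(path: str | Path, name: str) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    with h5py.File(path, "r") as fh:
        g = fh[name]
        return (g["values"][()], g["freqs_hz"][()], g["times_s"][()], dict(g.attrs))
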