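"""Behavioural summaries of the manipulandum kinematics: reaction time
and Steady-phase stability metrics per trial and condition."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["reaction_time", "steady_metrics", "behaviour_table"]


def reaction_time(
    t: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    go_time: float,
    target: tuple[float, float],
    fraction: float = 0.1,
) -> float:
    """Time after the go cue at which displacement from the cue-time
    position reaches ``fraction`` of the distance to the target.

    Displacement is measured as Euclidean distance from the position at
    cue time (robust to pre-cue drift).  Returns NaN when the threshold
    is never reached.
    """
    t = np.asarray(t)
    sel = t >= go_time
    if not sel.any():
        raise ValueError("go_time is outside the trace")
    x0, y0 = x[sel][0], y[sel][0]
    dist_to_target = np.hypot(target[0] - x0, target[1] - y0)
    if dist_to_target == 0:
        raise ValueError("target coincides with the start position")
    disp = np.hypot(x[sel] - x0, y[sel] - y0)
    crossed = np.flatnonzero(disp >= fraction * dist_to_target)
    if crossed.size == 0:
        return float("nan")
    return float(t[sel][crossed[0]] - go_time)


def steady_metrics(
    t: np.ndarray, x: np.ndarray, y: np.ndarray, speed: np.ndarray, interval: tuple[float, float]
) -> dict:
    """Mean speed, mean Euclidean distance from the centre, and maximal
    displacement over the Steady interval."""
    sel = (t >= interval[0]) & (t < interval[1])
    if not sel.any():
        raise ValueError("empty steady interval")
    dist = np.hypot(x[sel], y[sel])
    return dict(
        mean_speed=float(np.mean(speed[sel])),
        mean_dist=float(np.mean(dist)),
        max_disp=float(np.max(dist)),
    )


def behaviour_table(kin: pd.DataFrame, schedule_df: pd.DataFrame, reach_distance_m: float) -> pd.DataFrame:
    """Per-trial behavioural table (trial, condition, RT_s, mean_speed,
    mean_dist, max_disp) from generator kinematics."""
    rows = []
    for row in schedule_df.itertuples():
        g = kin[kin["trial"] == row.trial]
        t = g["t"].to_numpy()
        x = g["x"].to_numpy()
        y = g["y"].to_numpy()
        sgn = 1.0 if row.direction == "right" else -1.0
        rt = reaction_time(t, x, y, row.t_go, (sgn * reach_distance_m, 0.0))
        sm = steady_metrics(t, x, y, g["speed"].to_numpy(), (row.t_steady, row.t_go))
        rows.append(dict(trial=row.trial, block=row.block, condition=row.condition, RT_s=rt, **sm))
    return pd.DataFrame(rows)
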