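"""Behavioural features from arena trajectories.

Four summary features are computed from each subject x trial path, all on
the 0.25 s coordinate grid of the arena logger:

* **total idle time** (s) — summed duration of steps whose Euclidean
  displacement is at most ``eps`` (default 0: exact non-movement);
* **total path length** (Vm) — summed Euclidean step lengths;
* **total angle shift** (deg) — summed absolute change in step heading,
  :math:`\\sum_t |\\theta_t - \\theta_{t-1}| \\cdot 180/\\pi`, where the
  heading of each moving step is the four-quadrant arctangent
  ``atan2(dy, dx)`` and differences are wrapped to [0°, 180°] so that a
  turn and its mirror image count equally.  Zero-displacement steps have
  no defined heading and are skipped;
* **average speed** (Vm/s) — total path length divided by the trial
  duration (``total_time``; for time-matched non-learners this equals the
  matched duration).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import TrajectorySeries, TRAJECTORY_DT
from .errors import DegenerateInputError

FEATURE_NAMES = (
    "total_idle_time",
    "total_path_length",
    "total_angle_shift",
    "average_speed",
)


def _step_vectors(traj: TrajectorySeries) -> tuple[np.ndarray, np.ndarray]:
    return np.diff(traj.xs), np.diff(traj.ys)


def total_idle_time(traj: TrajectorySeries, eps: float = 0.0) -> float:
    """Seconds spent not moving: steps with displacement <= ``eps``."""
    dx, dy = _step_vectors(traj)
    disp = np.hypot(dx, dy)
    return float(np.sum(disp <= eps) * TRAJECTORY_DT)


def total_path_length(traj: TrajectorySeries) -> float:
    """Total distance travelled, in Virtual Metres."""
    dx, dy = _step_vectors(traj)
    return float(np.sum(np.hypot(dx, dy)))


def total_angle_shift(traj: TrajectorySeries) -> float:
    """Summed absolute heading change over consecutive moving steps, degrees.

    Raises
    ------
    DegenerateInputError
        If fewer than two steps have nonzero displacement (no heading
        change is defined).
    """
    dx, dy = _step_vectors(traj)
    moving = np.hypot(dx, dy) > 0
    if np.sum(moving) < 2:
        raise DegenerateInputError(
            f"subject {traj.subject_id}: fewer than two moving steps; "
            "angle shift undefined"
        )
    headings = np.arctan2(dy[moving], dx[moving])
    d = np.abs(np.diff(headings))
    d = np.minimum(d, 2.0 * np.pi - d)  # wrap to [0, pi]
    return float(np.degrees(np.sum(d)))


def average_speed(traj: TrajectorySeries) -> float:
    """Path length divided by trial duration, Vm/s."""
    if traj.total_time <= 0:
        raise DegenerateInputError(
            f"subject {traj.subject_id}: non-positive total time"
        )
    return total_path_length(traj) / traj.total_time


def trajectory_features(traj: TrajectorySeries, eps: float = 0.0) -> dict:
    """All four behavioural features for one trajectory, as a dict."""
    return {
        "total_idle_time": total_idle_time(traj, eps=eps),
        "total_path_length": total_path_length(traj),
        "total_angle_shift": total_angle_shift(traj),
        "average_speed": average_speed(traj),
    }


def trajectory_feature_table(
    trajectories, eps: float = 0.0
) -> pd.DataFrame:
    """Feature rows for a collection of trajectories.

    Returns a DataFrame with one row per subject x trial, indexed by
    ``(subject_id, trial)``, carrying the four feature columns plus the
    group label.
    """
    rows = []
    for traj in trajectories:
        row = {"subject_id": traj.subject_id, "group": traj.group,
               "trial": traj.trial}
        row.update(trajectory_features(traj, eps=eps))
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.set_index(["subject_id", "trial"]).sort_index()
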