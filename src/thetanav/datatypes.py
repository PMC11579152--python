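"""Core data containers.

A cohort is a collection of per-subject, per-trial records of two kinds:

* :class:`ThetaSeries` — the frontal-midline theta-power trace of one
  subject during one trial, sampled at whatever rate the upstream
  time-frequency extraction produced (the methods here are rate-agnostic).
* :class:`TrajectorySeries` — the x-y path of the same subject in the
  circular virtual arena, sampled on a fixed 0.25 s grid.

Both carry the subject identifier, the experimental group
(``learner`` / ``non_learner``) and the trial label (1 = first exposure,
12 = final trial).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

GROUPS = ("learner", "non_learner")
TRIALS = (1, 12)

#: sampling interval of the arena coordinate logger, in seconds
TRAJECTORY_DT = 0.25

_GRID_TOL = 1e-9


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    if np.any(~np.isfinite(arr)):
        raise ValidationError(f"{name} contains missing or non-finite values")
    return arr


def _check_group(group: str) -> str:
    if group not in GROUPS:
        raise ValidationError(f"unknown group {group!r}; expected one of {GROUPS}")
    return group


def _check_trial(trial) -> int:
    trial = int(trial)
    if trial not in TRIALS:
        raise ValidationError(f"unknown trial {trial!r}; expected one of {TRIALS}")
    return trial


@dataclass
class ThetaSeries:
    """One subject x trial theta-power trace.

    Parameters
    ----------
    subject_id : str
        Subject identifier.
    group : {"learner", "non_learner"}
        Experimental condition.
    trial : {1, 12}
        Trial label.
    times : array-like of float
        Sample times in seconds, strictly increasing, length >= 3.
    values : array-like of float
        Theta power (arbitrary units), same length as ``times``.
    """

    subject_id: str
    group: str
    trial: int
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.group = _check_group(self.group)
        self.trial = _check_trial(self.trial)
        self.times = _as_float_array(self.times, "times")
        self.values = _as_float_array(self.values, "values")
        if len(self.times) != len(self.values):
            raise ValidationError(
                f"subject {self.subject_id}: times and values differ in length"
            )
        if len(self.times) < 3:
            raise ValidationError(
                f"subject {self.subject_id}: series must have length >= 3"
            )
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError(
                f"subject {self.subject_id} trial {self.trial}: "
                "times are not strictly increasing"
            )

    def __len__(self) -> int:
        return len(self.values)

    @property
    def duration(self) -> float:
        """Elapsed time from first to last sample, seconds."""
        return float(self.times[-1] - self.times[0])

    @property
    def key(self) -> tuple:
        return (self.subject_id, self.trial)


@dataclass
class TrajectorySeries:
    """One subject x trial arena path on the 0.25 s coordinate grid.

    ``total_time`` is the trial duration reported by the task software;
    it is at least the last sample time (the logger may stop a fraction
    of a step before the trial formally ends).
    """

    subject_id: str
    group: str
    trial: int
    times: np.ndarray
    xs: np.ndarray
    ys: np.ndarray
    total_time: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.group = _check_group(self.group)
        self.trial = _check_trial(self.trial)
        self.times = _as_float_array(self.times, "times")
        self.xs = _as_float_array(self.xs, "xs")
        self.ys = _as_float_array(self.ys, "ys")
        if not (len(self.times) == len(self.xs) == len(self.ys)):
            raise ValidationError(
                f"subject {self.subject_id}: times/xs/ys differ in length"
            )
        if len(self.times) < 3:
            raise ValidationError(
                f"subject {self.subject_id}: trajectory must have length >= 3"
            )
        steps = np.diff(self.times)
        if np.any(steps <= 0):
            raise ValidationError(
                f"subject {self.subject_id} trial {self.trial}: "
                "duplicated or non-increasing time stamps"
            )
        if np.any(np.abs(steps - TRAJECTORY_DT) > _GRID_TOL):
            raise ValidationError(
                f"subject {self.subject_id} trial {self.trial}: sampling is "
                f"not on the {TRAJECTORY_DT} s grid (max deviation "
                f"{np.max(np.abs(steps - TRAJECTORY_DT)):.3g} s)"
            )
        if self.total_time is None:
            self.total_time = float(self.times[-1])
        self.total_time = float(self.total_time)
        if self.total_time < self.times[-1] - _GRID_TOL:
            raise ValidationError(
                f"subject {self.subject_id}: total_time {self.total_time} "
                f"precedes last sample time {self.times[-1]}"
            )

    def __len__(self) -> int:
        return len(self.times)

    @property
    def key(self) -> tuple:
        return (self.subject_id, self.trial)
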