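"""CSV readers and writers for theta-series and coordinate tables.

The on-disk format is long/tidy plain CSV with a header.  Default
column names follow the study's dataset description and are
configurable:

theta table
    ``subject_id, group, trial, time, theta``
coordinates table
    ``subject_id, group, trial, time, x, y`` (optional ``total_time``)

Rows are grouped by (subject, trial) into :class:`ThetaSeries` /
:class:`TrajectorySeries` records, sorted by time within each series.
"""

from __future__ import annotations

import pandas as pd

from .datatypes import ThetaSeries, TrajectorySeries
from .errors import FormatError, ValidationError

THETA_COLUMNS = {
    "subject": "subject_id",
    "group": "group",
    "trial": "trial",
    "time": "time",
    "theta": "theta",
}

COORD_COLUMNS = {
    "subject": "subject_id",
    "group": "group",
    "trial": "trial",
    "time": "time",
    "x": "x",
    "y": "y",
    "total_time": "total_time",
}


def _read_table(path, columns: dict, required: tuple) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: file is empty or has no header") from exc
    for key in required:
        name = columns[key]
        if name not in df.columns:
            raise FormatError(
                f"{path}: missing required column {name!r} (role: {key})"
            )
    if len(df) == 0:
        raise FormatError(f"{path}: no data rows")
    return df


def read_theta_csv(path, columns: dict = None) -> list[ThetaSeries]:
    """Read a theta-power CSV into one ThetaSeries per subject x trial.

    ``columns`` may remap the role -> column-name defaults in
    :data:`THETA_COLUMNS`.
    """
    cols = dict(THETA_COLUMNS)
    if columns:
        cols.update(columns)
    df = _read_table(path, cols, ("subject", "group", "trial", "time", "theta"))
    out = []
    for (sid, trial), g in df.groupby([cols["subject"], cols["trial"]],
                                      sort=True):
        g = g.sort_values(cols["time"], kind="stable")
        groups = g[cols["group"]].unique()
        if len(groups) != 1:
            raise ValidationError(
                f"subject {sid} trial {trial}: inconsistent group labels {groups}"
            )
        out.append(ThetaSeries(
            subject_id=str(sid), group=str(groups[0]), trial=int(trial),
            times=g[cols["time"]].to_numpy(float),
            values=g[cols["theta"]].to_numpy(float),
        ))
    return out


def write_theta_csv(path, series_list, columns: dict = None) -> None:
    """Write ThetaSeries records as a tidy CSV (inverse of the reader)."""
    cols = dict(THETA_COLUMNS)
    if columns:
        cols.update(columns)
    frames = []
    for s in series_list:
        frames.append(pd.DataFrame({
            cols["subject"]: s.subject_id,
            cols["group"]: s.group,
            cols["trial"]: s.trial,
            cols["time"]: s.times,
            cols["theta"]: s.values,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_coordinates_csv(path, columns: dict = None) -> list[TrajectorySeries]:
    """Read an arena-coordinates CSV into TrajectorySeries records.

    The 0.25 s sampling grid is validated per series.
    """
    cols = dict(COORD_COLUMNS)
    if columns:
        cols.update(columns)
    df = _read_table(path, cols, ("subject", "group", "trial", "time", "x", "y"))
    has_total = cols["total_time"] in df.columns
    out = []
    for (sid, trial), g in df.groupby([cols["subject"], cols["trial"]],
                                      sort=True):
        g = g.sort_values(cols["time"], kind="stable")
        groups = g[cols["group"]].unique()
        if len(groups) != 1:
            raise ValidationError(
                f"subject {sid} trial {trial}: inconsistent group labels {groups}"
            )
        total_time = float(g[cols["total_time"]].iloc[0]) if has_total else None
        out.append(TrajectorySeries(
            subject_id=str(sid), group=str(groups[0]), trial=int(trial),
            times=g[cols["time"]].to_numpy(float),
            xs=g[cols["x"]].to_numpy(float),
            ys=g[cols["y"]].to_numpy(float),
            total_time=total_time,
        ))
    return out


def write_coordinates_csv(path, traj_list, columns: dict = None) -> None:
    """Write TrajectorySeries records as a tidy CSV (inverse of the reader)."""
    cols = dict(COORD_COLUMNS)
    if columns:
        cols.update(columns)
    frames = []
    for t in traj_list:
        frames.append(pd.DataFrame({
            cols["subject"]: t.subject_id,
            cols["group"]: t.group,
            cols["trial"]: t.trial,
            cols["time"]: t.times,
            cols["x"]: t.xs,
            cols["y"]: t.ys,
            cols["total_time"]: t.total_time,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
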