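"""Per-series standardisation of theta-power traces.

Two rescalings are applied to each subject x trial series before feature
extraction, always using statistics computed *within* that series (never
pooled across subjects, which would leak information across
cross-validation folds):

* ``minmax`` — :math:`(x_t - \\min x)/(\\max x - \\min x)`, mapping the
  series onto [0, 1];
* ``zscore`` — :math:`(x_t - \\bar x)/s` with the sample (n-1) standard
  deviation, giving mean 0 and SD 1.

``raw`` leaves the series untouched.  All three are strictly monotone, so
peak locations are preserved; peak heights and curvatures change scale,
which is the point of comparing the three.
"""

from __future__ import annotations

import numpy as np

from .errors import DegenerateInputError

METHODS = ("raw", "minmax", "zscore")


def minmax_scale(values) -> np.ndarray:
    """Rescale a series onto [0, 1] by its own minimum and maximum.

    Raises
    ------
    DegenerateInputError
        If the series is constant (the transform is undefined) or shorter
        than 2 samples.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise DegenerateInputError("minmax requires at least 2 samples")
    lo, hi = np.min(x), np.max(x)
    if hi == lo:
        raise DegenerateInputError("minmax undefined for a constant series")
    return (x - lo) / (hi - lo)


def zscore_scale(values) -> np.ndarray:
    """Centre and scale a series by its sample mean and (n-1) SD.

    Raises
    ------
    DegenerateInputError
        If the series is constant or shorter than 2 samples.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise DegenerateInputError("zscore requires at least 2 samples")
    s = np.std(x, ddof=1)
    if s == 0:
        raise DegenerateInputError("zscore undefined for a zero-variance series")
    return (x - np.mean(x)) / s


def standardise(values, method: str) -> np.ndarray:
    """Apply one of the named standardisations (``raw`` is the identity)."""
    if method == "raw":
        return np.asarray(values, dtype=float).copy()
    if method == "minmax":
        return minmax_scale(values)
    if method == "zscore":
        return zscore_scale(values)
    raise ValueError(f"unknown standardisation {method!r}; expected one of {METHODS}")
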