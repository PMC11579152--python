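"""Peak features and the random-intercept/random-slope mixed model.

From each (standardised) theta series we take every interior local
maximum k and record its height :math:`y = x_k` and its curvature, the
second-order difference :math:`x_{k-1} - 2x_k + x_{k+1}` (negative at a
strict peak).  Peaks from all subjects in a trial dataset are then
pooled into a linear mixed model of height on curvature,

.. math::

    Y_{ij} \\mid b_{0i}, b_{1i} \\sim N(b_{0i} + b_{1i} x_{ij}, \\sigma^2),
    \\qquad
    b_{0i} \\sim N(\\beta_0, \\sigma_0^2), \\quad
    b_{1i} \\sim N(\\beta_1, \\sigma_1^2),

with the random intercept and slope independent
(:math:`\\mathrm{Corr}(b_{0i}, b_{1i}) = 0`, a diagonal random-effects
covariance).  The model is estimated by maximising the closed-form
Gaussian marginal likelihood (REML optional) over
:math:`(\\beta_0, \\beta_1, \\sigma^2, \\sigma_0^2, \\sigma_1^2)`; the
per-subject features are the empirical-Bayes predictions (BLUPs)
:math:`\\hat b_{0i}, \\hat b_{1i}` — each subject's own regression line
shrunk toward the population line in proportion to how little data the
subject contributes.

BLUPs for a subject *not* in the fitting set (a held-out
cross-validation subject) are computed from the trained parameters and
that subject's own peaks, so feature extraction never leaks the held-out
label into training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import FitError, ValidationError

logger = logging.getLogger(__name__)

_LOG_2PI = float(np.log(2.0 * np.pi))


def detect_peaks(series) -> np.ndarray:
    """Indices of interior local maxima of a series.

    Strict maxima (x_{k-1} < x_k > x_{k+1}) are peaks; a flat plateau
    whose value exceeds the values on both sides contributes its first
    index only.  Endpoints are never peaks.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValidationError("peak detection requires a 1-D series, length >= 3")
    peaks = []
    k = 1
    n = x.size
    while k < n - 1:
        if x[k] > x[k - 1]:
            j = k
            while j + 1 < n and x[j + 1] == x[k]:
                j += 1
            if j < n - 1 and x[j + 1] < x[k]:
                peaks.append(k)
            k = j + 1
        else:
            k += 1
    return np.asarray(peaks, dtype=int)


def peak_curvature(series, k: int) -> float:
    """Second-order difference x_{k-1} - 2 x_k + x_{k+1} at index k."""
    x = np.asarray(series, dtype=float)
    if not (1 <= k <= x.size - 2):
        raise IndexError(f"index {k} is not interior to a series of length {x.size}")
    return float(x[k - 1] - 2.0 * x[k] + x[k + 1])


@dataclass
class PeakSet:
    """Peak heights and curvatures of one subject x trial series."""

    subject_id: str
    trial: int
    indices: np.ndarray
    heights: np.ndarray
    curvatures: np.ndarray
    group: str = None  # type: ignore[assignment]

    @classmethod
    def from_series(cls, values, subject_id: str = "", trial: int = 1,
                    group: str = None) -> "PeakSet":
        x = np.asarray(values, dtype=float)
        idx = detect_peaks(x)
        heights = x[idx]
        curv = np.array([peak_curvature(x, int(k)) for k in idx])
        return cls(subject_id=subject_id, trial=trial, indices=idx,
                   heights=heights, curvatures=curv, group=group)

    def __len__(self) -> int:
        return len(self.indices)


class PeakLMM:
    """Linear mixed model of peak height on peak curvature.

    Random intercepts and slopes per subject with a diagonal
    random-effects covariance.  ``fit`` maximises the marginal
    likelihood; ``fit(reml=True)`` uses REML for the variance
    components.

    Parameters
    ----------
    peaksets : sequence of PeakSet
        One entry per subject (within one trial dataset).  Subjects with
        fewer than 2 peaks are retained — their BLUPs simply shrink
        almost entirely to the population line — but are logged.
    """

    MIN_TOTAL_PEAKS = 5

    def __init__(self, peaksets):
        peaksets = list(peaksets)
        if len(peaksets) < 2:
            raise FitError("mixed model needs at least 2 subjects")
        total = sum(len(ps) for ps in peaksets)
        if total < self.MIN_TOTAL_PEAKS:
            raise FitError(
                f"only {total} peaks in total; need >= {self.MIN_TOTAL_PEAKS}"
            )
        for ps in peaksets:
            if len(ps) < 2:
                logger.warning(
                    "subject %s has %d peak(s); BLUP will shrink to the "
                    "population line", ps.subject_id, len(ps)
                )
        self.peaksets = peaksets
        self._y = [np.asarray(ps.heights, dtype=float) for ps in peaksets]
        self._x = [np.asarray(ps.curvatures, dtype=float) for ps in peaksets]
        # per-subject sufficient statistics: with X_i = [1, x_i],
        # G = X'X, h = X'y, q = y'y and n; everything downstream is 2x2
        # algebra via the Woodbury/push-through identities, so likelihood
        # evaluations cost O(subjects) regardless of peak counts.
        self._suff = []
        for y, x in zip(self._y, self._x):
            X = np.column_stack([np.ones_like(x), x])
            self._suff.append((X.T @ X, X.T @ y, float(y @ y), len(y)))

    # -- marginal likelihood --------------------------------------------
    @staticmethod
    def _subject_pieces(G, h, q, n, s2, s20, s21):
        """(logdet V, X'V^-1 X, X'V^-1 y, y'V^-1 y) for one subject.

        Uses det(s2 I + X D X') = s2^n det(I + D G / s2) and
        V^-1 = s2^-1 [I - X D (s2 I + G D)^-1 X'], both valid when D is
        singular (a variance component estimated at zero).
        """
        D = np.diag([s20, s21])
        C = s2 * np.eye(2) + G @ D
        sign, logdetC = np.linalg.slogdet(C / s2)
        if sign <= 0:
            return None
        logdetV = n * np.log(s2) + logdetC
        K = D @ np.linalg.solve(C, np.eye(2))  # D (s2 I + G D)^-1
        XtViX = (G - G @ K @ G) / s2
        XtViy = (h - G @ K @ h) / s2
        ytViy = (q - h @ K @ h) / s2
        return logdetV, XtViX, XtViy, ytViy

    def _assemble(self, s2, s20, s21):
        """Pooled GLS quantities across subjects at given variances."""
        A = np.zeros((2, 2))
        b = np.zeros(2)
        logdet = 0.0
        yy = 0.0
        n_total = 0
        for G, h, q, n in self._suff:
            pieces = self._subject_pieces(G, h, q, n, s2, s20, s21)
            if pieces is None:
                return None
            ld, XtViX, XtViy, ytViy = pieces
            logdet += ld
            A += XtViX
            b += XtViy
            yy += ytViy
            n_total += n
        return A, b, logdet, yy, n_total

    def _profile_beta(self, s2, s20, s21):
        """GLS fixed effects and their information at given variances."""
        A, b, *_ = self._assemble(s2, s20, s21)
        return np.linalg.solve(A, b), A

    def loglike(self, beta, s2, s20, s21, reml: bool = False) -> float:
        """Marginal (or REML) log-likelihood at the given parameters."""
        beta = np.asarray(beta, dtype=float)
        out = self._assemble(s2, s20, s21)
        if out is None:
            return -np.inf
        A, b, logdet, yy, n_total = out
        quad = yy - 2.0 * beta @ b + beta @ A @ beta
        ll = -0.5 * (n_total * _LOG_2PI + logdet + quad)
        if reml:
            sign, logdetA = np.linalg.slogdet(A)
            ll += -0.5 * logdetA + _LOG_2PI  # REML adjustment (p = 2)
        return float(ll)

    def fit(self, reml: bool = False, tol: float = 1e-8,
            maxiter: int = 500, start=None) -> "PeakLMMResults":
        """Maximise the (restricted) marginal likelihood.

        Variances are optimised on the log scale with Nelder-Mead and
        the fixed effects profiled out by GLS at each step; convergence
        is on relative log-likelihood change.  ``start`` may supply
        initial ``(sigma2, sigma2_0, sigma2_1)`` values (used to
        warm-start the cross-validation refits).
        """
        if start is None:
            ys = np.concatenate(self._y)
            xs = np.concatenate(self._x)
            X = np.column_stack([np.ones_like(xs), xs])
            beta0, *_ = np.linalg.lstsq(X, ys, rcond=None)
            resid_var = max(float(np.var(ys - X @ beta0)), 1e-8)
            start_log = np.log([resid_var / 2, resid_var / 4, resid_var / 4])
        else:
            start_log = np.log(np.maximum(np.asarray(start, dtype=float),
                                          1e-12))

        def neg(logv):
            s2, s20, s21 = np.exp(np.clip(logv, -40, 40))
            out = self._assemble(s2, s20, s21)
            if out is None:
                return np.inf
            A, b, logdet, yy, n_total = out
            beta = np.linalg.solve(A, b)
            quad = yy - 2.0 * beta @ b + beta @ A @ beta
            ll = -0.5 * (n_total * _LOG_2PI + logdet + quad)
            if reml:
                _, logdetA = np.linalg.slogdet(A)
                ll += -0.5 * logdetA + _LOG_2PI
            return -ll

        res = optimize.minimize(
            neg, start_log, method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": tol, "maxiter": maxiter * 10},
        )
        s2, s20, s21 = np.exp(np.clip(res.x, -40, 40))
        beta, A = self._profile_beta(s2, s20, s21)
        cov_beta = np.linalg.inv(A)
        ll = self.loglike(beta, s2, s20, s21, reml=reml)
        return PeakLMMResults(
            model=self, beta0=float(beta[0]), beta1=float(beta[1]),
            bse=np.sqrt(np.diag(cov_beta)), sigma2=float(s2),
            sigma2_0=float(s20), sigma2_1=float(s21), loglik=float(ll),
            converged=bool(res.success), reml=reml,
        )


@dataclass
class PeakLMMResults:
    """Fitted peak-height mixed model.

    ``beta0``/``beta1`` are the population intercept and slope, ``bse``
    their standard errors; ``sigma2`` the residual variance and
    ``sigma2_0``/``sigma2_1`` the random intercept/slope variances.
    """

    model: PeakLMM
    beta0: float
    beta1: float
    bse: np.ndarray
    sigma2: float
    sigma2_0: float
    sigma2_1: float
    loglik: float
    converged: bool
    reml: bool

    def predict_random_effects(self, curvatures, heights) -> tuple[float, float]:
        """BLUP (b0_hat, b1_hat) for one subject's peaks.

        Works for fitted and held-out subjects alike: the conditional
        mean of (b0, b1) given the subject's data under the trained
        parameters,
        ``beta + D X' V^{-1} (y - X beta)`` with D = diag(s20, s21).
        A subject with no peaks receives the population values.
        """
        x = np.asarray(curvatures, dtype=float)
        y = np.asarray(heights, dtype=float)
        beta = np.array([self.beta0, self.beta1])
        if x.size == 0:
            return float(beta[0]), float(beta[1])
        X = np.column_stack([np.ones_like(x), x])
        D = np.diag([self.sigma2_0, self.sigma2_1])
        V = self.sigma2 * np.eye(len(y)) + X @ D @ X.T
        b = beta + D @ X.T @ np.linalg.solve(V, y - X @ beta)
        return float(b[0]), float(b[1])

    @property
    def per_subject(self) -> pd.DataFrame:
        """BLUP intercept/slope per fitted subject."""
        rows = {}
        for ps in self.model.peaksets:
            rows[ps.subject_id] = self.predict_random_effects(
                ps.curvatures, ps.heights
            )
        return pd.DataFrame.from_dict(
            rows, orient="index", columns=["lmm_intercept", "lmm_slope"]
        ).rename_axis("subject_id")

    def summary(self) -> str:
        lines = [
            "Peak height ~ curvature linear mixed model "
            f"({'REML' if self.reml else 'ML'})",
            f"  subjects:   {len(self.model.peaksets)}",
            f"  peaks:      {sum(len(ps) for ps in self.model.peaksets)}",
            f"  beta0:      {self.beta0:.6g} (SE {self.bse[0]:.3g})",
            f"  beta1:      {self.beta1:.6g} (SE {self.bse[1]:.3g})",
            f"  sigma2:     {self.sigma2:.6g}",
            f"  sigma2_0:   {self.sigma2_0:.6g}",
            f"  sigma2_1:   {self.sigma2_1:.6g}",
            f"  loglik:     {self.loglik:.6f}",
            f"  converged:  {self.converged}",
        ]
        return "\n".join(lines)


def lmm_features(fit: PeakLMMResults) -> pd.DataFrame:
    """Per-subject (lmm_intercept, lmm_slope) feature frame."""
    return fit.per_subject
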