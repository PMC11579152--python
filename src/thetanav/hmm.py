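"""Gaussian hidden Markov models for single theta-power series.

One HMM is fitted per subject x trial series.  The latent state
:math:`C_t \\in \\{S_1..S_M\\}` follows a first-order Markov chain with
transition matrix :math:`P` and initial distribution :math:`\\delta`;
emissions are conditionally independent given the state,
:math:`X_t \\mid C_t \\sim N(\\mu(C_t), \\sigma^2(C_t))`.

Estimation is by Baum-Welch EM from several seeded initialisations
(means at jittered series quantiles, variances at the sample variance,
uniform transitions), keeping the restart with the best log-likelihood.
After fitting, states are put in canonical order — ascending mean, ties
broken by ascending variance — so that "state k" means the same thing
for every subject and the per-state features are comparable across the
cohort.  With :math:`M` states the model has
:math:`M^2 + 2M - 1` free parameters (M means, M variances,
M(M-1) transition entries, M-1 initial probabilities), the count used
for AIC.

The per-subject feature vector at the default ``M = 4`` has 11 entries:
the 4 state means, the 4 state variances, and the decoded occupancy
frequencies of states 1-3 (state 4's frequency is redundant, being one
minus the other three).  The M(M-1) free transition probabilities can be
appended behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _recursions as _rec
from .errors import FitError, ValidationError

_ROWSUM_TOL = 1e-10
_LOG_2PI = math.log(2.0 * math.pi)


@dataclass
class GaussianHMMParams:
    """Parameters of a Gaussian-emission HMM.

    States are indexed 0..M-1 internally; user-facing feature names use
    1-based labels.
    """

    means: np.ndarray
    variances: np.ndarray
    transition: np.ndarray
    initial: np.ndarray

    def __post_init__(self):
        self.means = np.atleast_1d(np.asarray(self.means, dtype=float))
        self.variances = np.atleast_1d(np.asarray(self.variances, dtype=float))
        self.transition = np.atleast_2d(np.asarray(self.transition, dtype=float))
        self.initial = np.atleast_1d(np.asarray(self.initial, dtype=float))
        M = self.means.shape[0]
        if self.variances.shape != (M,):
            raise ValidationError("variances must match means in length")
        if self.transition.shape != (M, M):
            raise ValidationError(f"transition matrix must be {M}x{M}")
        if self.initial.shape != (M,):
            raise ValidationError("initial distribution must have length M")
        if np.any(self.variances <= 0):
            raise ValidationError("state variances must be positive")
        if np.any(self.transition < 0) or np.any(self.initial < 0):
            raise ValidationError("probabilities must be non-negative")
        rowsums = self.transition.sum(axis=1)
        if np.any(np.abs(rowsums - 1.0) > _ROWSUM_TOL):
            raise ValidationError(
                f"transition matrix rows must sum to 1 (got {rowsums})"
            )
        if abs(self.initial.sum() - 1.0) > _ROWSUM_TOL:
            raise ValidationError("initial distribution must sum to 1")

    @property
    def n_states(self) -> int:
        return self.means.shape[0]

    @property
    def n_free_params(self) -> int:
        """M^2 + 2M - 1 free parameters."""
        M = self.n_states
        return M * M + 2 * M - 1

    def stationary_distribution(self) -> np.ndarray:
        """Stationary distribution of the state chain (left eigenvector)."""
        vals, vecs = np.linalg.eig(self.transition.T)
        idx = int(np.argmin(np.abs(vals - 1.0)))
        v = np.real(vecs[:, idx])
        v = np.abs(v)
        return v / v.sum()

    def reordered(self, order: np.ndarray) -> "GaussianHMMParams":
        """Return a copy with states permuted by ``order``."""
        order = np.asarray(order)
        return GaussianHMMParams(
            means=self.means[order],
            variances=self.variances[order],
            transition=self.transition[np.ix_(order, order)],
            initial=self.initial[order],
        )

    def canonical(self) -> tuple["GaussianHMMParams", np.ndarray]:
        """Canonically ordered copy (ascending mean, ties by variance)."""
        order = np.lexsort((self.variances, self.means))
        return self.reordered(order), order


def _emission_logdens(params: GaussianHMMParams, x: np.ndarray) -> np.ndarray:
    """Log N(x_t; mu_m, sigma2_m) for every (t, m)."""
    mu = params.means[None, :]
    v = params.variances[None, :]
    return -0.5 * (_LOG_2PI + np.log(v) + (x[:, None] - mu) ** 2 / v)


def forward_loglik(params: GaussianHMMParams, series) -> float:
    """log P(x_1..x_T) via the scaled forward recursion."""
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 1:
        raise ValidationError("series must be a non-empty 1-D sequence")
    logB = _emission_logdens(params, x)
    _, ll = _rec.forward_scaled(logB, params.transition, params.initial)
    return float(ll)


def viterbi_decode(params: GaussianHMMParams, series) -> np.ndarray:
    """Jointly most probable hidden-state path (0-based state labels)."""
    x = np.asarray(series, dtype=float)
    logB = _emission_logdens(params, x)
    with np.errstate(divide="ignore"):
        logP = np.log(params.transition)
        logd = np.log(params.initial)
    path, _ = _rec.viterbi_path(logB, logP, logd)
    return path


def posterior_occupancy(params: GaussianHMMParams, series) -> np.ndarray:
    """Smoothed state posteriors gamma_t(m); rows sum to 1."""
    x = np.asarray(series, dtype=float)
    logB = _emission_logdens(params, x)
    gamma, _, _ = _rec.e_step(logB, params.transition, params.initial)
    return gamma


def state_frequencies(path, n_states: int) -> np.ndarray:
    """Occupancy fraction of each state along a decoded path."""
    path = np.asarray(path, dtype=int)
    if path.size == 0:
        raise ValidationError("state path is empty")
    counts = np.bincount(path, minlength=n_states)
    return counts / path.size


class GaussianHMM:
    """Gaussian HMM for one series, statsmodels-style.

    Parameters
    ----------
    endog : array-like
        The observed series (one subject x trial theta-power trace,
        typically standardised).
    n_states : int
        Number of latent states M (the study default is 4).

    Examples
    --------
    >>> model = GaussianHMM(series, n_states=4)
    >>> res = model.fit(seed=0)
    >>> res.aic, res.params.means
    """

    #: minimum observations per state (rule of thumb), configurable
    min_length_factor = 10

    def __init__(self, endog, n_states: int = 4):
        self.endog = np.asarray(endog, dtype=float)
        if self.endog.ndim != 1:
            raise ValidationError("endog must be one-dimensional")
        if n_states < 1:
            raise ValidationError("n_states must be >= 1")
        self.n_states = int(n_states)

    # -- initialisation -------------------------------------------------
    def _initial_params(self, rng: np.random.Generator) -> GaussianHMMParams:
        x = self.endog
        M = self.n_states
        q = (np.arange(M) + 0.5) / M
        means = np.quantile(x, q)
        sd = np.std(x)
        if sd == 0:
            sd = 1.0
        means = means + rng.normal(0.0, 0.1 * sd, size=M)
        variances = np.full(M, max(np.var(x), 1e-12))
        transition = np.full((M, M), 1.0 / M)
        initial = np.full(M, 1.0 / M)
        return GaussianHMMParams(means, variances, transition, initial)

    # -- EM -------------------------------------------------------------
    def _run_em(self, params: GaussianHMMParams, tol: float, max_iter: int):
        x = self.endog
        var_floor = 1e-6 * max(np.var(x), 1e-300)
        means = params.means.copy()
        variances = params.variances.copy()
        P = params.transition.copy()
        delta = params.initial.copy()
        prev_ll = -np.inf
        floored = False
        converged = False
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            p = GaussianHMMParams(means, variances, P, delta)
            logB = _emission_logdens(p, x)
            gamma, xi_sum, ll = _rec.e_step(logB, P, delta)
            if ll < prev_ll - 1e-8 * (1.0 + abs(prev_ll)):
                raise FitError(
                    f"EM log-likelihood decreased ({prev_ll:.10g} -> {ll:.10g})"
                )
            if np.isfinite(prev_ll) and abs(ll - prev_ll) <= tol * (
                1.0 + abs(prev_ll)
            ):
                converged = True
                prev_ll = ll
                break
            prev_ll = ll
            # M-step
            occ = gamma.sum(axis=0)
            means = gamma.T @ x / occ
            variances = (gamma * (x[:, None] - means[None, :]) ** 2).sum(
                axis=0
            ) / occ
            low = variances < var_floor
            if np.any(low):
                variances = np.where(low, var_floor, variances)
                floored = True
            if self.n_states > 1:
                rows = xi_sum.sum(axis=1, keepdims=True)
                P = np.where(rows > 0, xi_sum / np.where(rows == 0, 1, rows),
                             1.0 / self.n_states)
                P = P / P.sum(axis=1, keepdims=True)
            delta = gamma[0] / gamma[0].sum()
        final = GaussianHMMParams(means, variances, P, delta)
        return final, prev_ll, n_iter, converged, floored

    def fit(
        self,
        seed: int = 0,
        n_restarts: int = 5,
        tol: float = 1e-8,
        max_iter: int = 500,
        enforce_min_length: bool = True,
    ) -> "GaussianHMMResults":
        """Fit by Baum-Welch EM with seeded restarts.

        The best restart by log-likelihood is kept; states are then put
        in canonical ascending-mean order.
        """
        x = self.endog
        M = self.n_states
        if enforce_min_length and x.size < self.min_length_factor * M:
            raise FitError(
                f"series of length {x.size} too short for M={M} "
                f"(need >= {self.min_length_factor * M})"
            )
        if M == 1:
            # EM closed form: single Gaussian
            mu = float(np.mean(x))
            v = max(float(np.var(x)), 1e-6 * max(np.var(x), 1e-300), 1e-300)
            params = GaussianHMMParams([mu], [v], [[1.0]], [1.0])
            ll = forward_loglik(params, x)
            return GaussianHMMResults(self, params, ll, n_iter=1,
                                      converged=True, variance_floored=False)
        rng = np.random.default_rng(seed)
        best = None
        for _ in range(max(1, n_restarts)):
            init = self._initial_params(rng)
            try:
                fitted = self._run_em(init, tol=tol, max_iter=max_iter)
            except np.linalg.LinAlgError:  # pragma: no cover - defensive
                continue
            if best is None or fitted[1] > best[1]:
                best = fitted
        if best is None:  # pragma: no cover - defensive
            raise FitError("all EM restarts failed")
        params, ll, n_iter, converged, floored = best
        params, _ = params.canonical()
        return GaussianHMMResults(self, params, ll, n_iter=n_iter,
                                  converged=converged,
                                  variance_floored=floored)


@dataclass
class GaussianHMMResults:
    """Fitted Gaussian HMM for one series.

    Attributes
    ----------
    params : GaussianHMMParams
        Canonically ordered parameter estimates.
    loglik : float
        Maximised log-likelihood.
    n_iter : int
        EM iterations used by the winning restart.
    converged : bool
        Whether the relative log-likelihood tolerance was reached.
    variance_floored : bool
        Whether any state variance hit the collapse floor during EM.
    """

    model: GaussianHMM
    params: GaussianHMMParams
    loglik: float
    n_iter: int
    converged: bool
    variance_floored: bool
    _decoded: np.ndarray = field(default=None, repr=False)  # type: ignore

    @property
    def aic(self) -> float:
        """-2 loglik + 2 (M^2 + 2M - 1)."""
        return -2.0 * self.loglik + 2.0 * self.params.n_free_params

    @property
    def decoded_path(self) -> np.ndarray:
        """Viterbi state path (cached)."""
        if self._decoded is None:
            self._decoded = viterbi_decode(self.params, self.model.endog)
        return self._decoded

    def state_frequencies(self, method: str = "viterbi") -> np.ndarray:
        """State occupancy fractions.

        ``viterbi`` (default) counts states along the decoded path;
        ``posterior`` averages the smoothed posteriors instead.
        """
        if method == "viterbi":
            return state_frequencies(self.decoded_path, self.params.n_states)
        if method == "posterior":
            gamma = posterior_occupancy(self.params, self.model.endog)
            return gamma.mean(axis=0)
        raise ValueError(f"unknown occupancy method {method!r}")

    def features(self, include_transitions: bool = False,
                 occupancy: str = "viterbi") -> dict:
        """Named per-subject features: 2M parameters + (M-1) frequencies.

        At M=4 this is the 11-feature set (4 means, 4 variances, 3 state
        frequencies).  With ``include_transitions`` the M(M-1) free
        transition probabilities are appended.
        """
        M = self.params.n_states
        feats: dict[str, float] = {}
        for m in range(M):
            feats[f"hmm_mean_{m + 1}"] = float(self.params.means[m])
        for m in range(M):
            feats[f"hmm_var_{m + 1}"] = float(self.params.variances[m])
        freqs = self.state_frequencies(method=occupancy)
        for m in range(M - 1):
            feats[f"hmm_freq_{m + 1}"] = float(freqs[m])
        if include_transitions:
            for i in range(M):
                for j in range(M):
                    if j == M - 1:
                        continue  # row sums to 1: last entry redundant
                    feats[f"hmm_p_{i + 1}{j + 1}"] = float(
                        self.params.transition[i, j]
                    )
        return feats

    def summary(self) -> str:
        """Plain-text fit summary."""
        p = self.params
        lines = [
            "Gaussian HMM fit",
            f"  states:     {p.n_states}",
            f"  T:          {self.model.endog.size}",
            f"  loglik:     {self.loglik:.4f}",
            f"  AIC:        {self.aic:.4f}",
            f"  EM iters:   {self.n_iter} (converged={self.converged})",
            f"  means:      {np.array2string(p.means, precision=4)}",
            f"  variances:  {np.array2string(p.variances, precision=4)}",
            "  transition:",
        ]
        for row in p.transition:
            lines.append("    " + np.array2string(row, precision=4))
        return "\n".join(lines)


def hmm_features(fit: GaussianHMMResults, include_transitions: bool = False,
                 occupancy: str = "viterbi") -> dict:
    """Module-level alias for :meth:`GaussianHMMResults.features`."""
    return fit.features(include_transitions=include_transitions,
                        occupancy=occupancy)


def aic_profile(series_collection, M_values=(2, 3, 4, 5), seed: int = 0,
                n_restarts: int = 5) -> pd.DataFrame:
    """AIC of per-series HMM fits across candidate state counts.

    Returns a tidy DataFrame with columns ``series``, ``M``, ``aic``,
    ``loglik``, ``converged`` and ``error`` (fit failures are recorded,
    not fatal), enabling the box-plot comparison used to choose M.
    """
    rows = []
    rng = np.random.default_rng(seed)
    for idx, series in enumerate(series_collection):
        x = np.asarray(series, dtype=float)
        for M in M_values:
            sub_seed = int(rng.integers(2**31))
            row = {"series": idx, "M": int(M), "aic": np.nan,
                   "loglik": np.nan, "converged": False, "error": ""}
            try:
                res = GaussianHMM(x, n_states=M).fit(
                    seed=sub_seed, n_restarts=n_restarts
                )
                row.update(aic=res.aic, loglik=res.loglik,
                           converged=res.converged)
            except Exception as exc:  # noqa: BLE001 - recorded per series
                row["error"] = str(exc)
            rows.append(row)
    return pd.DataFrame(rows)
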