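"""Local surrogate explanations (LIME-style K-Lasso).

For each subject, the trained classifier's continuous score is probed
with Gaussian perturbations around the subject's feature vector
(per-feature SD = ``noise_scale`` x the cohort SD of that feature).  An
exponential kernel on standardised Euclidean distance weights the
perturbations, and a sparse local linear surrogate is fitted by
*K-Lasso*: LARS selects the ``K`` most informative features, then a
kernel-weighted least-squares refit on the selected features gives the
local coefficients.  Each subject therefore receives at most K nonzero
feature weights describing what drove its own prediction.

Aggregation mirrors the study's reporting: within each (group, trial)
cell, rank features by how often they appear among subjects' selected
sets and report the top-k with their mean absolute local weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import Lars

from .errors import ConfigError


@dataclass
class ExplanationRecord:
    """Per-subject local surrogate coefficients plus subject metadata.

    ``coefficients`` is subjects x features (zeros for unselected
    features); ``meta`` carries ``group`` and ``trial`` per subject.
    """

    coefficients: pd.DataFrame
    meta: pd.DataFrame
    K: int


def explain_subjects(
    score_fn,
    X: pd.DataFrame,
    meta: pd.DataFrame,
    n_samples: int = 500,
    noise_scale: float = 0.25,
    K: int = 3,
    kernel_width: float = None,
    seed: int = 0,
) -> ExplanationRecord:
    """Fit a sparse local linear surrogate around every subject.

    Parameters
    ----------
    score_fn : callable
        Maps an (n, p) feature array to n continuous scores — the
        trained classifier's scoring function on the *original* feature
        scale.
    X : DataFrame
        Subjects x features used to train the classifier.
    meta : DataFrame
        ``group`` and ``trial`` per subject (same index as ``X``).
    n_samples : int
        Perturbations per subject.
    noise_scale : float
        Perturbation SD as a fraction of each feature's cohort SD.
    K : int
        Number of features retained by the K-Lasso step.
    kernel_width : float, optional
        Width of the exponential kernel on standardised distance;
        defaults to 0.75 * sqrt(p).
    """
    p = X.shape[1]
    sd = X.to_numpy(dtype=float).std(axis=0)
    if np.any(sd == 0):
        bad = X.columns[sd == 0].tolist()
        raise ConfigError(
            f"degenerate perturbation variance for constant features {bad}"
        )
    if kernel_width is None:
        kernel_width = 0.75 * np.sqrt(p)
    rng = np.random.default_rng(seed)
    K_eff = min(K, p)
    coef_rows = {}
    for sid, row in X.iterrows():
        x0 = row.to_numpy(dtype=float)
        Z = x0 + rng.normal(0.0, noise_scale * sd, size=(n_samples, p))
        target = np.asarray(score_fn(Z), dtype=float)
        Zs = (Z - x0) / sd  # standardised displacement from the subject
        d = np.linalg.norm(Zs, axis=1)
        w = np.exp(-(d**2) / kernel_width**2)
        sw = np.sqrt(w)
        # weighted centring so the surrogate has a free local intercept
        zbar = (w[:, None] * Zs).sum(axis=0) / w.sum()
        tbar = (w * target).sum() / w.sum()
        Zc = (Zs - zbar) * sw[:, None]
        tc = (target - tbar) * sw
        sel = Lars(n_nonzero_coefs=K_eff, fit_intercept=False)
        sel.fit(Zc, tc)
        active = np.flatnonzero(sel.coef_)
        coefs = np.zeros(p)
        if active.size:
            beta, *_ = np.linalg.lstsq(Zc[:, active], tc, rcond=None)
            coefs[active] = beta / sd[active]  # back to the original scale
        coef_rows[sid] = coefs
    coefficients = pd.DataFrame.from_dict(
        coef_rows, orient="index", columns=X.columns
    ).rename_axis(X.index.name)
    return ExplanationRecord(coefficients=coefficients,
                             meta=meta.loc[X.index].copy(), K=K_eff)


def top_frequent_features(records, k: int = 3) -> pd.DataFrame:
    """Most frequently selected features per (group, trial).

    ``records`` is one ExplanationRecord or a sequence of them (e.g. one
    per trial).  Within each (group, trial) cell, features are ranked by
    how many subjects selected them (nonzero local weight), ties broken
    by mean absolute weight; the top ``k`` are returned with columns
    ``group, trial, rank, feature, frequency, mean_abs_weight``.
    """
    if isinstance(records, ExplanationRecord):
        records = [records]
    rows = []
    for rec in records:
        df = rec.coefficients
        meta = rec.meta
        for (group, trial), idx in meta.groupby(
            ["group", "trial"], sort=True
        ).groups.items():
            sub = df.loc[idx]
            nonzero = sub != 0
            freq = nonzero.sum(axis=0)
            mean_abs = sub.abs().where(nonzero).mean(axis=0).fillna(0.0)
            ranking = pd.DataFrame({
                "frequency": freq, "mean_abs_weight": mean_abs
            }).sort_values(["frequency", "mean_abs_weight"],
                           ascending=False, kind="stable")
            ranking = ranking[ranking["frequency"] > 0].head(k)
            for rank, (feat, r) in enumerate(ranking.iterrows(), start=1):
                rows.append({
                    "group": group, "trial": trial, "rank": rank,
                    "feature": feat, "frequency": int(r["frequency"]),
                    "mean_abs_weight": float(r["mean_abs_weight"]),
                })
    return pd.DataFrame(rows)
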