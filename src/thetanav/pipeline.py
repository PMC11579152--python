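"""End-to-end orchestration: series -> features -> evaluation -> explanations.

The pipeline is a pure function of (inputs, config, seed).  A single
integer seed is fanned out into named substreams (simulation, HMM
restarts, classifier initialisation, explanation perturbations) so that
every stage is independently reproducible.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .classify import (
    ClassifierSpec, FeatureTable, assemble_feature_table, loocv_evaluate,
    loocv_lmm_blups, CLASSIFIER_NAMES,
)
from .errors import ConfigError
from .explain import explain_subjects, top_frequent_features
from .hmm import GaussianHMM
from .lmm import PeakSet, PeakLMM, lmm_features
from .preprocessing import standardise, METHODS
from .simulate import CohortSpec, simulate_cohort
from .trajectory import trajectory_feature_table

logger = logging.getLogger(__name__)

LABEL_CODES = {"learner": 1, "non_learner": 0}


def _stream_seed(seed: int, *key) -> int:
    """Stable integer child seed below 2**31."""
    h = zlib.crc32(repr((seed,) + key).encode())
    return int(h % (2**31))


@dataclass
class TrialFeatures:
    """All per-subject features for one (trial, standardisation) slice."""

    trial: int
    standardisation: str
    hmm_table: pd.DataFrame
    hmm_diagnostics: pd.DataFrame
    lmm_table: pd.DataFrame
    lmm_fit: object
    peaksets: dict
    traj_table: pd.DataFrame
    labels: pd.Series
    groups: pd.Series

    def feature_table(self, dataset: str) -> FeatureTable:
        """Assemble the eeg / coordinates / combined table."""
        return assemble_feature_table(
            hmm_feats=self.hmm_table, lmm_feats=self.lmm_table,
            traj_feats=self.traj_table, labels=self.labels,
            dataset=dataset, trial=self.trial,
            standardisation=self.standardisation,
        )


def extract_features(
    theta_list,
    traj_list=None,
    M: int = 4,
    standardisation: str = "zscore",
    seed: int = 0,
    n_restarts: int = 5,
    include_transitions: bool = False,
    occupancy: str = "viterbi",
    idle_eps: float = 0.0,
    include_series_summaries: bool = False,
) -> dict:
    """Compute every feature family, per trial.

    Per subject x trial: the series is standardised, an M-state Gaussian
    HMM is fitted (2M parameter features + M-1 decoded state
    frequencies), peaks are detected and the trial-level peak mixed
    model supplies BLUP intercept/slope features; trajectory features
    are added when coordinate data are given.  Returns
    ``{trial: TrialFeatures}``.

    ``include_series_summaries`` appends the per-series mean and SD of
    the standardised trace to the EEG feature block (off by default).
    """
    if standardisation not in METHODS:
        raise ConfigError(f"unknown standardisation {standardisation!r}")
    trials = sorted({s.trial for s in theta_list})
    traj_table_all = (trajectory_feature_table(traj_list, eps=idle_eps)
                      if traj_list else None)
    out = {}
    for trial in trials:
        series = [s for s in theta_list if s.trial == trial]
        series.sort(key=lambda s: s.subject_id)
        logger.info("trial %s: extracting features for %d subjects "
                    "(standardisation=%s, M=%d)",
                    trial, len(series), standardisation, M)
        hmm_rows, diag_rows, peaksets = {}, {}, {}
        groups = {}
        for s in series:
            x = standardise(s.values, standardisation)
            fit = GaussianHMM(x, n_states=M).fit(
                seed=_stream_seed(seed, "hmm", s.subject_id, trial),
                n_restarts=n_restarts,
            )
            feats = fit.features(include_transitions=include_transitions,
                                 occupancy=occupancy)
            feats["series_duration"] = s.duration
            if include_series_summaries:
                feats["series_mean"] = float(np.mean(x))
                feats["series_sd"] = float(np.std(x, ddof=1))
            hmm_rows[s.subject_id] = feats
            diag_rows[s.subject_id] = {
                "loglik": fit.loglik, "aic": fit.aic, "n_iter": fit.n_iter,
                "converged": fit.converged,
                "variance_floored": fit.variance_floored,
            }
            peaksets[s.subject_id] = PeakSet.from_series(
                x, subject_id=s.subject_id, trial=trial, group=s.group
            )
            groups[s.subject_id] = s.group
        hmm_table = pd.DataFrame.from_dict(hmm_rows, orient="index") \
            .rename_axis("subject_id")
        diagnostics = pd.DataFrame.from_dict(diag_rows, orient="index") \
            .rename_axis("subject_id")
        lmm_fit = PeakLMM(list(peaksets.values())).fit()
        lmm_table = lmm_features(lmm_fit).loc[hmm_table.index]
        groups_s = pd.Series(groups, name="group").rename_axis("subject_id")
        labels = groups_s.map(LABEL_CODES).astype(int).rename("label")
        traj_table = None
        if traj_table_all is not None:
            tt = traj_table_all.xs(trial, level="trial")
            traj_table = tt.drop(columns=["group"]).loc[hmm_table.index] \
                if set(hmm_table.index) <= set(tt.index) \
                else tt.drop(columns=["group"])
        logger.info("trial %s: %d HMM features, %d LMM features, "
                    "%s trajectory features per subject", trial,
                    hmm_table.shape[1], lmm_table.shape[1],
                    traj_table.shape[1] if traj_table is not None else 0)
        out[trial] = TrialFeatures(
            trial=trial, standardisation=standardisation,
            hmm_table=hmm_table, hmm_diagnostics=diagnostics,
            lmm_table=lmm_table, lmm_fit=lmm_fit, peaksets=peaksets,
            traj_table=traj_table, labels=labels, groups=groups_s,
        )
    return out


def evaluate_classifiers(
    trial_features: dict,
    datasets=("eeg", "coordinates", "combined"),
    classifiers=CLASSIFIER_NAMES,
    seed: int = 0,
    lmm_mode: str = "per_fold",
) -> tuple[pd.DataFrame, dict]:
    """LOOCV AUROC for every (trial, dataset, classifier) combination.

    Returns a tidy AUROC table and the dict of EvalResult objects.  The
    per-fold mixed-model BLUPs are computed once per trial and shared
    across classifiers.
    """
    for name in classifiers:
        if name not in CLASSIFIER_NAMES:
            raise ConfigError(f"unknown classifier {name!r}")
    results = {}
    rows = []
    for trial, tf in sorted(trial_features.items()):
        fold_blups = None
        if lmm_mode == "per_fold":
            fold_blups = loocv_lmm_blups(
                tf.peaksets, tf.hmm_table.index.tolist()
            )
        for dataset in datasets:
            if dataset != "eeg" and tf.traj_table is None:
                continue
            table = tf.feature_table(dataset)
            for name in classifiers:
                spec = ClassifierSpec(
                    name, seed=_stream_seed(seed, "clf", name, trial, dataset)
                )
                res = loocv_evaluate(
                    table, spec, peaksets=tf.peaksets, lmm_mode=lmm_mode,
                    fold_blups=fold_blups if dataset != "coordinates" else None,
                )
                logger.info("trial %s %s %s: AUROC %.3f",
                            trial, dataset, name, res.auroc)
                results[(trial, dataset, name)] = res
                rows.append(res.to_row())
    return pd.DataFrame(rows), results


def explain_best(
    trial_features: dict,
    classifier: str = "dnn",
    dataset: str = "combined",
    K: int = 3,
    n_samples: int = 500,
    noise_scale: float = 0.25,
    seed: int = 0,
) -> tuple[pd.DataFrame, list]:
    """Local-surrogate feature ranking for one classifier configuration.

    The classifier is trained on each trial's full table, every subject
    is explained, and the per-(group, trial) top-K ranking is returned
    together with the per-trial ExplanationRecord list.
    """
    from .classify import build_classifier, continuous_score, SCALE_SENSITIVE

    records = []
    for trial, tf in sorted(trial_features.items()):
        table = tf.feature_table(dataset)
        X = table.X
        constant = X.columns[X.std(ddof=0) == 0].tolist()
        if constant:
            logger.info("trial %s: dropping constant features %s from the "
                        "explanation", trial, constant)
            X = X.drop(columns=constant)
        mu, sd = X.mean(), X.std(ddof=0).replace(0, 1.0)
        spec = ClassifierSpec(
            classifier, seed=_stream_seed(seed, "explain-clf", trial)
        )
        clf = build_classifier(spec)
        X_fit = ((X - mu) / sd).to_numpy() \
            if classifier in SCALE_SENSITIVE else X.to_numpy()
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            clf.fit(X_fit, table.y.to_numpy())

        def score_fn(Z, _clf=clf, _mu=mu.to_numpy(), _sd=sd.to_numpy(),
                     _scaled=classifier in SCALE_SENSITIVE):
            Zt = (Z - _mu) / _sd if _scaled else Z
            return continuous_score(_clf, Zt)

        meta = pd.DataFrame({"group": tf.groups, "trial": trial})
        rec = explain_subjects(
            score_fn, X, meta, n_samples=n_samples, noise_scale=noise_scale,
            K=K, seed=_stream_seed(seed, "explain-perturb", trial),
        )
        records.append(rec)
    ranking = top_frequent_features(records, k=K)
    return ranking, records


# ---------------------------------------------------------------------------
# config-driven run
# ---------------------------------------------------------------------------

DEFAULT_CONFIG = {
    "simulate": True,
    "n_per_group": 25,
    "theta_csv": None,
    "coordinates_csv": None,
    "standardisation": "zscore",
    "M": 4,
    "n_restarts": 5,
    "classifiers": list(CLASSIFIER_NAMES),
    "datasets": ["eeg", "coordinates", "combined"],
    "lmm_mode": "per_fold",
    "explain": {"classifier": "dnn", "dataset": "combined", "K": 3},
    "seed": 0,
}


def run_pipeline(config: dict, out_dir) -> dict:
    """Run simulate/load -> features -> evaluate -> explain, writing CSVs.

    Returns a report dict with the output paths and the AUROC table.
    Deterministic given the config's seed.
    """
    cfg = dict(DEFAULT_CONFIG)
    explain_cfg = dict(DEFAULT_CONFIG["explain"])
    user_explain = (config or {}).get("explain") or {}
    cfg.update(config or {})
    explain_cfg.update(user_explain if isinstance(user_explain, dict) else {})
    cfg["explain"] = explain_cfg
    unknown = set(cfg) - set(DEFAULT_CONFIG)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    seed = int(cfg["seed"])
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if cfg["simulate"]:
        logger.info("simulating cohort (n_per_group=%d, seed=%d)",
                    cfg["n_per_group"], seed)
        spec = CohortSpec(n_per_group=int(cfg["n_per_group"]),
                          seed=_stream_seed(seed, "simulate"))
        theta_list, traj_list, _ = simulate_cohort(spec)
    else:
        if not cfg["theta_csv"]:
            raise ConfigError("theta_csv required when simulate is false")
        theta_list = tio.read_theta_csv(cfg["theta_csv"])
        traj_list = (tio.read_coordinates_csv(cfg["coordinates_csv"])
                     if cfg["coordinates_csv"] else None)
    logger.info("loaded %d theta series, %d trajectories",
                len(theta_list), len(traj_list) if traj_list else 0)

    tfs = extract_features(
        theta_list, traj_list, M=int(cfg["M"]),
        standardisation=cfg["standardisation"],
        seed=_stream_seed(seed, "features"),
        n_restarts=int(cfg["n_restarts"]),
    )
    datasets = [d for d in cfg["datasets"]
                if d == "eeg" or traj_list is not None]
    for trial, tf in tfs.items():
        for dataset in datasets:
            table = tf.feature_table(dataset)
            path = out_dir / (f"features_{dataset}_trial{trial}_"
                              f"{cfg['standardisation']}.csv")
            table.X.assign(label=table.y).to_csv(path)
        tf.hmm_diagnostics.to_csv(
            out_dir / f"hmm_diagnostics_trial{trial}_"
                      f"{cfg['standardisation']}.csv")

    auroc_df, _ = evaluate_classifiers(
        tfs, datasets=datasets, classifiers=cfg["classifiers"],
        seed=_stream_seed(seed, "evaluate"), lmm_mode=cfg["lmm_mode"],
    )
    auroc_path = out_dir / "auroc.csv"
    auroc_df.to_csv(auroc_path, index=False)

    explain_path = None
    if explain_cfg and explain_cfg.get("dataset") in datasets:
        ranking, _ = explain_best(
            tfs, classifier=explain_cfg["classifier"],
            dataset=explain_cfg["dataset"], K=int(explain_cfg["K"]),
            seed=_stream_seed(seed, "explain"),
        )
        explain_path = out_dir / "explanations.csv"
        ranking.to_csv(explain_path, index=False)

    report = {
        "seed": seed,
        "n_series": len(theta_list),
        "auroc_csv": str(auroc_path),
        "explanations_csv": str(explain_path) if explain_path else None,
        "auroc": auroc_df.to_dict(orient="records"),
    }
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
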