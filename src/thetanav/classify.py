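"""Feature-table assembly, LOOCV evaluation and AUROC.

Classification is binary — learner (1) vs non-learner (0) — on one
feature table per (trial, standardisation, dataset variant):

* ``eeg``          — the 11 HMM features, the 2 mixed-model features and
                     the series duration;
* ``coordinates``  — the four trajectory features;
* ``combined``     — the column union of the two, row-aligned by subject.

Six classifier configurations are evaluated: 3rd-order polynomial SVM,
RBF ("non-linear") SVM, random forest (1000 trees, depth 5), 1-nearest
neighbour, elastic-net logistic regression (L2-dominant mix, alpha =
0.98 on the L2 term) and a deep MLP with hidden layers
100-150-200-150-46-20-10 and a single sigmoid output.  Evaluation is
leave-one-out cross-validation: each subject is scored by a model
trained on the remaining n-1 (with feature standardisation and,
optionally, the peak mixed model refitted inside the training fold),
and a single AUROC is computed from the n pooled held-out scores.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .errors import ConfigError, UndefinedMetricError, ValidationError
from .lmm import PeakLMM

logger = logging.getLogger(__name__)

CLASSIFIER_NAMES = (
    "poly_svm", "rbf_svm", "random_forest", "knn",
    "elastic_net_logistic", "dnn",
)

#: learners whose features are centred/scaled by training-fold statistics
SCALE_SENSITIVE = ("poly_svm", "rbf_svm", "knn", "elastic_net_logistic", "dnn")

DATASET_VARIANTS = ("eeg", "coordinates", "combined")


@dataclass
class FeatureTable:
    """Subjects x features with binary labels, the unit of classification."""

    X: pd.DataFrame
    y: pd.Series
    dataset: str
    trial: int
    standardisation: str = "raw"

    def __post_init__(self):
        if self.dataset not in DATASET_VARIANTS:
            raise ValidationError(
                f"unknown dataset tag {self.dataset!r}; "
                f"expected one of {DATASET_VARIANTS}"
            )
        if not self.X.index.equals(self.y.index):
            raise ValidationError("feature matrix and labels are misaligned")
        if self.X.isna().any().any():
            bad = self.X.columns[self.X.isna().any()].tolist()
            raise ValidationError(f"missing cells in feature columns {bad}")
        if not set(np.unique(self.y)) <= {0, 1}:
            raise ValidationError("labels must be binary 0/1")
        if self.X.columns.duplicated().any():
            raise ValidationError("feature names must be unique")

    @property
    def n_subjects(self) -> int:
        return len(self.X)


def assemble_feature_table(
    hmm_feats: pd.DataFrame = None,
    lmm_feats: pd.DataFrame = None,
    traj_feats: pd.DataFrame = None,
    labels: pd.Series = None,
    dataset: str = "combined",
    trial: int = 12,
    standardisation: str = "raw",
) -> FeatureTable:
    """Join per-subject feature sources into one FeatureTable.

    All sources must be indexed by subject_id and cover the same subject
    set; a subject present in one source but missing in another raises,
    naming the offending subjects.
    """
    if dataset == "eeg":
        parts = [hmm_feats, lmm_feats]
    elif dataset == "coordinates":
        parts = [traj_feats]
    else:
        parts = [hmm_feats, lmm_feats, traj_feats]
    parts = [p for p in parts if p is not None]
    if not parts or labels is None:
        raise ValidationError(
            f"dataset {dataset!r} requires its feature sources and labels"
        )
    index = parts[0].index
    for p in parts[1:]:
        if not p.index.sort_values().equals(index.sort_values()):
            missing = sorted(set(index.symmetric_difference(p.index)))
            raise ValidationError(
                f"feature sources cover different subjects: {missing}"
            )
    X = pd.concat([p.loc[index] for p in parts], axis=1)
    y = labels.loc[index]
    return FeatureTable(X=X, y=y, dataset=dataset, trial=trial,
                        standardisation=standardisation)


# ---------------------------------------------------------------------------
# classifiers
# ---------------------------------------------------------------------------

#: the study's printed hyperparameters plus documented defaults for the rest
DEFAULT_HYPERPARAMETERS = {
    "poly_svm": {"kernel": "poly", "degree": 3, "gamma": "scale", "C": 1.0},
    "rbf_svm": {"kernel": "rbf", "gamma": "scale", "C": 1.0},
    "random_forest": {"n_estimators": 1000, "max_depth": 5},
    "knn": {"n_neighbors": 1},
    # penalty = lambda [alpha ||b||_2^2 + (1 - alpha) ||b||_1], alpha = 0.98
    "elastic_net_logistic": {"alpha": 0.98, "lam": 1.0, "max_iter": 5000},
    "dnn": {
        "hidden_layer_sizes": (100, 150, 200, 150, 46, 20, 10),
        "activation": "relu",
        "learning_rate_init": 1e-3,
        "max_iter": 200,
    },
}


@dataclass
class ClassifierSpec:
    """One named classifier configuration with its hyperparameters."""

    name: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.name not in CLASSIFIER_NAMES:
            raise ConfigError(
                f"unknown classifier {self.name!r}; "
                f"expected one of {CLASSIFIER_NAMES}"
            )
        hp = dict(DEFAULT_HYPERPARAMETERS[self.name])
        hp.update(self.hyperparameters)
        self.hyperparameters = hp


def build_classifier(spec: ClassifierSpec):
    """Instantiate the scikit-learn estimator for a ClassifierSpec."""
    hp = spec.hyperparameters
    if spec.name == "poly_svm":
        return SVC(kernel=hp["kernel"], degree=hp["degree"],
                   gamma=hp["gamma"], C=hp["C"], random_state=spec.seed)
    if spec.name == "rbf_svm":
        return SVC(kernel=hp["kernel"], gamma=hp["gamma"], C=hp["C"],
                   random_state=spec.seed)
    if spec.name == "random_forest":
        return RandomForestClassifier(
            n_estimators=hp["n_estimators"], max_depth=hp["max_depth"],
            random_state=spec.seed,
        )
    if spec.name == "knn":
        return KNeighborsClassifier(n_neighbors=hp["n_neighbors"])
    if spec.name == "elastic_net_logistic":
        # sklearn's l1_ratio is the L1 share; alpha multiplies the L2 term
        return LogisticRegression(
            penalty="elasticnet", solver="saga",
            l1_ratio=1.0 - hp["alpha"], C=1.0 / hp["lam"],
            max_iter=hp["max_iter"], random_state=spec.seed,
        )
    if spec.name == "dnn":
        # tol=0 disables sklearn's loss-plateau stopping so the net
        # trains for the configured number of epochs
        return MLPClassifier(
            hidden_layer_sizes=hp["hidden_layer_sizes"],
            activation=hp["activation"], solver="adam",
            learning_rate_init=hp["learning_rate_init"],
            max_iter=hp["max_iter"], tol=0.0,
            n_iter_no_change=hp["max_iter"], random_state=spec.seed,
        )
    raise ConfigError(f"unknown classifier {spec.name!r}")  # pragma: no cover


def continuous_score(clf, X: np.ndarray) -> np.ndarray:
    """A continuous learner-score for each row (higher = more learner-like)."""
    if hasattr(clf, "predict_proba"):
        return clf.predict_proba(X)[:, 1]
    return clf.decision_function(X)


# ---------------------------------------------------------------------------
# AUROC
# ---------------------------------------------------------------------------

def auroc(scores, labels) -> float:
    """Area under the ROC curve (Mann-Whitney form; ties count 1/2)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise UndefinedMetricError("AUROC undefined with a single class")
    return float(roc_auc_score(labels, scores))


# ---------------------------------------------------------------------------
# LOOCV
# ---------------------------------------------------------------------------

@dataclass
class EvalResult:
    """Pooled-LOOCV evaluation of one classifier on one feature table."""

    classifier: str
    dataset: str
    trial: int
    standardisation: str
    auroc: float
    scores: pd.Series
    labels: pd.Series
    seed: int

    def to_row(self) -> dict:
        return {
            "classifier": self.classifier, "dataset": self.dataset,
            "trial": self.trial, "standardisation": self.standardisation,
            "auroc": self.auroc, "n_subjects": len(self.scores),
            "seed": self.seed,
        }


def loocv_lmm_blups(peaksets: dict, subjects, reml: bool = False) -> dict:
    """Per-fold BLUP features for leave-one-out evaluation.

    For each held-out subject, the peak mixed model is fitted on the
    other subjects' peaks (warm-started from the full-data fit) and
    BLUPs are predicted for everyone — the held-out subject's BLUP uses
    only trained parameters and its own peaks.  Returns
    ``held_out_subject -> {subject -> (b0, b1)}``; classifier-agnostic,
    so the result can be shared across all six configurations.
    """
    subjects = list(subjects)
    full = PeakLMM([peaksets[s] for s in subjects]).fit(reml=reml)
    warm = (full.sigma2, full.sigma2_0, full.sigma2_1)
    out = {}
    for held in subjects:
        train = [s for s in subjects if s != held]
        fit = PeakLMM([peaksets[s] for s in train]).fit(reml=reml, start=warm)
        out[held] = {
            s: fit.predict_random_effects(peaksets[s].curvatures,
                                          peaksets[s].heights)
            for s in subjects
        }
    return out


def _fold_standardise(train: np.ndarray, test: np.ndarray):
    """Centre/scale by training-fold statistics; constant columns pass
    through centred."""
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (train - mu) / sd, (test - mu) / sd


def loocv_evaluate(
    table: FeatureTable,
    spec,
    peaksets: dict = None,
    lmm_mode: str = "per_fold",
    reml: bool = False,
    fold_blups: dict = None,
) -> EvalResult:
    """Leave-one-out evaluation with pooled-score AUROC.

    Parameters
    ----------
    table : FeatureTable
        Features and labels, one row per subject.
    spec : ClassifierSpec or str
        Which classifier configuration to run.
    peaksets : dict, optional
        ``subject_id -> PeakSet`` for this trial/standardisation.  When
        given and ``lmm_mode == "per_fold"``, the peak mixed model is
        refitted on each training fold and the table's
        ``lmm_intercept``/``lmm_slope`` columns are replaced by
        fold-specific BLUPs (the held-out subject's BLUP uses only the
        trained parameters plus its own peaks).  ``lmm_mode ==
        "fit_once"`` keeps the table's columns as supplied.
    """
    if isinstance(spec, str):
        spec = ClassifierSpec(name=spec)
    if lmm_mode not in ("per_fold", "fit_once"):
        raise ConfigError(f"unknown lmm_mode {lmm_mode!r}")
    n = table.n_subjects
    if n < 4:
        raise ValidationError("LOOCV needs at least 4 subjects")
    if len(np.unique(table.y)) < 2:
        raise ValidationError("both classes must be present")

    refit_lmm = (
        lmm_mode == "per_fold" and (peaksets is not None
                                    or fold_blups is not None)
        and {"lmm_intercept", "lmm_slope"} <= set(table.X.columns)
    )
    subjects = table.X.index.to_numpy()
    if refit_lmm and fold_blups is None:
        fold_blups = loocv_lmm_blups(peaksets, subjects, reml=reml)
    X_all = table.X.to_numpy(dtype=float)
    y_all = table.y.to_numpy()
    lmm_cols = [table.X.columns.get_loc("lmm_intercept"),
                table.X.columns.get_loc("lmm_slope")] if refit_lmm else []
    scores = np.empty(n)
    rng = np.random.default_rng(spec.seed)
    for i in range(n):
        train_idx = np.setdiff1d(np.arange(n), [i])
        if len(np.unique(y_all[train_idx])) < 2:  # pragma: no cover
            logger.warning("fold %d skipped: single-class training fold", i)
            scores[i] = np.nan
            continue
        X_tr = X_all[train_idx].copy()
        X_te = X_all[[i]].copy()
        if refit_lmm:
            blups = fold_blups[subjects[i]]
            for row, s in enumerate(subjects[train_idx]):
                X_tr[row, lmm_cols] = blups[s]
            X_te[0, lmm_cols] = blups[subjects[i]]
        if spec.name in SCALE_SENSITIVE:
            X_tr, X_te = _fold_standardise(X_tr, X_te)
        clf = build_classifier(
            ClassifierSpec(spec.name, dict(spec.hyperparameters),
                           seed=int(rng.integers(2**31)))
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # MLP convergence on tiny folds
            clf.fit(X_tr, y_all[train_idx])
        scores[i] = continuous_score(clf, X_te)[0]
    valid = ~np.isnan(scores)
    value = auroc(scores[valid], y_all[valid])
    return EvalResult(
        classifier=spec.name, dataset=table.dataset, trial=table.trial,
        standardisation=table.standardisation, auroc=value,
        scores=pd.Series(scores, index=table.X.index, name="score"),
        labels=table.y.copy(), seed=spec.seed,
    )
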