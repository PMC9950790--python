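"""Resampled imbalanced-ensemble training and evaluation.

The class imbalance between known combinations (positives) and the vastly
larger non-combination pool is handled by undersampling: R independent
training sets each keep every positive and draw ``ratio`` negatives per
positive without replacement (1:5 by default).  One classifier is fitted per
training set; the ensemble's prediction for a candidate pair is the count of
members voting positive (see :mod:`synergyscreen.vote`).

Five classifier families are pluggable behind one spec string: random forest
(default, 300 trees), k-nearest neighbours, Gaussian naive Bayes, RBF-kernel
SVM, and AdaBoost.  Evaluation is stratified repeated k-fold CV with the
confusion counts pooled per repeat, or a 70/30 internal-validation holdout.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .io_core import FEATURE_NAMES, RunConfig, derive_seed

logger = logging.getLogger("synergyscreen")

CLASSIFIER_SPECS = ("rf", "knn", "nb", "svm_rbf", "adaboost")


def make_classifier(spec: str, config: RunConfig, seed: int):
    """Instantiate one classifier by spec string; unknown spec is an error."""
    if spec == "rf":
        return RandomForestClassifier(n_estimators=config.rf_ntree,
                                      random_state=seed, n_jobs=1)
    if spec == "knn":
        return make_pipeline(StandardScaler(), KNeighborsClassifier())
    if spec == "nb":
        return GaussianNB()
    if spec == "svm_rbf":
        return make_pipeline(StandardScaler(),
                             SVC(kernel="rbf", probability=True, random_state=seed))
    if spec == "adaboost":
        return AdaBoostClassifier(random_state=seed)
    raise ValueError(f"unknown classifier_spec {spec!r}; choose from {CLASSIFIER_SPECS}")


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionMetrics:
    precision: float
    recall: float
    accuracy: float
    f1: float
    degenerate: bool = False


def classification_metrics(tp: int, fp: int, fn: int, tn: int) -> ConfusionMetrics:
    """Precision, recall, accuracy and F1 from confusion counts.

    A zero denominator yields 0 for that rate with ``degenerate`` set.
    """
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("confusion counts must be non-negative")
    degenerate = False
    if tp + fp > 0:
        precision = tp / (tp + fp)
    else:
        precision, degenerate = 0.0, True
    if tp + fn > 0:
        recall = tp / (tp + fn)
    else:
        recall, degenerate = 0.0, True
    total = tp + fp + fn + tn
    accuracy = (tp + tn) / total if total else 0.0
    f1 = f1_from_precision_recall(precision, recall)
    return ConfusionMetrics(precision, recall, accuracy, f1, degenerate)


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def roc_pr_areas(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """AUROC (tie-aware trapezoid) and AUPRC (right-continuous step integral)."""
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC/PR areas need both classes present")
    return (float(roc_auc_score(labels, scores)),
            float(average_precision_score(labels, scores)))


@dataclass
class MetricSet:
    """Mean +- sd of the six evaluation metrics over repeats or members."""

    mean: dict[str, float]
    sd: dict[str, float]
    n: int

    FIELDS = ("accuracy", "precision", "recall", "f1", "auroc", "auprc")

    @classmethod
    def from_rows(cls, rows: list[dict[str, float]]) -> "MetricSet":
        frame = pd.DataFrame(rows)
        return cls(mean={k: float(frame[k].mean()) for k in cls.FIELDS},
                   sd={k: float(frame[k].std(ddof=1)) if len(frame) > 1 else 0.0
                       for k in cls.FIELDS},
                   n=len(frame))

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.mean, "sd": self.sd})


# ---------------------------------------------------------------------------
# training-set resampling
# ---------------------------------------------------------------------------

def build_training_set(positives: list[tuple[str, str]],
                       negative_pool: list[tuple[str, str]],
                       ratio: int, seed: int) -> list[tuple[tuple[str, str], int]]:
    """All positives plus ratio * n_pos negatives sampled without replacement.

    Returns (pair_key, label) rows; total row count is n_pos * (1 + ratio).
    """
    n_pos = len(positives)
    n_neg = ratio * n_pos
    if len(negative_pool) < n_neg:
        raise ValueError(f"negative pool too small: need {n_neg}, "
                         f"have {len(negative_pool)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(negative_pool), size=n_neg, replace=False)
    rows = [(key, 1) for key in positives]
    rows += [(negative_pool[i], 0) for i in sorted(idx.tolist())]
    return rows


def _score_positive(clf, X: np.ndarray) -> np.ndarray:
    proba = clf.predict_proba(X)
    pos_col = list(clf.classes_).index(1)
    return proba[:, pos_col]


def cross_validate(X: pd.DataFrame, y: np.ndarray, classifier_spec: str,
                   folds: int, repeats: int, seed: int,
                   config: RunConfig | None = None) -> MetricSet:
    """Stratified repeated k-fold CV with metrics pooled per repeat.

    Confusion counts (threshold 0.5 on the positive-class probability) and
    held-out scores are pooled over the folds of one repeat; AUROC/AUPRC come
    from the pooled scores; the MetricSet averages over repeats.
    """
    config = config or RunConfig()
    y = np.asarray(y, dtype=int)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if min(np.bincount(y, minlength=2)) < folds:
        raise ValueError("each class needs at least `folds` members")
    Xv = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=int(rng.integers(2**31)))
        scores = np.zeros(len(y))
        for tr, te in skf.split(Xv, y):
            clf = make_classifier(classifier_spec, config, int(rng.integers(2**31)))
            clf.fit(Xv[tr], y[tr])
            scores[te] = _score_positive(clf, Xv[te])
        pred = (scores >= 0.5).astype(int)
        tp = int(((pred == 1) & (y == 1)).sum())
        fp = int(((pred == 1) & (y == 0)).sum())
        fn = int(((pred == 0) & (y == 1)).sum())
        tn = int(((pred == 0) & (y == 0)).sum())
        cm = classification_metrics(tp, fp, fn, tn)
        auroc, auprc = roc_pr_areas(scores, y)
        rows.append({"accuracy": cm.accuracy, "precision": cm.precision,
                     "recall": cm.recall, "f1": cm.f1,
                     "auroc": auroc, "auprc": auprc})
    return MetricSet.from_rows(rows)


def evaluate_holdout(X: pd.DataFrame, y: np.ndarray, classifier_spec: str,
                     seed: int, config: RunConfig | None = None,
                     test_size: float = 0.30) -> dict[str, float]:
    """70/30 internal-validation split: fit on 70%, metrics on the held-out 30%."""
    config = config or RunConfig()
    y = np.asarray(y, dtype=int)
    Xv = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    Xtr, Xte, ytr, yte = train_test_split(Xv, y, test_size=test_size,
                                          stratify=y, random_state=seed)
    clf = make_classifier(classifier_spec, config, seed)
    clf.fit(Xtr, ytr)
    scores = _score_positive(clf, Xte)
    pred = (scores >= 0.5).astype(int)
    cm = classification_metrics(int(((pred == 1) & (yte == 1)).sum()),
                                int(((pred == 1) & (yte == 0)).sum()),
                                int(((pred == 0) & (yte == 1)).sum()),
                                int(((pred == 0) & (yte == 0)).sum()))
    auroc, auprc = roc_pr_areas(scores, yte)
    return {"accuracy": cm.accuracy, "precision": cm.precision, "recall": cm.recall,
            "f1": cm.f1, "auroc": auroc, "auprc": auprc}


# ---------------------------------------------------------------------------
# the resampled ensemble
# ---------------------------------------------------------------------------

@dataclass
class EnsembleMember:
    seed: int
    negative_ids: list[tuple[str, str]]
    features: list[str]
    classifier: object
    cv_metrics: MetricSet | None = None


@dataclass
class ResampledEnsemble:
    """R classifiers, one per resampled 1:5 training set."""

    members: list[EnsembleMember]
    classifier_spec: str
    config: RunConfig

    def __len__(self) -> int:
        return len(self.members)

    @property
    def feature_names(self) -> list[str]:
        return self.members[0].features

    def mean_cv_metrics(self) -> MetricSet:
        rows = [m.cv_metrics.mean for m in self.members if m.cv_metrics is not None]
        if not rows:
            raise ValueError("ensemble was trained without CV metrics")
        return MetricSet.from_rows(rows)

    # -- persistence (directory of member files + one metadata file) -------

    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "classifier_spec": self.classifier_spec,
            "n_members": len(self.members),
            "config": self.config.__dict__,
            "members": [{"seed": m.seed, "features": m.features,
                         "negative_ids": [list(k) for k in m.negative_ids]}
                        for m in self.members],
        }
        (directory / "ensemble.json").write_text(json.dumps(meta, indent=1))
        for i, m in enumerate(self.members):
            joblib.dump(m.classifier, directory / f"member_{i:04d}.joblib")
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "ResampledEnsemble":
        directory = Path(directory)
        meta = json.loads((directory / "ensemble.json").read_text())
        members = []
        for i, info in enumerate(meta["members"]):
            clf = joblib.load(directory / f"member_{i:04d}.joblib")
            members.append(EnsembleMember(
                seed=info["seed"],
                negative_ids=[tuple(k) for k in info["negative_ids"]],
                features=info["features"], classifier=clf))
        return cls(members=members, classifier_spec=meta["classifier_spec"],
                   config=RunConfig(**meta["config"]))


def train_resampled_ensemble(positives: list[tuple[str, str]],
                             negative_pool: list[tuple[str, str]],
                             features: pd.DataFrame, config: RunConfig,
                             classifier_spec: str = "rf",
                             feature_subset: list[str] | None = None,
                             n_resamples: int | None = None,
                             with_cv: bool = True) -> ResampledEnsemble:
    """Fit R classifiers on R resampled training sets.

    ``features`` is a pair-indexed table containing the columns in
    ``feature_subset`` (default: all 16).  Per-member seeds derive from
    ``config.master_seed``; the run is fully deterministic given that seed.
    Per-member CV metrics (``config.cv_folds`` x ``config.cv_repeats``, or a
    70/30 holdout when ``config.eval_mode == "holdout"``) are recorded when
    ``with_cv``.
    """
    if classifier_spec not in CLASSIFIER_SPECS:
        raise ValueError(f"unknown classifier_spec {classifier_spec!r}")
    r = n_resamples or config.n_resamples
    cols = feature_subset or FEATURE_NAMES
    members: list[EnsembleMember] = []
    for i in range(r):
        seed = derive_seed(config.master_seed, "resample", i)
        rows = build_training_set(positives, negative_pool,
                                  config.ratio_neg_per_pos, seed)
        keys = [key for key, _ in rows]
        X = features.loc[keys, cols]
        y = np.array([lab for _, lab in rows], dtype=int)
        clf = make_classifier(classifier_spec, config,
                              derive_seed(config.master_seed, "fit", i))
        clf.fit(X.to_numpy(dtype=float), y)
        cv: MetricSet | None = None
        if with_cv:
            eval_seed = derive_seed(config.master_seed, "eval", i)
            if config.eval_mode == "holdout":
                cv = MetricSet.from_rows([evaluate_holdout(
                    X, y, classifier_spec, eval_seed, config)])
            else:
                cv = cross_validate(X, y, classifier_spec, config.cv_folds,
                                    config.cv_repeats, eval_seed, config)
        members.append(EnsembleMember(
            seed=seed,
            negative_ids=[key for key, lab in rows if lab == 0],
            features=list(cols), classifier=clf, cv_metrics=cv))
    logger.info("ensemble: trained %d %s members on %d features",
                len(members), classifier_spec, len(cols))
    return ResampledEnsemble(members=members, classifier_spec=classifier_spec,
                             config=config)
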