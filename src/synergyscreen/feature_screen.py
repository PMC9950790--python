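"""Feature screening: group-difference tests and resampled RFE frequencies.

Two complementary screens run on the 16 pair features:

1. Per-feature two-sided Welch t-test and Mann-Whitney U test between the
   combination and non-combination groups, with group means and standard
   deviations.
2. Recursive feature elimination (RFE) driven by random-forest importance,
   repeated over many resampled 1:5 training sets; a feature is retained if
   it appears in at least ``feature_frequency_cutoff`` (default 70%) of the
   per-resample selections.

The RFE follows the caret ``rfe``/``rfFuncs`` protocol: within each CV fold
the features are ranked once by random-forest importance on the fold's
training part, candidate subset sizes 1..p are evaluated by held-out
accuracy, the best size wins (ties go to the smaller subset), and the final
subset of that size is taken from a ranking on the full training set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .io_core import FEATURE_NAMES, RunConfig, derive_seed

logger = logging.getLogger("synergyscreen")


@dataclass
class FeatureScreenReport:
    """Per-feature test statistics and RFE selection frequencies."""

    table: pd.DataFrame  # index: feature; columns below
    cutoff: float = 0.70

    COLUMNS = ["mean_neg", "sd_neg", "mean_pos", "sd_pos",
               "t_p", "mw_p", "degenerate", "rfe_frequency", "selected"]

    @property
    def selected_features(self) -> list[str]:
        return self.table.index[self.table["selected"]].tolist()

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "feature", out.index)
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def group_difference_tests(feature_matrix: pd.DataFrame, labels: np.ndarray,
                           ) -> pd.DataFrame:
    """Welch t and Mann-Whitney U p-values per feature between label groups.

    Returns a frame indexed by feature with group means +- sd and two-sided
    p-values.  A feature constant and identical in both groups is degenerate:
    reported with p = 1 and ``degenerate`` = True.
    """
    labels = np.asarray(labels, dtype=bool)
    if labels.sum() < 2 or (~labels).sum() < 2:
        raise ValueError("each group needs at least 2 members")
    rows = []
    for name in feature_matrix.columns:
        x = feature_matrix[name].to_numpy(dtype=float)
        pos, neg = x[labels], x[~labels]
        degenerate = pos.std() == 0 and neg.std() == 0 and pos.mean() == neg.mean()
        if degenerate:
            t_p = mw_p = 1.0
        else:
            t_p = float(stats.ttest_ind(pos, neg, equal_var=False).pvalue)
            mw_p = float(stats.mannwhitneyu(pos, neg, alternative="two-sided",
                                            method="auto").pvalue)
        rows.append({"feature": name,
                     "mean_neg": neg.mean(), "sd_neg": neg.std(ddof=1),
                     "mean_pos": pos.mean(), "sd_pos": pos.std(ddof=1),
                     "t_p": t_p, "mw_p": mw_p, "degenerate": degenerate})
    return pd.DataFrame(rows).set_index("feature")


def _rf_ranking(X: np.ndarray, y: np.ndarray, n_trees: int, seed: int) -> np.ndarray:
    """Feature indices sorted by decreasing random-forest importance."""
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    rf.fit(X, y)
    return np.argsort(-rf.feature_importances_, kind="stable")


def rfe_select(feature_matrix: pd.DataFrame, labels: np.ndarray,
               *, n_trees: int = 50, cv_folds: int = 5,
               sizes: list[int] | None = None, seed: int = 0) -> list[str]:
    """Random-forest RFE: best cross-validated subset size, then final subset.

    Candidate sizes default to 1..p.  Accuracy is the CV criterion; ties in
    accuracy go to the smaller size.
    """
    X = feature_matrix.to_numpy(dtype=float)
    y = np.asarray(labels, dtype=int)
    names = list(feature_matrix.columns)
    p = X.shape[1]
    if p < 2:
        raise ValueError("RFE needs at least 2 features")
    if len(y) < 20:
        raise ValueError("RFE needs at least 20 rows")
    if len(np.unique(y)) < 2:
        raise ValueError("single-class training set")
    sizes = sorted(sizes or range(1, p + 1))

    rng = np.random.default_rng(seed)
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True,
                          random_state=int(rng.integers(2**31)))
    acc = np.zeros((cv_folds, len(sizes)))
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        ranking = _rf_ranking(X[tr], y[tr], n_trees, int(rng.integers(2**31)))
        for j, k in enumerate(sizes):
            cols = ranking[:k]
            rf = RandomForestClassifier(n_estimators=n_trees,
                                        random_state=int(rng.integers(2**31)), n_jobs=1)
            rf.fit(X[tr][:, cols], y[tr])
            acc[fold, j] = (rf.predict(X[te][:, cols]) == y[te]).mean()
    mean_acc = acc.mean(axis=0)
    best_size = sizes[int(np.argmax(mean_acc))]  # argmax takes first = smallest on ties
    final_ranking = _rf_ranking(X, y, n_trees, int(rng.integers(2**31)))
    chosen = sorted(final_ranking[:best_size].tolist())
    return [names[i] for i in chosen]


def feature_frequency(resampled_selections: list[list[str]], cutoff: float,
                      feature_names: list[str] | None = None) -> pd.DataFrame:
    """Per-feature selection frequency over R resampled RFE runs.

    ``selected`` is True when frequency >= cutoff.
    """
    if not resampled_selections:
        raise ValueError("need at least one resampled selection")
    names = feature_names or FEATURE_NAMES
    r = len(resampled_selections)
    counts = {name: 0 for name in names}
    for subset in resampled_selections:
        for name in subset:
            counts[name] += 1
    freq = pd.DataFrame({"rfe_frequency": {n: counts[n] / r for n in names}})
    freq["selected"] = freq["rfe_frequency"] >= cutoff
    return freq


def screen_features(features: pd.DataFrame, positives: list[tuple[str, str]],
                    negative_pool: list[tuple[str, str]], config: RunConfig,
                    n_resamples: int | None = None) -> FeatureScreenReport:
    """Full screening stage: tests on the pooled sample, RFE frequency over resamples.

    ``features`` is a pair-indexed table with the 16 feature columns.  Each
    of the R resamples is a fresh 1:5 training set (all positives + sampled
    negatives) put through ``rfe_select``; the statistical tests run once on
    positives vs the whole negative pool.
    """
    from .ensemble import build_training_set  # local import to avoid a cycle

    r = n_resamples or config.n_resamples
    fmat = features[FEATURE_NAMES]
    labels = np.zeros(len(fmat), dtype=bool)
    pos_set = set(positives)
    labels[[i for i, key in enumerate(fmat.index) if key in pos_set]] = True
    tests = group_difference_tests(fmat, labels)

    selections: list[list[str]] = []
    for i in range(r):
        seed = derive_seed(config.master_seed, "screen-resample", i)
        tset = build_training_set(positives, negative_pool,
                                  config.ratio_neg_per_pos, seed)
        X = fmat.loc[[key for key, _ in tset]]
        y = np.array([lab for _, lab in tset], dtype=int)
        selections.append(rfe_select(X, y, n_trees=config.rfe_ntree,
                                     cv_folds=config.rfe_cv_folds,
                                     seed=derive_seed(config.master_seed, "rfe", i)))
    freq = feature_frequency(selections, config.feature_frequency_cutoff,
                             list(fmat.columns))
    table = tests.join(freq)
    logger.info("screen: %d/%d features at frequency >= %.0f%% over %d resamples",
                int(table["selected"].sum()), len(table),
                100 * config.feature_frequency_cutoff, r)
    return FeatureScreenReport(table=table, cutoff=config.feature_frequency_cutoff)
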