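"""Model criticism: surrogate-feature modes and projection-based classification.

The surrogate test asks whether the *specific* assignment of fitted
first-mode weights to features matters, or whether any linear weighting of
the same features would covary with age (or separate groups) equally well.
Each surrogate permutes the first-mode weights within each block
independently, recomputes the projections, and re-evaluates the statistic;
the original statistic is ranked two-sidedly in the surrogate
distribution with the add-one formula.

Classification trains a linear soft-margin SVM (C = 1, no tuning) on the
latent projections to separate healthy from clinical participants under
stratified ten-fold cross-validation, reporting the ROC AUC per fold and
its mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import ConfigurationError
from .pls import PLSModel

__all__ = [
    "SurrogateDistribution",
    "ClassificationResult",
    "surrogate_feature_test",
    "classify_projections",
]

STATISTICS = ("age_slope_cog", "age_slope_brain", "group_mean_diff")


@dataclass
class SurrogateDistribution:
    statistic_name: str
    original_value: float
    surrogate_values: np.ndarray
    p_value: float
    n_surr: int
    seed: int | None


@dataclass
class ClassificationResult:
    feature_set: tuple
    auc_per_fold: np.ndarray
    auc_mean: float
    n_folds: int
    seed: int | None


def _slope(y, x):
    x = x - x.mean()
    return float((x @ (y - y.mean())) / (x @ x))


def _make_statistic(statistic, age, groups):
    if callable(statistic):
        return statistic
    if statistic == "age_slope_cog":
        if age is None:
            raise ConfigurationError("age vector required for age-slope statistics")
        return lambda xp, yp: _slope(yp, age)
    if statistic == "age_slope_brain":
        if age is None:
            raise ConfigurationError("age vector required for age-slope statistics")
        return lambda xp, yp: _slope(xp, age)
    if statistic == "group_mean_diff":
        if groups is None:
            raise ConfigurationError("group labels required for group_mean_diff")
        g = np.asarray(groups)
        levels = np.unique(g)
        if levels.size != 2:
            raise ConfigurationError("group_mean_diff needs exactly two groups")
        m0, m1 = g == levels[0], g == levels[1]
        # difference of cognitive-projection means, second level minus first
        return lambda xp, yp: float(yp[m1].mean() - yp[m0].mean())
    raise ConfigurationError(f"unknown statistic {statistic!r}; expected {STATISTICS}")


def surrogate_feature_test(
    model: PLSModel,
    Xb: np.ndarray,
    Yc: np.ndarray,
    statistic="age_slope_cog",
    n_surr: int = 1000,
    seed: int | None = None,
    age=None,
    groups=None,
) -> SurrogateDistribution:
    """Compare the fitted first mode against randomly re-weighted features.

    Each surrogate shuffles the assignment of first-mode weights to
    features (independently within the brain and cognition blocks, both
    blocks shuffled per surrogate), recomputes first-mode projections and
    the statistic.  p is two-sided: the add-one rank of ``|original|``
    among ``|surrogates|``.
    """
    Xb = np.asarray(Xb, dtype=float)
    Yc = np.asarray(Yc, dtype=float)
    wx = model.x_weights[:, 0]
    wy = model.y_weights[:, 0]
    if age is not None:
        age = np.asarray(age, dtype=float)
    stat = _make_statistic(statistic, age, groups)

    xp0 = Xb @ wx
    yp0 = Yc @ wy
    if np.ptp(xp0) == 0 or np.ptp(yp0) == 0:
        raise ConfigurationError("constant projections; surrogate test undefined")
    original = float(stat(xp0, yp0))

    rng = np.random.default_rng(seed)
    values = np.empty(n_surr)
    for i in range(n_surr):
        xp = Xb @ wx[rng.permutation(wx.size)]
        yp = Yc @ wy[rng.permutation(wy.size)]
        values[i] = stat(xp, yp)
    p = (1.0 + np.sum(np.abs(values) >= abs(original))) / (n_surr + 1.0)
    name = statistic if isinstance(statistic, str) else getattr(statistic, "__name__", "custom")
    return SurrogateDistribution(name, original, values, float(p), n_surr, seed)


def classify_projections(
    scores: pd.DataFrame,
    labels,
    feature_set,
    seed: int | None = None,
    n_folds: int = 10,
    C: float = 1.0,
) -> ClassificationResult:
    """Linear-SVM classification of clinical status from projections.

    ``scores`` holds one column per projection; ``feature_set`` names the
    columns to use.  Stratified ``n_folds``-fold cross-validation; within
    each training fold features are standardized and a linear SVM (fixed
    C) fitted; AUC is computed from decision values on the held-out fold
    and averaged over folds.
    """
    y = np.asarray(labels)
    feature_set = tuple(feature_set)
    missing = [f for f in feature_set if f not in scores.columns]
    if missing:
        raise ConfigurationError(f"unknown projection columns: {missing}")
    X = scores[list(feature_set)].to_numpy(dtype=float)
    if len(y) != len(X) or len(y) < 20:
        raise ConfigurationError("need aligned labels and at least 20 subjects")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ConfigurationError("exactly two classes required")
    if counts.min() < n_folds:
        raise ConfigurationError(
            f"minority class has {counts.min()} subjects; cannot stratify "
            f"{n_folds} folds with both classes present"
        )
    y_bin = (y == classes[1]).astype(int)

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    aucs = np.empty(n_folds)
    for k, (tr, te) in enumerate(skf.split(X, y_bin)):
        scaler = StandardScaler().fit(X[tr])
        clf = SVC(kernel="linear", C=C).fit(scaler.transform(X[tr]), y_bin[tr])
        decision = clf.decision_function(scaler.transform(X[te]))
        aucs[k] = roc_auc_score(y_bin[te], decision)
    return ClassificationResult(feature_set, aucs, float(aucs.mean()), n_folds, seed)
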