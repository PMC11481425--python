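"""SVM classification of relationship type from dIFC features.

Samples are (dyad, hand condition, timepoint) triples; features are the
inter-brain correlations of the selected channel pairs at that timepoint.
The default split is group-aware (all samples of a dyad land on the same
side of the train/test split); ``paper_split=True`` reproduces the pooled
random shuffle in which a dyad's timepoints may straddle the split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import auc as sk_auc
from sklearn.metrics import classification_report, roc_curve
from sklearn.model_selection import (GridSearchCV, GroupShuffleSplit, KFold,
                                     StratifiedGroupKFold, train_test_split)
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .difc import DIFCTensor, split_halves

__all__ = [
    "FeatureMatrix",
    "ClassReport",
    "DEFAULT_GRID",
    "build_features",
    "train_eval",
    "roc_auc",
    "compare_halves",
]

#: hyperparameter grid searched by 10-fold CV (rbf and linear kernels)
DEFAULT_GRID: list[dict] = [
    {"svc__kernel": ["rbf"], "svc__C": [0.1, 1.0, 10.0, 100.0],
     "svc__gamma": ["scale", 0.01, 0.1]},
    {"svc__kernel": ["linear"], "svc__C": [0.1, 1.0, 10.0, 100.0]},
]


@dataclass
class FeatureMatrix:
    """Samples x features design for the relationship classifier."""

    X: np.ndarray
    y: np.ndarray          # 0 = stranger, 1 = lover
    groups: np.ndarray     # pair id per sample
    feature_names: list[str]
    half: str = "all"

    def __post_init__(self) -> None:
        if not (len(self.X) == len(self.y) == len(self.groups)):
            raise ValueError("X, y and groups must share the sample axis")


@dataclass
class ClassReport:
    """Held-out test metrics in the detailed-classification-report shape."""

    half: str
    report: dict
    accuracy: float
    auc: float
    roc: tuple[np.ndarray, np.ndarray, np.ndarray]
    best_params: dict
    seed: int
    n_train: int
    n_test: int

    def to_table(self) -> pd.DataFrame:
        """Rows: class 0, class 1, accuracy, macro avg, weighted avg."""
        rows = []
        for key in ("0", "1"):
            r = self.report[key]
            rows.append([key, r["precision"], r["recall"], r["f1-score"],
                         int(r["support"])])
        rows.append(["accuracy", np.nan, np.nan, self.accuracy, self.n_test])
        for key in ("macro avg", "weighted avg"):
            r = self.report[key]
            rows.append([key, r["precision"], r["recall"], r["f1-score"],
                         int(r["support"])])
        return pd.DataFrame(rows, columns=["type", "precision", "recall",
                                           "f1-score", "support"])


def build_features(tensors: list[DIFCTensor], half: str = "all",
                   channel_pairs: list[tuple[str, str]] | None = None
                   ) -> FeatureMatrix:
    """Pool dIFC timepoints into a feature matrix.

    ``half`` restricts to the first or second half of the window axis;
    ``channel_pairs`` restricts the feature set (default: every male x
    female channel pair).  Samples containing NaN are dropped.
    """
    if half not in ("all", "first", "second"):
        raise ValueError(f"unknown half {half!r}")
    ref = tensors[0]
    for t in tensors:
        if t.window != ref.window or t.male_channels != ref.male_channels \
                or t.female_channels != ref.female_channels:
            raise ValueError("tensors must share window spec and channel axes")

    if channel_pairs is None:
        channel_pairs = [(m, f) for m in ref.male_channels
                         for f in ref.female_channels]
    if not channel_pairs:
        raise ValueError("empty channel-pair selection")
    mi = [ref.male_channels.index(m) for m, _ in channel_pairs]
    fi = [ref.female_channels.index(f) for _, f in channel_pairs]
    names = [f"{m}-{f}" for m, f in channel_pairs]

    X_rows, y_rows, g_rows = [], [], []
    for t in tensors:
        if half != "all":
            first, second = split_halves(t)
            t_use = first if half == "first" else second
        else:
            t_use = t
        feats = t_use.values[mi, fi, :]          # (n_features, n_windows)
        for w in range(t_use.n_windows):
            X_rows.append(feats[:, w])
            y_rows.append(t_use.relationship)
            g_rows.append(t_use.pair_id)
    X = np.asarray(X_rows)
    y = np.asarray(y_rows)
    groups = np.asarray(g_rows)
    keep = ~np.isnan(X).any(axis=1)
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} samples with NaN features")
    return FeatureMatrix(X=X[keep], y=y[keep], groups=groups[keep],
                         feature_names=names, half=half)


def _split(fm: FeatureMatrix, test_frac: float, seed: int, paper_split: bool):
    if paper_split:
        return train_test_split(np.arange(len(fm.y)), test_size=test_frac,
                                random_state=seed, shuffle=True)
    gss = GroupShuffleSplit(n_splits=1, test_size=test_frac, random_state=seed)
    train, test = next(gss.split(fm.X, fm.y, fm.groups))
    return train, test


def train_eval(fm: FeatureMatrix, test_frac: float = 0.30, cv_folds: int = 10,
               grid: list[dict] | None = None, seed: int = 0,
               paper_split: bool = False, max_redraws: int = 10) -> ClassReport:
    """Grid-searched SVM with a held-out test set.

    70/30 shuffle split (group-aware by dyad unless ``paper_split``),
    ``cv_folds``-fold cross-validated grid search on the training portion
    only, final refit on the full training set, metrics on the test set.
    Feature standardization is fitted on the training data only (inside the
    pipeline).  A split leaving a single class on either side is redrawn
    with a logged seed bump.
    """
    if len(np.unique(fm.y)) < 2:
        raise ValueError("both classes required")
    grid = grid if grid is not None else DEFAULT_GRID

    use_seed = seed
    for _ in range(max_redraws):
        train, test = _split(fm, test_frac, use_seed, paper_split)
        if len(np.unique(fm.y[train])) == 2 and len(np.unique(fm.y[test])) == 2:
            break
        warnings.warn(f"single-class split at seed {use_seed}; redrawing")
        use_seed += 1
    else:
        raise ValueError("could not draw a two-class split")

    pipe = Pipeline([("scale", StandardScaler()),
                     ("svc", SVC(random_state=use_seed))])
    if paper_split:
        cv = KFold(n_splits=cv_folds, shuffle=True, random_state=use_seed)
        cv_groups = None
    else:
        # stratify the group folds so every CV training fold sees both
        # classes even on small cohorts
        per_class = [len(np.unique(fm.groups[train][fm.y[train] == c]))
                     for c in np.unique(fm.y[train])]
        n_splits = max(2, min(cv_folds, min(per_class)))
        cv = StratifiedGroupKFold(n_splits=n_splits, shuffle=True,
                                  random_state=use_seed)
        cv_groups = fm.groups[train]
    search = GridSearchCV(pipe, grid, cv=cv, scoring="accuracy", n_jobs=1)
    search.fit(fm.X[train], fm.y[train], groups=cv_groups)

    model = search.best_estimator_
    y_pred = model.predict(fm.X[test])
    scores = model.decision_function(fm.X[test])
    rep = classification_report(fm.y[test], y_pred, output_dict=True,
                                zero_division=0)
    (fpr, tpr, thr), auc_val = roc_auc(scores, fm.y[test])
    return ClassReport(half=fm.half, report=rep,
                       accuracy=float(rep["accuracy"]), auc=auc_val,
                       roc=(fpr, tpr, thr),
                       best_params=dict(search.best_params_), seed=use_seed,
                       n_train=len(train), n_test=len(test))


def roc_auc(scores: np.ndarray, labels: np.ndarray):
    """ROC curve and AUC (probability a positive outranks a negative,
    ties counting one half)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes required for a ROC curve")
    fpr, tpr, thr = roc_curve(labels, scores)
    return (fpr, tpr, thr), float(sk_auc(fpr, tpr))


def compare_halves(reports: list[ClassReport]) -> pd.DataFrame:
    """Descriptive accuracy/AUC table ordered best-first (ties share rank).

    Purely descriptive: no significance claim is attached to the ordering.
    """
    if not reports:
        raise ValueError("no reports to compare")
    df = pd.DataFrame({
        "half": [r.half for r in reports],
        "accuracy": [r.accuracy for r in reports],
        "auc": [r.auc for r in reports],
    })
    df = df.sort_values(["auc", "accuracy"], ascending=False,
                        kind="stable").reset_index(drop=True)
    df["rank"] = df[["auc", "accuracy"]].apply(tuple, axis=1).rank(
        method="min", ascending=False).astype(int)
    return df
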