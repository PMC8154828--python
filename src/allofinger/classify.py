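"""Supervised activator/inhibitor prediction and its evaluation protocol.

Three model families are compared — logistic regression (LR, the baseline),
a linear-kernel support vector machine (SVM) and a random forest (RF, 1000
trees, Gini splits). Evaluation follows the study protocol:

* a 70/30 random holdout split;
* 10-fold cross-validation on contiguous, unshuffled blocks of the input
  row order (earlier folds absorb the remainder: n=133 gives three folds of
  14 and seven of 13);
* a learning curve — median holdout accuracy over 100 random subsets per
  subset fraction;
* a feature-type ablation that drops one metric block (best_score,
  score_rms or pose_spread) panel-wide and compares fold-level balanced
  accuracies via a standardized-difference z score.

The positive class defaults to "activator" (the larger class); balanced
accuracy — the mean of the true-positive and true-negative rates — is the
headline metric because the classes are imbalanced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from .features import METRICS, FeatureMatrix

FAMILIES = ("LR", "SVM", "RF")
POSITIVE_CLASS = "activator"


def _xy(X, y=None):
    if isinstance(X, FeatureMatrix):
        if y is None:
            y = X.labels
        X = X.X
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy()
    if y is None:
        raise ValueError("labels are required")
    y = np.asarray(pd.Series(y).to_numpy())
    return np.asarray(X, float), y


# ------------------------------------------------------------------ metrics


@dataclass
class EvalReport:
    """Confusion counts and derived binary-classification metrics."""

    model: str
    split: str
    tp: int
    fp: int
    tn: int
    fn: int
    positive_class: str = POSITIVE_CLASS
    balanced_accuracy: float = field(init=False)
    precision: float = field(init=False)
    recall: float = field(init=False)
    false_positive_rate: float = field(init=False)
    false_negative_rate: float = field(init=False)
    accuracy: float = field(init=False)

    def __post_init__(self) -> None:
        def ratio(num: int, den: int, name: str) -> float:
            if den == 0:
                warnings.warn(f"{name} undefined (zero denominator); reported as NaN")
                return float("nan")
            return num / den

        tpr = ratio(self.tp, self.tp + self.fn, "recall")
        tnr = ratio(self.tn, self.tn + self.fp, "specificity")
        self.recall = tpr
        self.precision = ratio(self.tp, self.tp + self.fp, "precision")
        self.false_positive_rate = ratio(self.fp, self.fp + self.tn, "FPR")
        self.false_negative_rate = ratio(self.fn, self.fn + self.tp, "FNR")
        self.balanced_accuracy = (tpr + tnr) / 2
        total = self.tp + self.fp + self.tn + self.fn
        self.accuracy = ratio(self.tp + self.tn, total, "accuracy")

    @classmethod
    def from_predictions(
        cls,
        y_true: Sequence[str],
        y_pred: Sequence[str],
        positive_class: str = POSITIVE_CLASS,
        model: str = "",
        split: str = "",
    ) -> "EvalReport":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        pos_t = y_true == positive_class
        pos_p = y_pred == positive_class
        return cls(
            model=model,
            split=split,
            tp=int(np.sum(pos_t & pos_p)),
            fp=int(np.sum(~pos_t & pos_p)),
            tn=int(np.sum(~pos_t & ~pos_p)),
            fn=int(np.sum(pos_t & ~pos_p)),
            positive_class=positive_class,
        )

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "split": self.split,
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "balanced_accuracy": self.balanced_accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "false_positive_rate": self.false_positive_rate,
            "false_negative_rate": self.false_negative_rate,
            "accuracy": self.accuracy,
        }


# ------------------------------------------------------------------- splits


def holdout_split(
    y: Sequence[str], train_frac: float = 0.7, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Random train/test split with |train| = floor(train_frac * n).

    Redraws (up to 100 times) until both classes appear in the training set.
    """
    y = np.asarray(pd.Series(y).to_numpy())
    n = len(y)
    if n < 2:
        raise ValueError("need at least 2 samples")
    if len(np.unique(y)) < 2:
        raise ValueError("single-class data cannot be split for classification")
    n_train = int(np.floor(train_frac * n))
    if n_train < 1 or n_train >= n:
        raise ValueError(f"train_frac={train_frac} leaves an empty train or test set")
    rng = np.random.default_rng(seed)
    for _ in range(100):
        perm = rng.permutation(n)
        train, test = perm[:n_train], perm[n_train:]
        if len(np.unique(y[train])) == 2:
            return np.sort(train), np.sort(test)
    raise ValueError("could not draw a training set containing both classes")


def contiguous_folds(n: int, k: int) -> list[np.ndarray]:
    """Unshuffled contiguous CV folds; earlier folds absorb the remainder."""
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    return [np.asarray(f) for f in np.array_split(np.arange(n), k)]


# ------------------------------------------------------------------- models


def train_classifier(X, y, family: str = "SVM", seed: int = 0, **overrides):
    """Fit one of the three model families with the protocol's settings."""
    X, y = _xy(X, y)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    if np.any(X.std(axis=0) == 0):
        warnings.warn("constant feature columns present; models may ignore them")
    if family == "LR":
        # sklearn defaults already give the L2 penalty with lbfgs
        model = LogisticRegression(tol=1e-4, solver="lbfgs", max_iter=1000, **overrides)
    elif family == "SVM":
        model = SVC(kernel="linear", **overrides)
    elif family == "RF":
        model = RandomForestClassifier(
            n_estimators=1000, criterion="gini", random_state=seed, **overrides
        )
    else:
        raise ValueError(f"unknown model family {family!r}; choose from {FAMILIES}")
    model.fit(X, y)
    return model


def evaluate(
    model, X_test, y_test, positive_class: str = POSITIVE_CLASS, split: str = "holdout"
) -> EvalReport:
    X_test, y_test = _xy(X_test, y_test)
    if len(y_test) == 0:
        raise ValueError("empty test set")
    y_pred = model.predict(X_test)
    return EvalReport.from_predictions(
        y_test, y_pred, positive_class, model=type(model).__name__, split=split
    )


# --------------------------------------------------------------------- CV


@dataclass
class CVResult:
    """Per-fold reports plus summary of an unshuffled k-fold CV."""

    family: str
    reports: list[EvalReport]
    fold_sizes: list[int]

    @property
    def balanced_accuracies(self) -> np.ndarray:
        return np.array([r.balanced_accuracy for r in self.reports])

    @property
    def mean_balanced_accuracy(self) -> float:
        return float(np.nanmean(self.balanced_accuracies))

    @property
    def sd_balanced_accuracy(self) -> float:
        return float(np.nanstd(self.balanced_accuracies, ddof=1))

    def to_frame(self) -> pd.DataFrame:
        rows = [r.to_dict() | {"fold": i} for i, r in enumerate(self.reports)]
        return pd.DataFrame(rows)


def cross_validate(
    X,
    y=None,
    family: str = "SVM",
    k: int = 10,
    seed: int = 0,
    positive_class: str = POSITIVE_CLASS,
) -> CVResult:
    """k-fold CV on contiguous unshuffled blocks of the input row order."""
    X, y = _xy(X, y)
    folds = contiguous_folds(len(y), k)
    reports = []
    for i, fold in enumerate(folds):
        train = np.setdiff1d(np.arange(len(y)), fold)
        if len(np.unique(y[train])) < 2:
            raise ValueError(f"fold {i}: training complement has a single class")
        model = train_classifier(X[train], y[train], family=family, seed=seed)
        reports.append(
            evaluate(model, X[fold], y[fold], positive_class, split=f"fold-{i}")
        )
    return CVResult(family, reports, [len(f) for f in folds])


def cv_predictions(
    X, y=None, family: str = "SVM", k: int = 10, seed: int = 0
) -> np.ndarray:
    """Out-of-fold predictions under the same unshuffled k-fold protocol."""
    X, y = _xy(X, y)
    preds = np.empty(len(y), dtype=object)
    for i, fold in enumerate(contiguous_folds(len(y), k)):
        train = np.setdiff1d(np.arange(len(y)), fold)
        model = train_classifier(X[train], y[train], family=family, seed=seed)
        preds[fold] = model.predict(X[fold])
    return preds.astype(str)


# ----------------------------------------------------------- learning curve


@dataclass
class LearningCurve:
    fractions: np.ndarray
    median_accuracy: np.ndarray
    median_balanced_accuracy: np.ndarray
    n_samples: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fraction": self.fractions,
                "median_accuracy": self.median_accuracy,
                "median_balanced_accuracy": self.median_balanced_accuracy,
            }
        )


def learning_curve(
    X,
    y=None,
    fractions: Sequence[float] | None = None,
    n_samples: int = 100,
    family: str = "SVM",
    seed: int = 0,
    train_frac: float = 0.7,
) -> LearningCurve:
    """Median holdout accuracy vs training-library size.

    For each subset fraction, ``n_samples`` random subsets are drawn; each is
    split 70/30 and scored on its test part. The headline statistic is the
    median plain accuracy (the balanced version is reported alongside).
    """
    X, y = _xy(X, y)
    n = len(y)
    if fractions is None:
        fractions = np.round(np.arange(0.2, 1.0001, 0.1), 10)
    fractions = np.asarray(fractions, float)
    if np.any((fractions <= 0) | (fractions > 1)):
        raise ValueError("fractions must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    med_acc, med_bal = [], []
    for frac in fractions:
        size = max(2, int(round(frac * n)))
        accs, bals = [], []
        for _ in range(n_samples):
            for _attempt in range(100):
                subset = rng.choice(n, size=size, replace=False)
                if len(np.unique(y[subset])) == 2:
                    break
            else:
                raise ValueError("subset too small to contain both classes")
            tr, te = holdout_split(
                y[subset], train_frac=train_frac, seed=int(rng.integers(2**31))
            )
            model = train_classifier(X[subset][tr], y[subset][tr], family=family)
            rep = evaluate(model, X[subset][te], y[subset][te])
            accs.append(rep.accuracy)
            bals.append(rep.balanced_accuracy)
        med_acc.append(float(np.nanmedian(accs)))
        med_bal.append(float(np.nanmedian(bals)))
    return LearningCurve(fractions, np.array(med_acc), np.array(med_bal), n_samples)


# ---------------------------------------------------------------- ablation


@dataclass
class AblationResult:
    """Fold-level comparison of full vs one-feature-type-ablated CV."""

    feature_type: str
    full_scores: np.ndarray
    ablated_scores: np.ndarray
    z: float
    note: str = ""


def ablation_z(full: np.ndarray, ablated: np.ndarray) -> tuple[float, str]:
    """|standardized mean difference| of two fold-score samples.

    z = |mean_f - mean_a| / sqrt(s_f^2/k + s_a^2/k); both-degenerate
    variances give z = 0 with a note.
    """
    full = np.asarray(full, float)
    ablated = np.asarray(ablated, float)
    k = len(full)
    vf, va = np.nanvar(full, ddof=1), np.nanvar(ablated, ddof=1)
    denom = np.sqrt(vf / k + va / k)
    diff = abs(np.nanmean(full) - np.nanmean(ablated))
    if denom == 0:
        return 0.0, "zero variance in both fold sets" if diff == 0 else "zero variance"
    return float(diff / denom), ""


def feature_ablation(
    fm: FeatureMatrix,
    family: str = "SVM",
    k: int = 10,
    seed: int = 0,
    positive_class: str = POSITIVE_CLASS,
) -> list[AblationResult]:
    """Drop each metric's panel-wide column block in turn and re-run CV."""
    for m in METRICS:
        if not fm.metric_columns(m):
            raise ValueError(f"feature matrix lacks the {m!r} column block")
    full = cross_validate(
        fm.X, fm.labels, family=family, k=k, seed=seed, positive_class=positive_class
    ).balanced_accuracies
    out = []
    for m in METRICS:
        keep = [c for c in fm.X.columns if not c.endswith("." + m)]
        abl = cross_validate(
            fm.X[keep],
            fm.labels,
            family=family,
            k=k,
            seed=seed,
            positive_class=positive_class,
        ).balanced_accuracies
        z, note = ablation_z(full, abl)
        out.append(AblationResult(m, full, abl, z, note))
    return out
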