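"""Counterbalanced 10-fold cross-validation, classifier backends, chance
baselines, paired fold-level tests, and the competition scoring rule.

Folds are built by a greedy stratified assignment approximately
counterbalancing diagnosis, gender, age, handedness, IQ, medication
status and site; the documented imbalance cost is the sum over strata,
levels and folds of the absolute deviation of the fold's level count
from proportional allocation.  Classifier families are the logistic
classifier and linear / quadratic / cubic / RBF-kernel SVMs.  Accuracies
are percentages; the chance baseline is majority-class guessing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix
from sklearn.svm import SVC

CLASS_ORDER = ("control", "adhd-c", "adhd-i")
ADHD_CLASSES = frozenset({"adhd-c", "adhd-i", "adhd"})
DEFAULT_STRATA = ("diagnosis", "gender", "age", "handedness",
                  "full4_iq", "medication", "site")

CLASSIFIER_FAMILIES = ("logistic", "linear-svm", "quadratic-svm",
                       "cubic-svm", "rbf-svm")


@dataclass
class FoldAssignment:
    """Participant-to-fold mapping with its balance diagnostics."""

    fold: np.ndarray  # int fold index per participant, 0..k-1
    k: int
    seed: int
    strata: tuple[str, ...]
    balance_report: pd.DataFrame = field(repr=False, default=None)

    def train_test(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        """(train indices, test indices) for fold i."""
        test = np.flatnonzero(self.fold == i)
        train = np.flatnonzero(self.fold != i)
        return train, test

    @property
    def fold_sizes(self) -> np.ndarray:
        return np.bincount(self.fold, minlength=self.k)


def _stratum_levels(table: pd.DataFrame, stratum: str) -> np.ndarray:
    """Coarse categorical encoding of one balancing variable."""
    col = table[stratum]
    if stratum in ("diagnosis", "site", "gender", "iq_measure"):
        return col.astype(str).to_numpy()
    vals = pd.to_numeric(col, errors="coerce")
    if stratum == "handedness":
        out = np.where(vals > 0, "right", "left")
    elif stratum == "medication":
        out = np.where(vals > 0, "medicated", "none")
    else:  # continuous: quartile bins
        try:
            binned = pd.qcut(vals, 4, labels=False, duplicates="drop")
        except ValueError:
            binned = pd.Series(np.zeros(len(vals)))
        out = np.asarray(binned, dtype=object).astype(str)
    out = np.asarray(out, dtype=object)
    out[vals.isna().to_numpy()] = "missing"
    return out.astype(str)


def imbalance_cost(fold: np.ndarray, strata_labels: dict[str, np.ndarray],
                   k: int) -> float:
    """Sum over strata of absolute deviation from proportional allocation."""
    n = len(fold)
    sizes = np.bincount(fold, minlength=k)
    cost = 0.0
    for labels in strata_labels.values():
        for level in np.unique(labels):
            n_level = int((labels == level).sum())
            for f in range(k):
                count = int(((labels == level) & (fold == f)).sum())
                cost += abs(count - n_level * sizes[f] / n)
    return cost


def make_counterbalanced_folds(table: pd.DataFrame, k: int = 10,
                               strata: tuple[str, ...] = DEFAULT_STRATA,
                               seed: int = 0) -> FoldAssignment:
    """Greedy stratified fold assignment, deterministic given the seed.

    Participants are processed rarest stratum-combination first (after a
    seeded shuffle); each is placed in the fold that currently holds the
    fewest participants sharing its stratum levels, subject to fold sizes
    differing by at most one.  Emits a per-fold balance report.
    """
    n = len(table)
    if k > n:
        raise ValueError(f"k={k} exceeds number of participants {n}")
    strata = tuple(s for s in strata if s in table.columns)
    labels = {s: _stratum_levels(table, s) for s in strata}
    keys = np.array(["|".join(labels[s][i] for s in strata) for i in range(n)])
    key_counts = pd.Series(keys).value_counts()
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    order = order[np.argsort([key_counts[keys[i]] for i in order], kind="stable")]

    q, rem = divmod(n, k)
    fold = np.full(n, -1, dtype=int)
    sizes = np.zeros(k, dtype=int)
    counts: dict[tuple[str, str], np.ndarray] = {}
    for i in order:
        eligible = [f for f in range(k)
                    if sizes[f] < q or (sizes[f] == q and (sizes > q).sum() < rem)]
        best_f, best_score = None, None
        for f in eligible:
            score = 0
            for s in strata:
                score += counts.get((s, labels[s][i]), np.zeros(k, dtype=int))[f]
            key = (score, sizes[f], f)
            if best_score is None or key < best_score:
                best_score, best_f = key, f
        fold[i] = best_f
        sizes[best_f] += 1
        for s in strata:
            counts.setdefault((s, labels[s][i]), np.zeros(k, dtype=int))[best_f] += 1

    report_rows = []
    for s in strata:
        for level in np.unique(labels[s]):
            row = {"stratum": s, "level": level}
            for f in range(k):
                row[f"fold{f}"] = int(((labels[s] == level) & (fold == f)).sum())
            report_rows.append(row)
    report = pd.DataFrame(report_rows)
    return FoldAssignment(fold, k, seed, strata, report)


# ---------------------------------------------------------------------------
# classifiers
# ---------------------------------------------------------------------------


def make_classifier(family: str, C: float = 1.0, seed: int = 0):
    """Unfitted classifier of the named family with toolkit-default settings."""
    if family == "logistic":
        # small ridge penalty, multinomial for the three-way task
        return LogisticRegression(C=1e4, max_iter=2000, random_state=seed)
    if family == "linear-svm":
        return SVC(kernel="linear", C=C, random_state=seed)
    if family == "quadratic-svm":
        return SVC(kernel="poly", degree=2, C=C, random_state=seed)
    if family == "cubic-svm":
        return SVC(kernel="poly", degree=3, C=C, random_state=seed)
    if family == "rbf-svm":
        return SVC(kernel="rbf", gamma="scale", C=C, random_state=seed)
    raise ValueError(f"unknown classifier family {family!r}; "
                     f"choose from {CLASSIFIER_FAMILIES}")


def train_classifier(X: np.ndarray, y, family: str, C: float = 1.0, seed: int = 0):
    """Fit a classifier; refuses single-class training labels."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    clf = make_classifier(family, C=C, seed=seed)
    return clf.fit(np.asarray(X, dtype=float), y)


def collapse_binary(labels) -> np.ndarray:
    """Collapse ADHD subtypes into one class for the binary task."""
    labels = np.asarray(labels, dtype=object)
    return np.where(labels == "control", "control", "adhd").astype(str)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CVResult:
    """Per-fold train/test accuracies (percent) and confusion matrices."""

    test_acc: np.ndarray
    train_acc: np.ndarray
    confusions: list[np.ndarray]
    classes: tuple[str, ...]

    @property
    def mean_test(self) -> float:
        return float(self.test_acc.mean())

    @property
    def sd_test(self) -> float:
        return float(self.test_acc.std(ddof=1))

    @property
    def mean_train(self) -> float:
        return float(self.train_acc.mean())

    @property
    def sd_train(self) -> float:
        return float(self.train_acc.std(ddof=1))

    def summary(self) -> str:
        return (f"test {self.mean_test:.1f} ± {self.sd_test:.1f}%, "
                f"train {self.mean_train:.1f} ± {self.sd_train:.1f}%")


def cross_validate(features, y, folds: FoldAssignment, family: str = "logistic",
                   task: str = "three-way", C: float = 1.0, seed: int = 0) -> CVResult:
    """Counterbalanced k-fold cross-validation of one diagnostic pipeline.

    ``features`` is either a precomputed (n x p) matrix or a callable
    ``(train_idx, test_idx) -> (X_train, X_test)`` that fits all its
    transforms (imputation, scaling, PCA bases, cluster selection) on the
    training rows only — the leakage-safe path for fitted feature
    extractors.  ``task`` is "binary" (ADHD subtypes collapsed) or
    "three-way".
    """
    y = np.asarray(y, dtype=object).astype(str)
    if task == "binary":
        y = collapse_binary(y)
    elif task != "three-way":
        raise ValueError(f"unknown task {task!r}")
    classes = tuple(sorted(np.unique(y)))
    test_acc = np.zeros(folds.k)
    train_acc = np.zeros(folds.k)
    confusions = []
    for i in range(folds.k):
        train, test = folds.train_test(i)
        if callable(features):
            X_train, X_test = features(train, test)
        else:
            X = np.asarray(features, dtype=float)
            X_train, X_test = X[train], X[test]
        clf = train_classifier(X_train, y[train], family, C=C, seed=seed)
        pred_train = clf.predict(X_train)
        pred_test = clf.predict(X_test)
        train_acc[i] = 100.0 * np.mean(pred_train == y[train])
        test_acc[i] = 100.0 * np.mean(pred_test == y[test])
        confusions.append(confusion_matrix(y[test], pred_test, labels=classes))
    return CVResult(test_acc, train_acc, confusions, classes)


# ---------------------------------------------------------------------------
# baselines, tests, scoring
# ---------------------------------------------------------------------------


def chance_baseline(labels) -> float:
    """Accuracy (%) of always guessing the majority class.

    Ties are broken by the documented class order (control, ADHD-C,
    ADHD-I); the accuracy is unaffected by which tied class is chosen.
    """
    labels = np.asarray(labels, dtype=object).astype(str)
    if labels.size == 0:
        raise ValueError("empty label vector")
    counts = pd.Series(labels).value_counts()
    order = {c: i for i, c in enumerate(CLASS_ORDER)}
    best = sorted(counts.index, key=lambda c: (-counts[c], order.get(c, len(order))))[0]
    return 100.0 * counts[best] / labels.size


def paired_onetailed_ttest(acc_a, acc_b) -> tuple[float, float, int]:
    """One-tailed paired t-test of fold accuracies, direction a > b.

    Returns ``(t, p, df)`` with df = n - 1 (9 for 10 folds).  A zero
    standard deviation of the differences degenerates to p -> 0, 0.5 or
    1 according to the sign of the mean difference, with a warning.
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("accuracy vectors must be 1D of equal length")
    d = a - b
    n = d.size
    df = n - 1
    sd = d.std(ddof=1)
    if sd == 0:
        warnings.warn("zero variance of paired differences; p degenerate")
        mean = d.mean()
        p = 0.0 if mean > 0 else (1.0 if mean < 0 else 0.5)
        t = np.inf if mean > 0 else (-np.inf if mean < 0 else 0.0)
        return float(t), float(p), df
    t = d.mean() / (sd / np.sqrt(n))
    p = float(sps.t.sf(t, df))
    return float(t), p, df


def competition_score(predicted, true) -> float:
    """Points: 1 per exact diagnosis, 0.5 for ADHD with the wrong subtype."""
    predicted = np.asarray(predicted, dtype=object).astype(str)
    true = np.asarray(true, dtype=object).astype(str)
    if predicted.shape != true.shape:
        raise ValueError("prediction and truth lengths differ")
    valid = set(CLASS_ORDER)
    score = 0.0
    for p, t in zip(predicted, true):
        if p not in valid or t not in valid:
            raise ValueError(f"unknown label in ({p!r}, {t!r})")
        if p == t:
            score += 1.0
        elif p in ADHD_CLASSES and t in ADHD_CLASSES:
            score += 0.5
    return score
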