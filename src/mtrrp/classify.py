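"""Group statistics and the SVM classification protocol.

Thin, leakage-safe wrappers over scipy and scikit-learn:

* one-way ANOVA per feature with partial eta squared and Bonferroni
  correction across the whole comparison family;
* Pearson-|r| feature ranking against the (numeric) group labels;
* SVM with leave-one-out cross-validation, where feature ranking and
  standardization are recomputed inside every fold on the training rows
  only;
* a label-shuffling permutation test that reruns the full LOOCV protocol
  (including in-fold feature re-selection) for each shuffle, with the
  +1-corrected p-value p = (1 + #{null >= observed}) / (1 + n_perm).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .eeg import FeatureTable
from .signals import ParameterError

logger = logging.getLogger("mtrrp")


class DesignError(ValueError):
    """The group design cannot support the requested analysis."""


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnovaResult:
    feature: str
    f_statistic: float
    df_between: int
    df_within: int
    p_raw: float
    p_adjusted: float       # Bonferroni over the whole family
    partial_eta_sq: float   # F*df1 / (F*df1 + df2)


def _as_table(table) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if isinstance(table, FeatureTable):
        return table.X, table.labels.to_numpy(), table.feature_names
    X = np.asarray(table, dtype=float)
    return X, None, [f"f{i}" for i in range(X.shape[1])]


def groupwise_anova(table, labels=None,
                    features: list[str] | None = None) -> list[AnovaResult]:
    """One-way ANOVA per feature across groups, Bonferroni-corrected.

    ``features`` restricts (and orders) the tested columns; the Bonferroni
    family is the set of tests actually run.
    """
    X, lab, names = _as_table(table)
    if labels is not None:
        lab = np.asarray(labels)
    if lab is None:
        raise ParameterError("labels are required")
    groups = pd.unique(lab)
    if len(groups) < 2:
        raise DesignError("ANOVA needs at least 2 groups")
    masks = [lab == g for g in groups]
    for g, mk in zip(groups, masks):
        if mk.sum() < 2:
            raise DesignError(f"group {g!r} has fewer than 2 subjects")
    if features is not None:
        idx = [names.index(f) for f in features]
    else:
        idx = list(range(X.shape[1]))
        features = [names[i] for i in idx]
    df1 = len(groups) - 1
    df2 = len(lab) - len(groups)
    n_tests = len(idx)
    out = []
    for name, j in zip(features, idx):
        samples = [X[mk, j] for mk in masks]
        f, p = _stats.f_oneway(*samples)
        if not np.isfinite(f):  # identical values in all groups
            f, p = 0.0, 1.0
        eta = f * df1 / (f * df1 + df2)
        out.append(AnovaResult(feature=name, f_statistic=float(f),
                               df_between=df1, df_within=df2,
                               p_raw=float(p),
                               p_adjusted=float(min(1.0, p * n_tests)),
                               partial_eta_sq=float(eta)))
    return out


def pairwise_comparisons(values: np.ndarray, labels: np.ndarray) -> dict[tuple, float]:
    """Post-hoc two-sample t-tests for every group pair, Bonferroni-adjusted."""
    groups = list(pd.unique(labels))
    pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1:]]
    out = {}
    for a, b in pairs:
        _, p = _stats.ttest_ind(values[labels == a], values[labels == b])
        out[(a, b)] = float(min(1.0, p * len(pairs)))
    return out


# ---------------------------------------------------------------------------
# Feature ranking
# ---------------------------------------------------------------------------

def select_features_pearson(X: np.ndarray, y: np.ndarray, k: int = 50) -> np.ndarray:
    """Indices of the top-k features by |Pearson r| with the labels.

    Ties in |r| break toward the earlier column index (stable ordering);
    zero-variance features get |r| = 0 with a logged warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if k > X.shape[1]:
        raise ParameterError(f"k={k} exceeds {X.shape[1]} features")
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((xc ** 2).sum(axis=0))
    sy = np.sqrt((yc ** 2).sum())
    if sy == 0:
        raise DesignError("labels have zero variance")
    dead = sx == 0
    if dead.any():
        logger.warning("select_features_pearson: %d zero-variance features "
                       "treated as |r| = 0", int(dead.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(dead, 0.0, (xc * yc[:, None]).sum(axis=0) / (sx * sy))
    order = np.argsort(-np.abs(r), kind="stable")
    return order[:k]


# ---------------------------------------------------------------------------
# SVM with leave-one-out cross-validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassificationReport:
    task: str
    accuracy: float
    recall: float        # sensitivity = TP / (TP + FN)
    specificity: float   # TN / (TN + FP)
    tp: int
    tn: int
    fp: int
    fn: int
    selected_features: list = field(default_factory=list)  # per-fold index arrays
    config: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def svm_loocv(X: np.ndarray, y: np.ndarray, k: int = 50,
              kernel: str = "linear", C: float = 1.0,
              class_weight: str | None = None, seed: int = 0,
              selection: str = "per_fold", task: str = "") -> ClassificationReport:
    """Leave-one-out SVM with in-fold Pearson feature selection.

    For each held-out subject, features are re-ranked on the remaining
    rows, the top ``k`` are standardized on the training rows, and an SVM
    predicts the held-out subject. ``selection='global'`` instead ranks
    once on all rows (the optimistic, leakage-prone variant, off by
    default). Labels must be binary 0/1; class 1 is the positive class.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = len(y)
    if n < 6:
        raise DesignError("LOOCV needs at least 6 subjects")
    if set(np.unique(y)) != {0, 1}:
        raise DesignError("labels must contain both classes, encoded 0/1")
    if selection not in ("per_fold", "global"):
        raise ParameterError(f"unknown selection mode {selection!r}")
    global_idx = select_features_pearson(X, y, k) if selection == "global" else None

    preds = np.empty(n, dtype=int)
    selected = []
    for i in range(n):
        train = np.ones(n, dtype=bool)
        train[i] = False
        ytr = y[train]
        if len(np.unique(ytr)) < 2:
            raise DesignError(f"fold {i}: a class is absent from the training rows")
        idx = global_idx if global_idx is not None \
            else select_features_pearson(X[train], ytr, k)
        selected.append(np.asarray(idx))
        scaler = StandardScaler().fit(X[train][:, idx])
        clf = SVC(kernel=kernel, C=C, class_weight=class_weight,
                  random_state=seed)
        clf.fit(scaler.transform(X[train][:, idx]), ytr)
        preds[i] = clf.predict(scaler.transform(X[i:i + 1, idx]))[0]

    tp = int(np.sum((preds == 1) & (y == 1)))
    tn = int(np.sum((preds == 0) & (y == 0)))
    fp = int(np.sum((preds == 1) & (y == 0)))
    fn = int(np.sum((preds == 0) & (y == 1)))
    return ClassificationReport(
        task=task,
        accuracy=(tp + tn) / n,
        recall=tp / (tp + fn) if tp + fn else float("nan"),
        specificity=tn / (tn + fp) if tn + fp else float("nan"),
        tp=tp, tn=tn, fp=fp, fn=fn,
        selected_features=selected,
        config={"k": k, "kernel": kernel, "C": C,
                "class_weight": class_weight, "seed": seed,
                "selection": selection})


# ---------------------------------------------------------------------------
# Permutation test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PermutationResult:
    observed_accuracy: float
    null_accuracies: np.ndarray
    n_perm: int
    p_value: float
    seed: int


def permutation_test(X: np.ndarray, y: np.ndarray, n_perm: int = 200,
                     k: int = 50, kernel: str = "linear", C: float = 1.0,
                     class_weight: str | None = None,
                     seed: int = 0) -> PermutationResult:
    """Label-shuffling null for the LOOCV accuracy.

    Every shuffle reruns the complete protocol — in-fold Pearson ranking,
    standardization, SVM fit — on the permuted labels, so the null
    distribution reflects the entire selection-plus-classification
    pipeline, not just the final classifier.
    """
    if n_perm < 20:
        logger.warning("permutation_test: n_perm=%d gives an unstable p-value",
                       n_perm)
    rng = np.random.default_rng(seed)
    observed = svm_loocv(X, y, k=k, kernel=kernel, C=C,
                         class_weight=class_weight, seed=seed).accuracy
    null = np.empty(n_perm)
    for b in range(n_perm):
        yp = rng.permutation(y)
        null[b] = svm_loocv(X, yp, k=k, kernel=kernel, C=C,
                            class_weight=class_weight, seed=seed).accuracy
    p = (1 + int(np.sum(null >= observed))) / (1 + n_perm)
    return PermutationResult(observed_accuracy=float(observed),
                             null_accuracies=null, n_perm=int(n_perm),
                             p_value=float(p), seed=int(seed))
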