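"""Cross-validation and ROC/AUC machinery.

Folds are stratified (class proportions preserved to within one gene per
fold) and seeded.  Binary performance is the area under the pooled
out-of-fold ROC curve; ties in scores receive half credit, which makes
the trapezoidal area equal the Mann-Whitney concordance estimator.
Multi-class performance is the Hand-Till AUC: the average over unordered
class pairs {i, j} of [A(i|j) + A(j|i)] / 2, where A(i|j) is the binary
AUC of the class-i probability restricted to genes of classes i and j.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve


@dataclass
class CVResult:
    """Pooled out-of-fold predictions from one stratified k-fold run."""

    k: int
    seed: int
    scores: pd.DataFrame  # genes x 1 ("score") or genes x classes
    folds: pd.Series
    labels: pd.Series

    @property
    def binary_scores(self) -> pd.Series:
        return self.scores.iloc[:, 0]

    def write(self, path) -> None:
        out = self.scores.copy()
        out.insert(0, "fold", self.folds)
        out.insert(1, "label", self.labels)
        out.index.name = "gene"
        out.to_csv(path, sep="\t")


@dataclass
class ROCCurve:
    """Threshold-swept ROC curve with trapezoidal area."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def write(self, path) -> None:
        pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr}).to_csv(
            path, sep="\t", index=False
        )


def stratified_folds(labels: pd.Series, k: int, seed: int) -> pd.Series:
    """Deal each class's members round-robin into k folds.

    A single cursor runs across classes, so k = n yields exact
    leave-one-out; per-fold class counts differ from proportionality by
    at most one gene.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > len(labels):
        raise ValueError(f"k={k} exceeds the {len(labels)} labeled genes")
    rng = np.random.default_rng(seed)
    fold = pd.Series(-1, index=labels.index, dtype=int)
    cursor = rng.integers(0, k)  # random fold offset, advanced across classes
    for cls in sorted(labels.unique()):
        members = np.asarray(labels.index[labels == cls])
        if len(members) == 0:
            raise ValueError(f"class {cls!r} has no members")
        members = members[rng.permutation(len(members))]
        for g in members:
            fold[g] = cursor % k
            cursor += 1
    return fold


def kfold_cv(m, labels: pd.Series, k: int, fitter, seed: int = 0) -> CVResult:
    """Stratified k-fold cross-validation of an arbitrary fitter.

    ``fitter(train_matrix, train_labels)`` must return a scoring callable
    ``scorer(test_matrix) -> ndarray`` of shape (n,) for binary scores or
    (n, K) for class probabilities.  Every labeled gene is scored exactly
    once, by a model that never saw it.
    """
    labels = pd.Series(labels)
    folds = stratified_folds(labels, k, seed)
    parts = []
    for f in range(k):
        test_genes = list(folds.index[folds == f])
        train_genes = list(folds.index[folds != f])
        if not test_genes:
            continue
        scorer = fitter(m.subset_genes(train_genes), labels.loc[train_genes])
        scored = np.asarray(scorer(m.subset_genes(test_genes)))
        if scored.ndim == 1:
            part = pd.DataFrame({"score": scored}, index=test_genes)
        else:
            part = pd.DataFrame(scored, index=test_genes)
        parts.append(part)
    scores = pd.concat(parts).loc[labels.index]
    return CVResult(k=k, seed=seed, scores=scores, folds=folds, labels=labels)


def roc_auc(scores, binary_labels) -> ROCCurve:
    """ROC curve (all thresholds) and trapezoidal AUC.

    Equals the probability that a random positive outranks a random
    negative, with ties counted half.
    """
    y = np.asarray(binary_labels, dtype=float)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, _ = _sk_roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr=fpr, tpr=tpr, auc=auc)


def hand_till_auc(prob_matrix: pd.DataFrame, class_labels: pd.Series) -> float:
    """Hand-Till multi-class AUC over all unordered class pairs.

    Classes without members are dropped with a warning.  A(i|j) ranks
    genes of classes i and j by their class-i probability.
    """
    labels = pd.Series(class_labels).loc[prob_matrix.index]
    present = [c for c in prob_matrix.columns if (labels == c).sum() > 0]
    absent = [c for c in prob_matrix.columns if c not in present]
    if absent:
        warnings.warn(f"classes with no members excluded from AUC: {absent}")
    if len(present) < 2:
        raise ValueError("Hand-Till AUC needs at least 2 populated classes")
    pair_aucs = []
    for ci, cj in combinations(present, 2):
        mask = labels.isin([ci, cj]).to_numpy()
        sub_labels = labels[mask]
        a_ij = roc_auc(prob_matrix.loc[mask, ci], (sub_labels == ci).astype(int)).auc
        a_ji = roc_auc(prob_matrix.loc[mask, cj], (sub_labels == cj).astype(int)).auc
        pair_aucs.append(0.5 * (a_ij + a_ji))
    return float(np.mean(pair_aucs))


def precision_vs_threshold(
    prob_matrix: pd.DataFrame, class_labels: pd.Series, thresholds
) -> pd.DataFrame:
    """Fraction of genes assigned and precision among them, per threshold.

    A gene is assigned when its top class probability reaches the
    threshold; at threshold 0 the precision is plain multi-class
    accuracy.  Precision is NA when nothing is assigned.
    """
    labels = pd.Series(class_labels).loc[prob_matrix.index]
    arr = prob_matrix.to_numpy()
    top = arr.max(axis=1)
    call = np.asarray(prob_matrix.columns)[arr.argmax(axis=1)]
    correct = call == labels.to_numpy()
    rows = []
    for t in thresholds:
        assigned = top >= t
        frac = float(assigned.mean())
        precision = float(correct[assigned].mean()) if assigned.any() else np.nan
        rows.append((float(t), frac, precision))
    return pd.DataFrame(rows, columns=["threshold", "fraction_assigned", "precision"])


def operating_point(scores, binary_labels, cutoff: float) -> tuple[float, float]:
    """(false positive rate, sensitivity) of a strict probability cutoff."""
    y = np.asarray(binary_labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    called = s > cutoff
    fpr = float(called[y == 0].mean()) if (y == 0).any() else 0.0
    sens = float(called[y == 1].mean()) if (y == 1).any() else 0.0
    return fpr, sens


def lambda_grid_auc(m, labels: pd.Series, fitter_factory, lambdas, k: int = 10, seed: int = 0) -> pd.DataFrame:
    """Sensitivity of cross-validated AUC to the ridge weight.

    ``fitter_factory(lam)`` must return a kfold_cv fitter; reports one
    (lambda, auc) row per grid point.
    """
    rows = []
    y = (pd.Series(labels) == "pos").astype(int) if labels.dtype == object else pd.Series(labels)
    for lam in lambdas:
        cv = kfold_cv(m, pd.Series(labels), k, fitter_factory(lam), seed)
        rows.append((float(lam), roc_auc(cv.binary_scores, y.loc[cv.scores.index]).auc))
    return pd.DataFrame(rows, columns=["lambda", "auc"])
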