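"""Ten-fold cross-validated multiclass SVM and the evaluation measures.

The classifier contract is a maximum-margin SVM: linear kernel, complexity
constant C = 1.0, one-vs-one pairwise voting for the multiclass decision,
with per-feature standardization fitted on each training split.  Folds are
a random permutation dealt round-robin, so fold sizes differ by at most
one; a stratified variant deals per class (useful when a 14-sample class
could otherwise vanish from a training split).

Metrics follow the per-class accuracy convention for multiclass screens:
ACC_j = x_j / X_j (correct in class j over class-j size), the overall
accuracy TACC = sum_j x_j / sum_j X_j, and per-class sensitivity and
specificity from the one-vs-rest collapse of the confusion matrix; SN_j
coincides with ACC_j by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FoldPartition:
    """Assignment of every sample to one of k folds."""

    fold_of_sample: pd.Series  # sample ID -> fold index in 0..k-1
    k: int
    seed: int

    def test_mask(self, fold: int, sample_ids: pd.Index) -> np.ndarray:
        return (self.fold_of_sample.loc[sample_ids] == fold).to_numpy()


@dataclass(frozen=True)
class ConfusionMatrix:
    """Square predicted-vs-true count table accumulated over CV folds."""

    counts: np.ndarray  # counts[true class, predicted class]
    classes: list[str]

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1] or c.shape[0] != len(self.classes):
            raise ValueError("counts must be square and match the class list")
        if (c < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_samples(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)


def kfold_partition(
    sample_ids: Sequence[str],
    k: int = 10,
    seed: int = 0,
    stratified: bool = False,
    labels: pd.Series | None = None,
) -> FoldPartition:
    """Random k-fold split: permute under ``seed``, deal round-robin.

    The first ``n mod k`` folds get one extra sample.  With
    ``stratified=True`` the deal is per class (``labels`` required), keeping
    every class spread across folds.
    """
    ids = pd.Index(sample_ids)
    n = len(ids)
    if k < 2 or k > n:
        raise ValueError(f"need 2 <= k <= n samples, got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    fold = pd.Series(-1, index=ids, dtype=int)
    if stratified:
        if labels is None:
            raise ValueError("stratified partition requires labels")
        counter = 0
        for cls in pd.unique(labels.loc[ids]):
            members = ids[(labels.loc[ids] == cls).to_numpy()]
            perm = rng.permutation(len(members))
            for pos, i in enumerate(perm):
                fold.loc[members[i]] = (counter + pos) % k
            counter += len(members)
    else:
        perm = rng.permutation(n)
        fold.iloc[perm] = np.arange(n) % k
    return FoldPartition(fold, k, seed)


def cross_validate(
    m: pd.DataFrame,
    labels: pd.Series,
    feature_subset: Sequence[str],
    partition: FoldPartition,
    C: float = 1.0,
) -> ConfusionMatrix:
    """k-fold CV of the linear SVM on a feature subset; pooled confusion matrix.

    Standardization is fitted on each training split only.  A training split
    that degenerates to a single class is logged and predicted as that class.
    """
    feature_subset = list(feature_subset)
    if not feature_subset:
        raise ValueError("feature_subset must be non-empty")
    missing = set(feature_subset) - set(m.index)
    if missing:
        raise KeyError(f"features absent from matrix: {sorted(missing)[:5]}")

    classes = list(pd.unique(labels.loc[m.columns]))
    class_idx = {c: i for i, c in enumerate(classes)}
    X = m.loc[feature_subset].to_numpy(dtype=float).T  # samples x features
    y = labels.loc[m.columns].to_numpy()

    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for fold in range(partition.k):
        test = partition.test_mask(fold, m.columns)
        train = ~test
        if not test.any():
            continue
        train_classes = np.unique(y[train])
        if len(train_classes) < 2:
            logger.warning("fold %d: single-class training split", fold)
            pred = np.full(int(test.sum()), train_classes[0], dtype=object)
        else:
            scaler = StandardScaler().fit(X[train])
            clf = SVC(kernel="linear", C=C, decision_function_shape="ovo")
            clf.fit(scaler.transform(X[train]), y[train])
            pred = clf.predict(scaler.transform(X[test]))
        for t, p in zip(y[test], pred):
            counts[class_idx[t], class_idx[p]] += 1
    return ConfusionMatrix(counts, classes)


def class_accuracy(cm: ConfusionMatrix, j: int) -> float:
    """ACC_j: correctly predicted class-j samples over the class-j size."""
    row = cm.counts[j]
    total = row.sum()
    if total == 0:
        raise ValueError(f"class {cm.classes[j]!r} has no samples; ACC undefined")
    return float(cm.counts[j, j] / total)


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """TACC: trace over grand total (class-size-weighted mean of ACC_j)."""
    total = cm.counts.sum()
    if total == 0:
        raise ValueError("empty confusion matrix; TACC undefined")
    return float(np.trace(cm.counts) / total)


def sensitivity_specificity(cm: ConfusionMatrix, j: int) -> tuple[float, float]:
    """(SN_j, SP_j) from the one-vs-rest collapse of row/column j.

    SN_j = TP/(TP+FN) equals ACC_j; SP_j = TN/(TN+FP) needs at least one
    sample outside class j, otherwise it is undefined.
    """
    counts = cm.counts
    tp = counts[j, j]
    fn = counts[j].sum() - tp
    fp = counts[:, j].sum() - tp
    tn = counts.sum() - tp - fn - fp
    if tp + fn == 0:
        raise ValueError(f"class {cm.classes[j]!r} empty; SN undefined")
    if tn + fp == 0:
        raise ValueError(f"no samples outside class {cm.classes[j]!r}; SP undefined")
    return float(tp / (tp + fn)), float(tn / (tn + fp))


def per_class_metrics(cm: ConfusionMatrix) -> pd.DataFrame:
    """ACC/SN/SP per class as a DataFrame indexed by class."""
    rows = {}
    for j, cls in enumerate(cm.classes):
        sn, sp = sensitivity_specificity(cm, j)
        rows[cls] = {"ACC": class_accuracy(cm, j), "SN": sn, "SP": sp}
    return pd.DataFrame.from_dict(rows, orient="index")
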