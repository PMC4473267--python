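"""Diagnostic classification harness: ROI features, PCA, linear SVM, LOO.

The computer-aided-diagnosis readout of a normalization method: striatal
voxel intensities are stacked into a feature vector per subject
(voxels-as-features, VAF), optionally compressed by PCA, and classified
by a linear support vector machine under leave-one-out cross-validation.
PCA is fitted inside each training fold only, so the held-out subject
never influences its own feature basis.  The Parkinsonian-syndrome class
is the positive class: sensitivity counts detected patients.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.svm import SVC

from .volume_io import PS, BinaryMask, Cohort


@dataclass
class FeatureMatrix:
    """Subjects x features, with aligned labels and ids."""

    X: np.ndarray
    labels: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.X.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains non-finite values")
        if len(self.labels) != self.X.shape[0] or len(self.ids) != self.X.shape[0]:
            raise ValueError("labels/ids must align with feature rows")


@dataclass
class ClassificationReport:
    """Accuracy/sensitivity/specificity (percent) plus confusion counts."""

    accuracy: float
    sensitivity: float
    specificity: float
    tp: int
    fp: int
    tn: int
    fn: int

    @classmethod
    def from_counts(cls, tp: int, fp: int, tn: int, fn: int) -> "ClassificationReport":
        total = tp + fp + tn + fn
        if total == 0:
            raise ValueError("no predictions to score")
        return cls(
            accuracy=100.0 * (tp + tn) / total,
            sensitivity=100.0 * tp / (tp + fn) if tp + fn else float("nan"),
            specificity=100.0 * tn / (tn + fp) if tn + fp else float("nan"),
            tp=tp,
            fp=fp,
            tn=tn,
            fn=fn,
        )


def vaf_features(cohort: Cohort, striatal: BinaryMask) -> FeatureMatrix:
    """One row per subject: striatal intensities in lexicographic voxel order."""
    if striatal.count == 0:
        raise ValueError("empty striatal mask")
    if cohort.shape != striatal.shape:
        raise ValueError("grid mismatch between cohort and mask")
    sel = striatal.data  # boolean indexing yields C (lexicographic) order
    X = np.stack([vol.data[sel] for vol in cohort.volumes])
    return FeatureMatrix(X, np.asarray(cohort.labels), list(cohort.ids))


def loo_classify(
    features: FeatureMatrix,
    use_pca: bool = False,
    pca_variance: float = 0.95,
    svm_c: float = 1.0,
    positive_label: str = PS,
) -> ClassificationReport:
    """Leave-one-out linear-SVM classification of a feature matrix.

    With ``use_pca`` the training fold is first projected onto the
    smallest number of principal components reaching ``pca_variance``
    explained variance (fitted on that fold only).
    """
    y = features.labels == positive_label
    n = len(y)
    if int(y.sum()) < 2 or int((~y).sum()) < 2:
        raise ValueError("need at least 2 subjects per class")
    tp = fp = tn = fn = 0
    for i in range(n):
        train = np.ones(n, dtype=bool)
        train[i] = False
        X_train, y_train = features.X[train], y[train]
        X_test = features.X[i : i + 1]
        if use_pca:
            pca = PCA(n_components=pca_variance, svd_solver="full")
            X_train = pca.fit_transform(X_train)
            X_test = pca.transform(X_test)
        clf = SVC(kernel="linear", C=svm_c)
        clf.fit(X_train, y_train)
        pred = bool(clf.predict(X_test)[0])
        if y[i]:
            tp += pred
            fn += not pred
        else:
            fp += pred
            tn += not pred
    return ClassificationReport.from_counts(tp=tp, fp=fp, tn=tn, fn=fn)


def report_tables(reports: Mapping[str, ClassificationReport]) -> pd.DataFrame:
    """Summarize reports as one row per normalization method.

    Percentages are rounded to 2 decimals, matching the usual reporting
    convention for CAD accuracy tables.
    """
    rows = [
        {
            "method": name,
            "accuracy": round(rep.accuracy, 2),
            "sensitivity": round(rep.sensitivity, 2),
            "specificity": round(rep.specificity, 2),
        }
        for name, rep in reports.items()
    ]
    return pd.DataFrame(rows, columns=["method", "accuracy", "sensitivity", "specificity"])
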