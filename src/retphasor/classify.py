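"""Classifier training/evaluation under a repeated 70/30 holdout protocol.

Four classical classifiers are compared on the per-case feature tables:
Nearest Centroid (NC), Gaussian Naive Bayes (GNB), an RBF Support Vector
Machine (SVM) and a ν-Support Vector Classifier (ν-SVC).  The dataset is
randomly split 70/30 into train/test over 10 independent repetitions from a
fixed seed (no stratification), the same partitions being reused across all
feature sets and classifiers, and six metrics are reported per repetition
and as means: overall accuracy, balanced accuracy, specificity, sensitivity,
precision and F1 score.  Diseased is the positive class throughout, so
sensitivity measures disease detection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import NearestCentroid
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, NuSVC

from .io import FeatureTable

__all__ = ["SplitProtocol", "ClassificationReport", "CLASSIFIERS", "make_splits",
           "train_predict", "compute_metrics", "evaluate"]

CLASSIFIERS = ("nc", "gnb", "svm", "nusvc")
METRICS = ("oa", "ba", "specificity", "sensitivity", "precision", "f1")


@dataclass(frozen=True)
class SplitProtocol:
    """Repeated random holdout: 70% train / 30% test × 10 repetitions, seeded."""

    train_fraction: float = 0.7
    n_reps: int = 10
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.n_reps < 1:
            raise ValueError("n_reps must be ≥ 1")


@dataclass
class ClassificationReport:
    """Six metrics per repetition plus their unweighted means.

    OA and BA are percentages in [0, 100]; the other four are ratios in [0, 1].
    """

    classifier: str
    per_rep: pd.DataFrame
    means: dict[str, float] = field(init=False)

    def __post_init__(self):
        self.means = {m: float(self.per_rep[m].mean()) for m in METRICS}
        # internal consistency: BA is the mean of sensitivity and specificity
        ba = (self.per_rep["sensitivity"] + self.per_rep["specificity"]) / 2 * 100
        assert np.allclose(ba, self.per_rep["ba"], atol=1e-9)

    def display_row(self) -> dict[str, object]:
        """Table-style row: integer percent OA/BA, 2-decimal ratios."""
        m = self.means
        return {
            "OA (%)": round(m["oa"]), "BA (%)": round(m["ba"]),
            "Specificity": round(m["specificity"], 2),
            "Sensitivity": round(m["sensitivity"], 2),
            "Precision": round(m["precision"], 2),
            "F1 Score": round(m["f1"], 2),
        }


def make_splits(n_cases: int, protocol: SplitProtocol) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded list of (train_idx, test_idx) partitions, |train| = round(f·n).

    Splits are plain random permutations — not stratified — and the same
    protocol yields the same list every time, so one list can be shared by
    every feature set and classifier in an experiment.
    """
    if n_cases < 4:
        raise ValueError("need at least 4 cases to split")
    n_train = int(round(protocol.train_fraction * n_cases))
    n_train = min(max(n_train, 1), n_cases - 1)
    rng = np.random.default_rng(protocol.seed)
    splits = []
    for _ in range(protocol.n_reps):
        perm = rng.permutation(n_cases)
        splits.append((np.sort(perm[:n_train]), np.sort(perm[n_train:])))
    return splits


def _make_estimator(kind: str, hyperparams: dict | None):
    hp = dict(hyperparams or {})
    if kind == "nc":
        return NearestCentroid(**hp)
    if kind == "gnb":
        return GaussianNB(**hp)
    # margin classifiers are scale-sensitive: standardize inside the split
    # (scaler fitted on the training fold only — no leakage)
    if kind == "svm":
        hp.setdefault("C", 1.0)
        return make_pipeline(StandardScaler(), SVC(kernel="rbf", gamma="scale", **hp))
    if kind == "nusvc":
        hp.setdefault("nu", 0.5)
        return make_pipeline(StandardScaler(), NuSVC(kernel="rbf", gamma="scale", **hp))
    raise ValueError(f"unknown classifier '{kind}', expected one of {CLASSIFIERS}")


def train_predict(table: FeatureTable, split: tuple[np.ndarray, np.ndarray],
                  classifier_kind: str, hyperparams: dict | None = None) -> np.ndarray:
    """Fit one classifier on the train fold and predict the test fold labels."""
    train_idx, test_idx = split
    y_train = table.y[train_idx]
    if len(np.unique(y_train)) < 2:
        raise ValueError("training set contains a single class")
    est = _make_estimator(classifier_kind, hyperparams)
    est.fit(table.X[train_idx], y_train)
    return est.predict(table.X[test_idx])


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name}: 0/0 encountered, using 0 by convention", stacklevel=3)
        return 0.0
    return num / den


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    """Six metrics from one test fold; diseased (label 1) is positive.

    Any undefined 0/0 ratio (e.g. precision with no positive predictions)
    is 0 by convention, with a warning.
    """
    y_true = np.asarray(y_true, int)
    y_pred = np.asarray(y_pred, int)
    if y_true.size == 0:
        raise ValueError("empty test fold")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    sens = _safe_ratio(tp, tp + fn, "sensitivity")
    spec = _safe_ratio(tn, tn + fp, "specificity")
    prec = _safe_ratio(tp, tp + fp, "precision")
    f1 = _safe_ratio(2 * prec * sens, prec + sens, "f1")
    return {
        "oa": (tp + tn) / y_true.size * 100.0,
        "ba": (sens + spec) / 2.0 * 100.0,
        "specificity": spec,
        "sensitivity": sens,
        "precision": prec,
        "f1": f1,
    }


def evaluate(table: FeatureTable, protocol: SplitProtocol, classifier_kind: str,
             hyperparams: dict | None = None,
             splits: list[tuple[np.ndarray, np.ndarray]] | None = None
             ) -> ClassificationReport:
    """Run the full repeated-holdout protocol for one classifier on one table.

    Pass precomputed ``splits`` to share identical partitions across feature
    sets/classifiers; otherwise they are generated from the protocol seed.
    """
    if splits is None:
        splits = make_splits(table.n_cases, protocol)
    rows = []
    for rep, split in enumerate(splits):
        y_pred = train_predict(table, split, classifier_kind, hyperparams)
        row = compute_metrics(table.y[split[1]], y_pred)
        row["rep"] = rep
        rows.append(row)
    per_rep = pd.DataFrame(rows).set_index("rep")
    return ClassificationReport(classifier_kind, per_rep)
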