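"""Supervised strategy classification with ensemble majority voting.

A zoo of classifier families is trained on manually labelled subsegments;
each candidate's stratified 10-fold cross-validated accuracy is estimated,
candidates at or above the selection threshold (default 75 %) are refit on
all training data, and new subsegments are labelled by plurality vote of
the selected classifiers.  A tie for the top vote count marks the
subsegment ``unidentified``.

The zoo approximates the usual families (discriminant analysis, naive
Bayes, k-NN variants, decision trees, SVM kernels, bagged/boosted trees and
random-subspace ensembles); it is configurable, and the selection + voting
procedure — not any particular preset — is the contract.  Features are
standardised with training-fold statistics inside each CV split, so no
information leaks across folds.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    RandomForestClassifier,
)
from sklearn.metrics import accuracy_score, f1_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .labels import UNIDENTIFIED

__all__ = [
    "CandidateReport",
    "EnsembleModel",
    "default_zoo",
    "train_candidates",
    "select_ensemble",
    "majority_vote",
    "classifier_agreement",
]


@dataclass
class CandidateReport:
    name: str
    cv_accuracy: float
    macro_f1: float
    selected: bool = False


@dataclass
class EnsembleModel:
    """Selected classifiers refit on the full training set."""

    names: list[str]
    members: list
    classes: np.ndarray

    def predictions(self, X) -> np.ndarray:
        """(n_members, n_samples) label matrix."""
        return np.stack([m.predict(X) for m in self.members])


def default_zoo(seed: int = 0) -> dict[str, object]:
    """The default classifier-family zoo.

    Every estimator is wrapped with a StandardScaler so scaling happens
    inside CV folds.  Seeded estimators share ``seed`` for determinism.
    """

    def p(est):
        return make_pipeline(StandardScaler(), est)

    return {
        "linear_discriminant": p(LinearDiscriminantAnalysis()),
        "quadratic_discriminant": p(QuadraticDiscriminantAnalysis(reg_param=1e-3)),
        "gaussian_naive_bayes": p(GaussianNB()),
        "fine_knn": p(KNeighborsClassifier(n_neighbors=1)),
        "medium_knn": p(KNeighborsClassifier(n_neighbors=10)),
        "coarse_knn": p(KNeighborsClassifier(n_neighbors=50)),
        "cosine_knn": p(KNeighborsClassifier(n_neighbors=10, metric="cosine")),
        "weighted_knn": p(KNeighborsClassifier(n_neighbors=10, weights="distance")),
        "fine_tree": p(DecisionTreeClassifier(max_depth=None, random_state=seed)),
        "medium_tree": p(DecisionTreeClassifier(max_depth=10, random_state=seed)),
        "coarse_tree": p(DecisionTreeClassifier(max_depth=4, random_state=seed)),
        "linear_svm": p(SVC(kernel="linear", random_state=seed)),
        "quadratic_svm": p(SVC(kernel="poly", degree=2, random_state=seed)),
        "cubic_svm": p(SVC(kernel="poly", degree=3, random_state=seed)),
        "gaussian_svm": p(SVC(kernel="rbf", random_state=seed)),
        "bagged_trees": p(BaggingClassifier(DecisionTreeClassifier(random_state=seed),
                                            n_estimators=30, random_state=seed)),
        "boosted_trees": p(AdaBoostClassifier(DecisionTreeClassifier(max_depth=3,
                                                                     random_state=seed),
                                              n_estimators=30, random_state=seed)),
        "subspace_forest": p(RandomForestClassifier(n_estimators=50, max_features=0.5,
                                                    random_state=seed)),
    }


def train_candidates(X, y, zoo: dict | None = None, n_splits: int = 10,
                     seed: int = 0) -> list[CandidateReport]:
    """Stratified k-fold CV accuracy and macro-F1 for every zoo member.

    Deterministic given ``seed``.  Raises if any expected class is missing
    from ``y``; warns when a class has fewer samples than folds.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two classes to train")
    if counts.min() < n_splits:
        warnings.warn(
            f"class {classes[np.argmin(counts)]!r} has only {counts.min()} samples "
            f"for {n_splits}-fold CV; folds will be degraded"
        )
        n_splits = max(2, int(counts.min()))
    zoo = zoo or default_zoo(seed)
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    folds = list(cv.split(X, y))
    reports = []
    for name, est in zoo.items():
        pred = np.empty(len(y), dtype=y.dtype)
        try:
            for train_idx, test_idx in folds:
                model = clone(est)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model.fit(X[train_idx], y[train_idx])
                pred[test_idx] = model.predict(X[test_idx])
        except Exception as err:  # e.g. singular class covariance on tiny data
            warnings.warn(f"candidate {name!r} failed to fit ({err}); scored 0")
            reports.append(CandidateReport(name=name, cv_accuracy=0.0, macro_f1=0.0))
            continue
        reports.append(
            CandidateReport(
                name=name,
                cv_accuracy=float(accuracy_score(y, pred)),
                macro_f1=float(f1_score(y, pred, average="macro")),
            )
        )
    return reports


def select_ensemble(X, y, reports: list[CandidateReport], zoo: dict | None = None,
                    threshold: float = 0.75, seed: int = 0) -> EnsembleModel:
    """Keep candidates with CV accuracy >= threshold, refit them on all data."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    zoo = zoo or default_zoo(seed)
    selected = [r for r in reports if r.cv_accuracy >= threshold]
    for r in reports:
        r.selected = r.cv_accuracy >= threshold
    if not selected:
        best = max(reports, key=lambda r: r.cv_accuracy)
        raise ValueError(
            f"no classifier reached {threshold:.0%} CV accuracy (best: {best.name} "
            f"at {best.cv_accuracy:.1%}); lower the threshold or improve the labels"
        )
    if len(selected) < 2:
        warnings.warn("ensemble has fewer than 2 members; majority voting is degenerate")
    members, names = [], []
    for r in selected:
        model = clone(zoo[r.name])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X, y)
        members.append(model)
        names.append(r.name)
    return EnsembleModel(names=names, members=members, classes=np.unique(y))


def majority_vote(ensemble: EnsembleModel, X, return_counts: bool = False):
    """Plurality label per subsegment; any tie for the top count is
    ``unidentified``."""
    X = np.asarray(X, dtype=float)
    preds = ensemble.predictions(X)  # (members, samples)
    classes = ensemble.classes
    counts = np.zeros((X.shape[0], len(classes)), dtype=int)
    for ci, c in enumerate(classes):
        counts[:, ci] = np.sum(preds == c, axis=0)
    top = counts.max(axis=1)
    n_top = np.sum(counts == top[:, None], axis=1)
    winner = classes[np.argmax(counts, axis=1)].astype(object)
    labels = np.where(n_top > 1, UNIDENTIFIED, winner)
    if return_counts:
        return labels, pd.DataFrame(counts, columns=list(classes))
    return labels


def classifier_agreement(ensemble: EnsembleModel, X) -> pd.DataFrame:
    """Pairwise fraction of subsegments on which two members agree."""
    preds = ensemble.predictions(np.asarray(X, dtype=float))
    m = len(ensemble.members)
    out = np.ones((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            out[i, j] = out[j, i] = float(np.mean(preds[i] == preds[j]))
    return pd.DataFrame(out, index=ensemble.names, columns=ensemble.names)
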